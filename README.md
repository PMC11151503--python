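# stromascope

Single-cell metabolic imaging analysis for cells on engineered fiber
scaffolds: frequency-domain **phasor FLIM** of NADH with two-component
lifetime fitting and the free/bound **metabolic index**, **optical redox
ratio** (ORR) imaging, per-cell segmentation with intensity quantification
and **nuclear morphometry**, scaffold **fiber-orientation** and stiffness
characterization, and the 2^−ΔΔCt / group-comparison statistics that tie
the stages into an aligned-vs-random scaffold study.

It is written for imaging labs that quantify cellular metabolism
label-free — e.g. mammary epithelial lines cultured on electrospun
nanofiber mats — and ships a fully seeded synthetic-data module that
generates every input (TCSPC decay stacks, two-channel cell fields, fiber
mats, Ct tables, stress–strain records) with exact ground truth, so the
entire pipeline is testable without any microscope.

## The models at the core

**Phasor FLIM.** Each decay histogram becomes a phasor
`g_k = Σ c_j cos(ω_k t_j)/Σ c_j`, `s_k = Σ c_j sin(ω_k t_j)/Σ c_j` at
harmonics `ω_k = 2πk/T` of the 20 MHz repetition rate (T = 50 ns, 256
bins).  Single exponentials fall on the universal circle
`(g−½)² + s² = ¼`; after calibration against a 3.6 ns reference standard,
multi-harmonic modulation/phase data are fitted by bounded non-linear least
squares to the two-lifetime NADH model (free τ₁ ≈ 0.4 ns, bound
τ₂ ∈ 1.4–9 ns) with amplitude fractions α₁ + α₂ = 1, yielding

    τ_m = α₁τ₁ + α₂τ₂        (mean lifetime)
    metabolic index = α₁/α₂   (free/bound; higher = more glycolytic)

The fit's forward model uses the exact phasor of bin-integrated decays, so
noiseless round trips recover parameters to optimizer precision
(see `docs/methods.md`).

**ORR.** `I_FAD/(I_FAD + I_NADH)` per pixel (1 = oxidative,
0 = glycolytic), with Rhodamine-B reference normalization and
nucleus-excluded per-cell means.

**Morphometry & scaffold.** Nuclei by minimum cross-entropy thresholding,
cells by seeded propagation, circularity `4πA/P²`; fiber orientation by
structure tensor summarized by the 2D Herman index `S = 2⟨cos²θ⟩ − 1`
(1 aligned, 0 random); fiber diameter by skeleton + distance transform;
Young's modulus from the linear stress–strain region.

**Statistics.** 2^−ΔΔCt relative expression (ACTB housekeeping), Welch's
and Student's t, two-sample Kolmogorov–Smirnov (exact at small n), means
with SEM.

## Worked example

Fit a noisy simulated NADH decay (5,000 photons, α₁ = 0.7, τ₁ = 0.4 ns,
τ₂ = 2.5 ns) after calibrating against an ideal 3.6 ns standard:

```python
from stromascope.simulate import DecaySimSpec, simulate_decay
from stromascope.phasor import (build_calibration, phasor_transform,
                                apply_calibration, fit_biexponential,
                                mean_lifetime, metabolic_index)

ref = simulate_decay(DecaySimSpec([3.6], [1.0], total_photons=1e6))
cal = build_calibration(ref, tau_ref_ns=3.6)

decay = simulate_decay(DecaySimSpec(
    lifetimes_ns=[0.4, 2.5], amplitude_fractions=[0.7, 0.3],
    total_photons=5000, noise="poisson", seed=1))
points = apply_calibration(phasor_transform(decay), cal)
fit = fit_biexponential(points, calibration=cal)
print(f"tau1 = {fit.tau1_ns:.3f} ns, tau2 = {fit.tau2_ns:.3f} ns, "
      f"alpha1 = {fit.alpha1:.3f}")
print(f"mean lifetime = {mean_lifetime(fit):.3f} ns, "
      f"metabolic index = {metabolic_index(fit):.3f}")
```

```
tau1 = 0.406 ns, tau2 = 2.555 ns, alpha1 = 0.708
mean lifetime = 1.034 ns, metabolic index = 2.424
```

The recovered α₁ = 0.708 is within Poisson uncertainty of the programmed
0.7; the metabolic index 2.42 (= 0.708/0.292) says this "cell" holds about
2.4× more free than bound NADH — a glycolytic signature.

A full synthetic aligned-vs-random study (FLIM, ORR, vimentin +
circularity, glucose uptake, fibers, qPCR, with the matching tests per
metric) runs in seconds:

```python
from stromascope import run_study
summary = run_study(seed=42)
print(summary["comparisons"]["metabolic_index"]["p_value"])
```

or from the shell: `stromascope run-study --seed 42 --out study/`.
The CLI also exposes each stage (`stromascope simulate ...`,
`flim`, `orr`, `quantify`, `fibers`, `tensile`, `qpcr`, `compare`).

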