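# Methods

This note documents the models, estimators and numerical conventions behind
`stromascope`, and what its synthetic-data suite does and does not
demonstrate about real data.

## Decay simulation and the binning convention

The decay generator emulates time-correlated single-photon counting: a laser
repetition period `T` (default 50 ns) divided into `n_bins` equal bins
(default 256).  The expected content of bin `j` is the **integral** of
`sum_i alpha_i exp(-t/tau_i)` over `[t_j, t_j + dt)` — the photon-counting
convention, not a midpoint sample — rescaled so the noiseless histogram sums
exactly to `total_photons`.  Poisson noise draws each bin independently.

Two deliberate idealizations:

- **No instrument response function.**  Real systems fold the decay with an
  IRF that the reference-standard calibration absorbs; simulating an ideal
  instrument makes the calibration contract testable in closed form.
- **No wrap-around excitation.**  Decays are truncated at the period.  At
  the NADH lifetimes involved (tau <= 9 ns, T = 50 ns) the wrapped tail is
  below `exp(-5)` of peak.  Conveniently, truncation at harmonic frequencies
  cancels **exactly** in the phasor (the residual factor `(1 - z^N)` equals
  `(1 - e^{-T/tau})` because `e^{i w_k T} = 1`), so it introduces no phasor
  bias at all.

Photon budget: the default 5,000 photons/pixel is a package choice (typical
of a 0.1 ms dwell over 3 scans); it is a field of `DecaySimSpec` and of the
study config.

## Phasor transform, calibration, and the exact binned model

The phasor at harmonic `k` is the normalized discrete Fourier sum over bin
centers.  For a bin-integrated, period-truncated mono-exponential this sum
has the exact closed form

    P_k(tau) = e^{i b} (1 - x) / (1 - x e^{2 i b}),
    b = w_k dt / 2,   x = e^{-dt/tau},

which approaches the continuous `1/(1 - i w_k tau)` as `dt -> 0` but
differs from it at second order: the relative distortion is approximately
`1 + (w_k dt)^2/24 + i (w_k dt^2)/(12 tau)`.  The imaginary part is
**lifetime-dependent**, so no per-harmonic scalar correction can remove it
for every lifetime simultaneously.  Two consequences shape the design:

- **Calibration** follows the standard frequency-domain recipe: per
  harmonic, a modulation scale `m_theory/m_measured` and phase offset
  `phi_theory - phi_measured`, with the continuous theory values
  `m = 1/sqrt(1+(w tau_ref)^2)`, `phi = atan(w tau_ref)` for the reference
  standard (Atto 425, 3.6 ns).  The correction lands the reference exactly
  on its theoretical phasor; other lifetimes retain the small
  lifetime-dependent binning residual (~1e-4 at harmonic 1 with 256 bins,
  growing quadratically with harmonic).
- **The bi-exponential fit** therefore uses the exact binned component
  phasors composed with the calibration correction whenever the calibration
  and the instrument layout (period, bin count, carried on every
  `PhasorPoint`) are available.  The forward model then matches the data
  convention to machine precision and the noiseless round trip
  (simulate -> transform -> calibrate -> fit) recovers `(alpha1, tau1,
  tau2)` to ~1e-9 relative across the physiological grid.  Without the
  metadata the fit falls back to the continuous component model, adequate
  for fine-binned or externally calibrated data.

The universal-circle identity `(g - 1/2)^2 + s^2 = 1/4` is a continuum
statement; the test suite checks it at harmonic 1 with fine binning
(`n_bins = 32768`), where the measured residual is ~1e-8.  At 256 bins the
identity holds to ~1e-4 — the floor set by the binning distortion above,
not by any estimator defect.

### Two-component model and derived metrics

The fit minimizes `sum_k (m_k - m_k^model)^2 + w (phi_k - phi_k^model)^2`
(phase weight `w = 1`) over harmonics 1–8 of the 20 MHz fundamental — 16
observations for 3 free parameters `(tau1, tau2, alpha1)`.  `alpha_i` are
amplitude (pre-exponential) fractions; the amplitude-to-intensity
conversion `f_i = alpha_i tau_i / sum_j alpha_j tau_j` happens inside the
frequency-domain model (in binned mode the effective integral
`tau_i (1 - e^{-T/tau_i})` is used).  An intensity-fraction reading of
alpha is available via `alpha_is_intensity_fraction=True`.

Bounds default to the physiological free/bound NADH ranges
(`tau1 in [0.1, 1]` ns, `tau2 in [1, 9]` ns); optimization is bounded
trust-region least squares from 5 deterministic starting points, keeping
the best.  `tau1 < tau2` is enforced by sorting (swapping `alpha` with the
components); fits with `|tau2 - tau1| < 0.05` ns are flagged degenerate.

Derived metrics: mean lifetime `tau_m = alpha1 tau1 + alpha2 tau2` and the
NADH metabolic index `alpha1/alpha2` (free over bound; higher = more
glycolytic).

### Per-cell aggregation

Per-pixel bi-exponential fits at a few thousand photons are unstable, so
per-cell metrics pool (sum) the histograms of a cell's qualifying pixels
(default threshold 100 photons/pixel) before one transform and fit per
cell.  Cells with no qualifying pixel are dropped with a warning.  Display
products can use per-pixel phase lifetimes; quantitative results come from
pooled fits only.

## Optical redox ratio

`ORR = I_FAD / (I_FAD + I_NADH)` per pixel (1 = oxidative, 0 = glycolytic).
Images taken under different settings are first divided by the spatial mean
of a Rhodamine B reference acquired at the same settings; normalization is
per channel (whether the original protocol normalized per channel or per
session is not stated; per-channel is the assumption here).  Pixels with a
zero denominator are masked and never imputed.  Optional per-channel scalar
background subtraction clips negatives to zero; the quantification path
instead **excludes** background via segmentation — subtraction is for
visualization.  Per-cell values average the ORR over cell-minus-nucleus
pixels, dropping cells with fewer than 20 qualifying pixels.

## Segmentation and morphometry

- **Nuclei**: global minimum cross-entropy (Li) threshold, connected
  components, size filter (defaults 50–10,000 px), and optional
  declumping by distance-transform watershed (smoothing scale 2 px).
  Declumping should be disabled for preparations with well-separated,
  strongly elongated nuclei, which a watershed would split.
- **Cells**: CellProfiler-style propagation.  Foreground is the Li
  threshold of the cytoplasmic channel united with the nuclei; each
  foreground pixel joins the nucleus seed of minimum accumulated cost,
  where a step of length `d` between pixels of (range-normalized)
  intensities `a, b` costs `d * lambda + |a - b|` with regularization
  `lambda = 0.05`.  With uniform intensity this is exactly nearest-seed
  geodesic distance (verified against an independent Dijkstra oracle).
- **Circularity** `4 pi A / P^2` uses area = pixel count and, by default, a
  perimeter measured on the 0.5-level marching-squares contour of the
  Gaussian-smoothed mask (sigma 2 px).  The common alternatives are biased
  at the few-percent level on canonical shapes: a 4-direction Crofton
  estimate makes the axis-aligned square read 0.88 instead of pi/4 = 0.785,
  and raw pixel-edge counts make the disk read 0.91.  The smoothed-contour
  default reads disk 0.999, square 0.799, ellipse(2:1) 0.841 (Ramanujan
  oracle 0.841), and is rotation-invariant within 0.03; `"crofton"` and
  `"pixel"` remain available as config switches.  For small nuclei
  (semi-minor axis < ~8 px) a smoothing sigma of 1 px is preferable — the
  study pipeline uses it.  Reported values are clipped at 1.0 with the raw
  value retained; single-pixel objects are undefined and flagged.

## Fiber orientation and mechanics

Angles are degrees in `[-90, 90)`, 0 = image x-axis, counter-clockwise
with y up — one convention shared by generator and analyzer and asserted in
tests.

- **Orientation distribution**: per-pixel structure tensor at smoothing
  scale 2 px; pixel weight = coherence x gradient energy; background
  (energy below 5% of max) and a 3-sigma border margin excluded.  Computed
  per pixel rather than per traced fiber: robust to crossings, and
  validated against the generator's per-fiber ground truth.
- **Herman index**: 2D form `S = 2<cos^2 theta> - 1` (endpoints: 1 aligned,
  0 isotropic, -1 perpendicular to a fixed axis); the 3D variant
  `(3<cos^2>-1)/2` behind a flag.  Auto-reference takes the principal
  direction `0.5 atan2(<sin 2theta>, <cos 2theta>)`, the maximizer of S,
  which guarantees `S in [0, 1]` and rotation invariance.  Per-image S on
  isotropic mats has large sampling variance at realistic fiber counts;
  report per-image values with uncertainty rather than a single number.
- **Diameter**: Li threshold, skeletonize, then `2 * EDT - 1` px at each
  skeleton pixel (the EDT of a centerline pixel of a w-px ribbon is
  `(w+1)/2`).  Unbiased within ~5% for widths >= 6 px on straight fibers;
  at fiber junctions the EDT inflates, so the median of the distribution is
  the robust summary on dense mats.
- **Young's modulus**: least-squares slope of stress vs strain.  The
  default window is the maximal leading window with `R^2 >= 0.99`, which on
  a sharp linear-plateau curve admits a short stretch of the bend (~6% slope
  underestimate); pass the elastic window explicitly when it is known.  An
  explicit window is fitted directly without the `R^2` gate; auto-selection
  with no qualifying window raises an error reporting the best window.

## Expression and comparison statistics

- **2^-ddCt**: per sample `dCt = Ct_target - Ct_housekeeping` (ACTB
  default); condition means of dCt are differenced against the baseline
  condition (condition-mean convention — no per-sample pairing is assumed),
  and `fold = 2^-ddCt`.  Per-sample fold changes
  `2^-(dCt - mean dCt_baseline)` are also emitted for dispersion.
- **Tests**: Welch's t, Student's t and the two-sample KS statistic are
  computed from their standard formulas; p-values come from the Student-t
  tail and, for KS, the asymptotic Kolmogorov distribution with the
  Stephens finite-sample correction `(en + 0.12 + 0.11/en) D` for
  `min(n, m) >= 10`, and exact lattice-path enumeration below.  The
  correction matters: at n = m = 10 the uncorrected tail puts the rejection
  threshold at D = 0.7 (true size 0.011), while the corrected tail rejects
  at D >= 0.6 (true size 0.052 by exact enumeration) — calibrated at the
  nominal 5%.  Degenerate zero-variance equal-mean groups return p = 1 by
  convention.  No multiple-testing correction is applied by default,
  matching per-comparison reporting.
- **Percent change** is `100 (mean_a - mean_b)/mean_b` with the baseline as
  group b.  Published summaries that report both rounded group means and a
  percent change need not be mutually consistent (0.27 vs 0.31 gives 12.9%,
  not 13.79%); the package always reports the value computed from its own
  unrounded means.

## The synthetic study and its limits

`run_study` programs an aligned-vs-random contrast into every stage using
values representative of breast-epithelial cells on electrospun
polycaprolactone mats: free-NADH amplitude fraction 0.66 vs 0.69 (per-cell
sd 0.01), per-cell ORR 0.31 vs 0.27 (sd 0.015), vimentin mean ratio 1.13
(per-cell sd 5%), nuclear aspect 2.5 vs 3.5 at constant nuclear area
(rasterized circularity ~0.75 vs ~0.59), glucose-analog ratio 1.3, fiber
laws uniform vs wrapped-normal kappa = 8.5 (`S_true = e^{-2/kappa} ~ 0.79`),
and qPCR folds VIM 1.5, CDH1 0.8, SNAI1 1.86, CD44 8.48, MMP2 2.25 (Ct
noise sd 0.1).  Ten cells per condition; tests follow the per-metric
conventions (KS for the imaging metrics, t-tests for intensities and
morphometry).  Problem sizes (128–512 px fields, one field per condition)
keep the full study under ten seconds while leaving every estimator in its
intended operating regime.

What passing does **not** show: the generator renders hard-edged disk
cells and ideal straight fibers with no point-spread function, no
photobleaching or motion, no spectral bleed-through (notably FMN into the
FAD channel), no 3D structure, and cell-to-cell variability that is purely
Gaussian in the programmed parameter.  Segmentation and recovery scores on
these scenes are upper bounds on real-data performance; the analytic
identities (phasor algebra, ORR boundary values, ddCt arithmetic,
circularity closed forms) transfer exactly.

## Degenerate inputs and tie-breaks

Empty histograms, constant images, empty foregrounds, missing baselines or
housekeeping genes, and zero-width fibers raise errors naming the offending
input.  Overlapping generated cells resolve by nearest center with a
warning.  Watershed/propagation ties at equidistant boundaries follow
heap order deterministically for a fixed input.  All generators are
seeded `numpy.random.default_rng` streams: identical spec + seed gives
bit-identical output.
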