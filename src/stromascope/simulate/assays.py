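"""Synthetic qPCR Ct tables and tensile stress-strain records."""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["simulate_ct_table", "simulate_stress_strain"]

# plausible baseline cycle-threshold levels per gene class
_HOUSEKEEPING_CT = 18.0
_TARGET_CT = 25.0


def simulate_ct_table(
    genes: Sequence[str],
    conditions: Sequence[str],
    true_fold_changes: Mapping,
    ct_noise_sd: float = 0.0,
    seed: Optional[int] = None,
    housekeeping_gene: str = "ACTB",
    baseline_condition: Optional[str] = None,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Simulate replicate Ct values with programmed fold changes.

    ``true_fold_changes`` maps ``(gene, condition)`` (or nested
    ``{gene: {condition: fold}}``) to the expression fold relative to the
    baseline condition (first condition by default).  Target Ct values are
    shifted by ``-log2(fold)`` so the expected delta-delta-Ct is exactly
    ``-log2(fold)`` and the 2^-ddCt method recovers the programmed fold.

    Returns a long-format table with columns ``sample, condition, gene, ct``.
    """
    genes = list(genes)
    conditions = list(conditions)
    if housekeeping_gene not in genes:
        raise ValueError(f"housekeeping gene {housekeeping_gene!r} missing from genes")
    if baseline_condition is None:
        baseline_condition = conditions[0]
    if baseline_condition not in conditions:
        raise ValueError(f"baseline condition {baseline_condition!r} not in conditions")

    def fold(gene: str, condition: str) -> float:
        if condition == baseline_condition:
            return 1.0
        fc = true_fold_changes
        if gene in fc and isinstance(fc[gene], Mapping):
            value = fc[gene].get(condition, 1.0)
        else:
            value = fc.get((gene, condition), 1.0)
        if value <= 0:
            raise ValueError("fold changes must be > 0")
        return float(value)

    rng = np.random.default_rng(seed)
    rows = []
    for condition in conditions:
        for rep in range(1, n_replicates + 1):
            sample = f"{condition}_{rep}"
            for gene in genes:
                base = _HOUSEKEEPING_CT if gene == housekeeping_gene else _TARGET_CT
                ct = base - np.log2(fold(gene, condition))
                if ct_noise_sd > 0:
                    ct += rng.normal(0.0, ct_noise_sd)
                rows.append(
                    {"sample": sample, "condition": condition, "gene": gene,
                     "ct": float(ct)}
                )
    return pd.DataFrame(rows)


def simulate_stress_strain(
    modulus_mpa: float,
    max_strain: float = 0.4,
    n_points: int = 200,
    yield_strain: Optional[float] = None,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate a tensile record: linear elastic segment, optional plateau.

    Stress (MPa) rises with slope ``modulus_mpa`` up to ``yield_strain``
    (no plateau if None), then stays constant; Gaussian noise is additive on
    stress.  Returns a table with columns ``strain, stress_mpa``.
    """
    if modulus_mpa <= 0:
        raise ValueError("modulus_mpa must be positive")
    if n_points < 2 or max_strain <= 0:
        raise ValueError("need a non-degenerate strain range (n_points >= 2)")
    strain = np.linspace(0.0, max_strain, n_points)
    if yield_strain is not None:
        stress = modulus_mpa * np.minimum(strain, yield_strain)
    else:
        stress = modulus_mpa * strain
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stress = stress + rng.normal(0.0, noise_sd, stress.shape)
    return pd.DataFrame({"strain": strain, "stress_mpa": stress})
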