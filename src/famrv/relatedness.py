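"""Genotype-based relatedness matrices (GRM and IBS).

The GRM is the centered, frequency-scaled estimator

    A_jk = (1/M_jk) * sum_m (x_jm - 2 p_m)(x_km - 2 p_m) / (2 p_m (1 - p_m))

with pairwise-complete denominators M_jk counting variants where both
subjects are typed; missing dosages contribute nothing. The IBS matrix is
the mean allelic agreement (2 - |x_j - x_k|)/2 over jointly typed variants.
"""

from __future__ import annotations

import numpy as np

from .datatypes import GenotypeMatrix, RelMatrix


def _alt_freq(dosage: np.ndarray) -> np.ndarray:
    """Per-variant frequency of the counted allele over typed subjects."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(dosage, axis=0) / 2.0


def grm(genotypes: GenotypeMatrix, maf_min: float = 0.05,
        freqs: np.ndarray | None = None) -> RelMatrix:
    """Genetic relationship matrix from variants with MAF > ``maf_min``.

    ``freqs`` may supply externally estimated counted-allele frequencies
    (e.g. founder-preferring ones from :mod:`famrv.qc`); by default sample
    frequencies over all typed subjects are used.
    """
    X = genotypes.dosage
    p = _alt_freq(X) if freqs is None else np.asarray(freqs, dtype=float)
    maf = np.minimum(p, 1.0 - p)
    use = np.isfinite(maf) & (maf > maf_min)
    if not use.any():
        raise ValueError(f"no variants with MAF > {maf_min} available for the GRM")
    Xu = X[:, use]
    pu = p[use]
    denom = 2.0 * pu * (1.0 - pu)
    Z = (Xu - 2.0 * pu) / np.sqrt(denom)
    obs = np.isfinite(Z).astype(float)
    Z = np.nan_to_num(Z)
    npair = obs @ obs.T
    with np.errstate(invalid="ignore", divide="ignore"):
        A = (Z @ Z.T) / npair
    A[npair == 0] = np.nan
    A = (A + A.T) / 2.0
    return RelMatrix(A, "GRM", list(genotypes.subject_order))


def ibs_matrix(genotypes: GenotypeMatrix) -> RelMatrix:
    """Identity-by-state matrix; entries NaN when a pair shares no typed
    variant, diagonal 1 for subjects with any typed variant."""
    X = genotypes.dosage
    obs = np.isfinite(X).astype(float)
    # |x_j - x_k| has no bilinear expansion, so accumulate the pairwise
    # sum per dosage-level combination via indicator matrix products
    levels = [0.0, 1.0, 2.0]
    ind = [((X == lv) & np.isfinite(X)).astype(float) for lv in levels]
    absdiff = np.zeros((X.shape[0], X.shape[0]))
    for a, ia in zip(levels, ind):
        for b, ib in zip(levels, ind):
            if a == b:
                continue
            absdiff += abs(a - b) * (ia @ ib.T)
    npair = obs @ obs.T
    with np.errstate(invalid="ignore", divide="ignore"):
        S = (2.0 * npair - absdiff) / (2.0 * npair)
    S[npair == 0] = np.nan
    S = (S + S.T) / 2.0
    return RelMatrix(S, "IBS", list(genotypes.subject_order))
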