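"""Family-based expected-dosage imputation.

Within a family, dosages at a variant with counted-allele frequency p are
modelled as jointly Gaussian with mean 2p and covariance

    Sigma = 2 * Phi * 2 p (1 - p)

where Phi is the family's kinship block. Missing entries are replaced by
the best linear (BLUP-type) conditional expectation

    g_M = 2p + Sigma_MO Sigma_OO^{-1} (g_O - 2p)

clipped to [0, 2]; a subject with no typed relatives gets the
unconditional mean 2p. This linear form is exact for the first two moments
of Mendelian transmission and scales to large pedigrees; exact peeling
over genotype configurations is a documented extension, not implemented.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import GenotypeMatrix, RelMatrix, check_aligned
from .pedigree import Pedigree, kinship_matrix

_RIDGE = 1e-8


def _condition_family(block: np.ndarray, dos: np.ndarray, p: float) -> np.ndarray:
    """Fill NaNs of one family's dosage vector at one variant."""
    out = dos.copy()
    miss = np.isnan(dos)
    if not miss.any():
        return out
    mu = 2.0 * p
    if p <= 0.0 or p >= 1.0:
        out[miss] = np.clip(mu, 0.0, 2.0)
        return out
    obs = ~miss
    if not obs.any():
        out[miss] = mu
        return out
    var = 2.0 * p * (1.0 - p)
    s_oo = block[np.ix_(obs, obs)] * var
    s_mo = block[np.ix_(miss, obs)] * var
    try:
        sol = np.linalg.solve(s_oo, dos[obs] - mu)
    except np.linalg.LinAlgError:
        warnings.warn("singular observed-covariance block; ridge added")
        sol = np.linalg.solve(s_oo + _RIDGE * np.eye(s_oo.shape[0]), dos[obs] - mu)
    out[miss] = np.clip(mu + s_mo @ sol, 0.0, 2.0)
    return out


def impute_family(genotypes: GenotypeMatrix, kcm: RelMatrix,
                  freqs: np.ndarray) -> GenotypeMatrix:
    """Replace missing dosages by family-conditional expected dosages.

    ``kcm`` must be a kinship matrix aligned to ``genotypes``; ``freqs``
    gives the per-variant counted-allele frequency p (NaN frequencies leave
    the variant untouched). Output dosages may be fractional.
    """
    if kcm.kind != "KCM":
        raise ValueError("family imputation needs a pedigree kinship matrix")
    check_aligned(genotypes.subject_order, kcm.subject_order)
    kernel = kcm.kernel  # 2*Phi
    X = genotypes.dosage.copy()
    fam_of = [k[0] for k in genotypes.subject_order]
    fams: dict[str, list[int]] = {}
    for i, f in enumerate(fam_of):
        fams.setdefault(f, []).append(i)
    for j in range(genotypes.n_variants):
        p = freqs[j]
        col = X[:, j]
        if not np.isnan(col).any() or not np.isfinite(p):
            continue
        for rows in fams.values():
            rows_a = np.asarray(rows)
            sub = col[rows_a]
            if not np.isnan(sub).any():
                continue
            block = kernel[np.ix_(rows_a, rows_a)]
            col[rows_a] = _condition_family(block, sub, float(p))
        X[:, j] = col
    return GenotypeMatrix(X, list(genotypes.subject_order), list(genotypes.variant_order))


def expected_dosage_untyped(pedigree: Pedigree, genotypes: GenotypeMatrix,
                            subject: tuple[str, str],
                            freqs: np.ndarray) -> np.ndarray:
    """Expected per-variant dosage of a pedigree member absent from the
    genotype matrix, conditioning on the typed members of its family."""
    keys = set(r.key for r in pedigree.records)
    if subject not in keys:
        raise ValueError(f"subject {subject} not in pedigree")
    fam = subject[0]
    fam_keys = [k for k in pedigree.topo_order if k[0] == fam]
    kcm = kinship_matrix(pedigree, subject_order=fam_keys)
    kernel = kcm.kernel
    gidx = genotypes.subject_index()
    if subject in gidx:
        raise ValueError(f"subject {subject} is already genotyped")
    pos = {k: i for i, k in enumerate(fam_keys)}
    si = pos[subject]
    out = np.empty(genotypes.n_variants)
    dos = np.full(len(fam_keys), np.nan)
    for j in range(genotypes.n_variants):
        dos[:] = np.nan
        for k, i in pos.items():
            if k in gidx:
                dos[i] = genotypes.dosage[gidx[k], j]
        p = freqs[j]
        if not np.isfinite(p):
            out[j] = np.nan
            continue
        filled = _condition_family(kernel, dos, float(p))
        out[j] = filled[si]
    return out


def impute_for_analysis(genotypes: GenotypeMatrix, freqs: np.ndarray,
                        kcm: RelMatrix | None = None) -> GenotypeMatrix:
    """Missing-dosage policy of the association tests: family-conditional
    expectation when a kinship matrix is available, else the unconditional
    mean 2p."""
    if kcm is not None:
        return impute_family(genotypes, kcm, freqs)
    X = genotypes.dosage.copy()
    for j in range(genotypes.n_variants):
        miss = np.isnan(X[:, j])
        if miss.any() and np.isfinite(freqs[j]):
            X[miss, j] = 2.0 * freqs[j]
    return GenotypeMatrix(X, list(genotypes.subject_order), list(genotypes.variant_order))


__all__ = ["impute_family", "expected_dosage_untyped", "impute_for_analysis"]
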