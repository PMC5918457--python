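"""Variant- and subject-level quality statistics and the filtering engine.

Allele-frequency conventions: relatives are not exchangeable draws from the
population, so frequency and Hardy-Weinberg statistics prefer founders.
A variant's frequency comes from founder subjects when at least 30 founder
alleles are typed there, and from all subjects otherwise; the exact HWE
test uses founder genotype counts only. The minor allele count (MAC) is
always over all typed subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import GenotypeMatrix, VariantRecord
from .pedigree import Pedigree, mendelian_errors

#: minimum typed founder alleles before falling back to all subjects
FOUNDER_ALLELE_MIN = 30


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def allele_freq(genotypes: GenotypeMatrix, pedigree: Pedigree | None = None,
                min_founder_alleles: int = FOUNDER_ALLELE_MIN) -> np.ndarray:
    """Per-variant frequency of the counted allele, founder-preferring.

    Returns NaN for all-missing variants.
    """
    X = genotypes.dosage
    typed = np.isfinite(X).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p_all = np.where(typed > 0, np.nansum(X, axis=0) / np.maximum(2 * typed, 1), np.nan)
    if pedigree is None:
        return p_all
    fmask = np.array([k in pedigree.founders for k in genotypes.subject_order])
    if not fmask.any():
        return p_all
    Xf = X[fmask]
    typed_alleles = 2 * np.sum(np.isfinite(Xf), axis=0)
    with np.errstate(invalid="ignore"):
        p_f = np.where(typed_alleles > 0, np.nansum(Xf, axis=0) / np.maximum(typed_alleles, 1), np.nan)
    return np.where(typed_alleles >= min_founder_alleles, p_f, p_all)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test conditional on allele counts.

    Sums the conditional probabilities of every heterozygote count with the
    same parity and allele totals whose probability does not exceed that of
    the observed count. Returns 1.0 when no genotypes were observed or the
    site is monomorphic.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    hets, logp = _hwe_logprobs(n, n_rare)
    logp_obs = logp[hets == n_het][0]
    p = float(np.exp(logp[logp <= logp_obs + 1e-12]).sum())
    return min(p, 1.0)


def _hwe_logprobs(n: int, n_rare: int):
    from scipy.special import gammaln

    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1) - gammaln(hom_r + 1) - gammaln(hets + 1) - gammaln(hom_c + 1)
        + gammaln(n_rare + 1) + gammaln(2 * n - n_rare + 1) - gammaln(2 * n + 1)
    )
    return hets, logp


@dataclass
class VariantQC:
    """Per-variant quality statistics (see module docstring for conventions)."""

    vid: str
    maf: float
    mac: int
    call_rate: float
    hwe_p: float
    mendel_rate: float


@dataclass
class SubjectQC:
    fid: str
    iid: str
    call_rate: float
    mendel_rate: float
    het_hom_ratio: float
    inbreeding_f: float


def variant_stats(genotypes: GenotypeMatrix, pedigree: Pedigree | None = None,
                  check_duos: bool = True) -> list[VariantQC]:
    """MAF/MAC/call-rate/HWE/Mendel statistics for every variant."""
    X = genotypes.dosage
    n = genotypes.n_subjects
    typed = np.isfinite(X)
    call_rate = typed.sum(axis=0) / max(n, 1)
    p = allele_freq(genotypes, pedigree)
    maf = np.minimum(p, 1.0 - p)
    # MAC over all typed subjects, in the minor orientation of p over all
    with np.errstate(invalid="ignore"):
        counted = np.nansum(X, axis=0)
        total = 2.0 * typed.sum(axis=0)
        p_all = np.where(total > 0, counted / np.maximum(total, 1), np.nan)
    mac = np.where(p_all <= 0.5, counted, total - counted)

    if pedigree is not None:
        fmask = np.array([k in pedigree.founders for k in genotypes.subject_order])
        if not fmask.any():
            fmask = np.ones(n, dtype=bool)
    else:
        fmask = np.ones(n, dtype=bool)
    Xf = X[fmask]

    if pedigree is not None:
        mendel, _, _ = mendelian_errors(pedigree, genotypes, check_duos=check_duos)
    else:
        mendel = np.full(genotypes.n_variants, np.nan)

    out = []
    for j, v in enumerate(genotypes.variant_order):
        col = Xf[:, j]
        col = col[np.isfinite(col)]
        hwe = hwe_exact(int(np.sum(col == 0)), int(np.sum(col == 1)), int(np.sum(col == 2)))
        out.append(VariantQC(
            vid=v.vid,
            maf=float(maf[j]) if np.isfinite(maf[j]) else np.nan,
            mac=int(mac[j]) if np.isfinite(mac[j]) else 0,
            call_rate=float(call_rate[j]),
            hwe_p=hwe,
            mendel_rate=float(mendel[j]) if np.isfinite(mendel[j]) else np.nan,
        ))
    return out


def subject_stats(genotypes: GenotypeMatrix, pedigree: Pedigree | None = None,
                  freqs: np.ndarray | None = None) -> list[SubjectQC]:
    X = genotypes.dosage
    m = genotypes.n_variants
    typed = np.isfinite(X)
    call_rate = typed.sum(axis=1) / max(m, 1)
    het = np.nansum(X == 1, axis=1)
    hom_alt = np.nansum(X == 2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_hom = np.where(hom_alt > 0, het / np.maximum(hom_alt, 1), np.nan)
    if pedigree is not None:
        _, sub_mendel, _ = mendelian_errors(pedigree, genotypes)
    else:
        sub_mendel = np.full(genotypes.n_subjects, np.nan)
    p = allele_freq(genotypes, pedigree) if freqs is None else freqs
    out = []
    for i, (fid, iid) in enumerate(genotypes.subject_order):
        out.append(SubjectQC(
            fid=fid, iid=iid,
            call_rate=float(call_rate[i]),
            mendel_rate=float(sub_mendel[i]) if np.isfinite(sub_mendel[i]) else np.nan,
            het_hom_ratio=float(het_hom[i]) if np.isfinite(het_hom[i]) else np.nan,
            inbreeding_f=inbreeding_coefficient(X[i], p),
        ))
    return out


def tstv_ratio(variant_records: list[VariantRecord], mask=None) -> float:
    """Transition/transversion ratio over masked-in SNVs (inf if no Tv)."""
    if mask is None:
        mask = [True] * len(variant_records)
    ts = tv = 0
    for v, keep in zip(variant_records, mask):
        if not keep or not v.is_snv:
            continue
        if v.is_transition:
            ts += 1
        else:
            tv += 1
    if tv == 0:
        return float("inf") if ts > 0 else float("nan")
    return ts / tv


def inbreeding_coefficient(dosages: np.ndarray, freqs: np.ndarray) -> float:
    """F = 1 - observed/expected heterozygosity for one subject.

    Expected heterozygosity sums 2 p (1-p) over the subject's typed
    polymorphic variants. Returns NaN when that expectation is zero.
    """
    d = np.asarray(dosages, dtype=float)
    p = np.asarray(freqs, dtype=float)
    use = np.isfinite(d) & np.isfinite(p) & (p > 0) & (p < 1)
    if not use.any():
        return float("nan")
    e_het = float(np.sum(2.0 * p[use] * (1.0 - p[use])))
    if e_het <= 0:
        return float("nan")
    o_het = float(np.sum(d[use] == 1))
    return 1.0 - o_het / e_het


def fixation_index(genotypes: GenotypeMatrix, population_labels):
    """Weir-Cockerham two-level Fst per variant and the ratio-of-sums
    genome-wide estimate.

    Returns ``(per_variant_fst, genome_wide)``; variants where the
    denominator vanishes get NaN per-variant but still enter the sums.
    """
    labels = np.asarray(population_labels)
    pops = np.unique(labels)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    X = genotypes.dosage
    m = genotypes.n_variants
    r = len(pops)
    a_sum = np.zeros(m)
    b_sum = np.zeros(m)
    c_sum = np.zeros(m)
    n_i = np.zeros((r, m))
    p_i = np.zeros((r, m))
    h_i = np.zeros((r, m))
    for k, pop in enumerate(pops):
        Xp = X[labels == pop]
        typed = np.isfinite(Xp)
        n_i[k] = typed.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.nansum(Xp, axis=0) / np.maximum(2 * n_i[k], 1)
            h_i[k] = np.nansum(Xp == 1, axis=0) / np.maximum(n_i[k], 1)
    nbar = n_i.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n_i ** 2).sum(axis=0) / np.maximum(r * nbar, 1e-300)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / np.maximum(r * nbar, 1e-300)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / np.maximum((r - 1) * nbar, 1e-300)
        hbar = (n_i * h_i).sum(axis=0) / np.maximum(r * nbar, 1e-300)
        a = (nbar / np.maximum(nc, 1e-300)) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / np.maximum(nbar - 1, 1e-300)
        )
        b = (nbar / np.maximum(nbar - 1, 1e-300)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4.0 * nbar)
        )
        c = hbar / 2.0
    a_sum, b_sum, c_sum = a, b, c
    denom = a_sum + b_sum + c_sum
    with np.errstate(invalid="ignore", divide="ignore"):
        per_variant = np.where(np.abs(denom) > 1e-300, a_sum / denom, np.nan)
    usable = np.isfinite(denom) & (np.abs(denom) > 0)
    genome = float(np.nansum(a_sum[usable]) / np.nansum(denom[usable])) if usable.any() else float("nan")
    return per_variant, genome


# ---------------------------------------------------------------------------
# Filtering engine
# ---------------------------------------------------------------------------

@dataclass
class QCThresholds:
    """Default thresholds; set any field to None to disable that rule.

    Variants are removed when HWE p < ``hwe_p_min``, call rate <
    ``variant_call_rate_min`` or Mendel error rate > ``variant_mendel_max``;
    subjects are removed when call rate < ``subject_call_rate_min`` or
    Mendel error rate > ``subject_mendel_max``. Optional MAF/MAC floors are
    off by default.
    """

    hwe_p_min: float | None = 1e-8
    variant_call_rate_min: float | None = 0.95
    variant_mendel_max: float | None = 0.01
    subject_call_rate_min: float | None = 0.95
    subject_mendel_max: float | None = 0.01
    maf_min: float | None = None
    mac_min: int | None = None


@dataclass
class FilterReport:
    removed_subjects: dict[str, int] = field(default_factory=dict)
    removed_variants: dict[str, int] = field(default_factory=dict)
    n_subjects_before: int = 0
    n_subjects_after: int = 0
    n_variants_before: int = 0
    n_variants_after: int = 0

    def summary(self) -> str:
        lines = [
            f"subjects: {self.n_subjects_before} -> {self.n_subjects_after}",
            *(f"  removed by {k}: {v}" for k, v in self.removed_subjects.items()),
            f"variants: {self.n_variants_before} -> {self.n_variants_after}",
            *(f"  removed by {k}: {v}" for k, v in self.removed_variants.items()),
        ]
        return "\n".join(lines)


def apply_filters(genotypes: GenotypeMatrix, pedigree: Pedigree | None = None,
                  thresholds: QCThresholds | None = None):
    """Subject filters first, then variant statistics are recomputed on the
    surviving subjects and variant filters applied. Returns
    ``(filtered GenotypeMatrix, FilterReport)``."""
    th = thresholds or QCThresholds()
    rep = FilterReport(
        n_subjects_before=genotypes.n_subjects,
        n_variants_before=genotypes.n_variants,
    )
    sstats = subject_stats(genotypes, pedigree)
    keep_s = np.ones(genotypes.n_subjects, dtype=bool)
    if th.subject_call_rate_min is not None:
        bad = np.array([s.call_rate < th.subject_call_rate_min for s in sstats])
        rep.removed_subjects["call_rate"] = int((bad & keep_s).sum())
        keep_s &= ~bad
    if th.subject_mendel_max is not None:
        bad = np.array([
            np.isfinite(s.mendel_rate) and s.mendel_rate > th.subject_mendel_max
            for s in sstats
        ])
        rep.removed_subjects["mendel_rate"] = int((bad & keep_s).sum())
        keep_s &= ~bad
    if not keep_s.any():
        raise ValueError("subject-level QC removed every subject")
    g = genotypes.subset_subjects(
        [k for k, keep in zip(genotypes.subject_order, keep_s) if keep]
    )

    vstats = variant_stats(g, pedigree)
    keep_v = np.ones(g.n_variants, dtype=bool)
    rules = []
    if th.variant_call_rate_min is not None:
        rules.append(("call_rate", np.array([v.call_rate < th.variant_call_rate_min for v in vstats])))
    if th.hwe_p_min is not None:
        rules.append(("hwe", np.array([v.hwe_p < th.hwe_p_min for v in vstats])))
    if th.variant_mendel_max is not None:
        rules.append(("mendel_rate", np.array([
            np.isfinite(v.mendel_rate) and v.mendel_rate > th.variant_mendel_max
            for v in vstats
        ])))
    if th.maf_min is not None:
        rules.append(("maf", np.array([
            not np.isfinite(v.maf) or v.maf < th.maf_min for v in vstats
        ])))
    if th.mac_min is not None:
        rules.append(("mac", np.array([v.mac < th.mac_min for v in vstats])))
    for name, bad in rules:
        rep.removed_variants[name] = int((bad & keep_v).sum())
        keep_v &= ~bad
    g = g.subset_variants(np.flatnonzero(keep_v))
    rep.n_subjects_after = g.n_subjects
    rep.n_variants_after = g.n_variants
    return g, rep
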