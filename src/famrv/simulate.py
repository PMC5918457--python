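"""Gene-dropping pedigree simulator for calibration and power studies.

Founder haplotype alleles are Bernoulli(p) per variant, offspring inherit
one uniformly chosen allele from each parent independently across variants
(linkage equilibrium). Phenotypes follow

    Y = X beta + sum_causal gamma_j g_j + u + e,
    u ~ N(0, sigma_g^2 * 2 KCM),  e ~ N(0, sigma_e^2 I),

with heritability h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2) conditional on
the fixed effects. The null model sets all gamma to zero. Per-replicate
randomness derives from the master seed by a counter scheme
(``SeedSequence((seed, stream, counter))``), so every experiment is
reproducible piecewise and independent of scheduling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import GeneSet, GenotypeMatrix, PedigreeRecord, PhenotypeFrame, RelMatrix
from .genetests import TestConfig, burden_test, skat_test, skato_test, vt_test
from .nullmodel import FamilyNullModel, KernelEigen, score_block
from .pedigree import Pedigree, build_pedigree, kinship_matrix
from .qc import allele_freq

# (iid, father, mother, sex); "0" = founder parent
PEDIGREE_TEMPLATES: dict[str, list[tuple[str, str, str, int]]] = {
    "trio": [
        ("1", "0", "0", 1), ("2", "0", "0", 2), ("3", "1", "2", 1),
    ],
    # three generations, 8 members: grandparent couple, two of their
    # children, two marry-ins, one grandchild per branch (4 founders)
    "gen3_8": [
        ("1", "0", "0", 1), ("2", "0", "0", 2),
        ("3", "1", "2", 1), ("4", "0", "0", 2),
        ("5", "1", "2", 2), ("6", "0", "0", 1),
        ("7", "3", "4", 1), ("8", "6", "5", 2),
    ],
    # three generations, 16 members: grandparent couple, three children
    # with marry-ins, eight grandchildren (5 founders)
    "gen3_16": [
        ("1", "0", "0", 1), ("2", "0", "0", 2),
        ("3", "1", "2", 1), ("4", "0", "0", 2),
        ("5", "1", "2", 1), ("6", "0", "0", 2),
        ("7", "1", "2", 2), ("8", "0", "0", 1),
        ("9", "3", "4", 1), ("10", "3", "4", 2), ("11", "3", "4", 1),
        ("12", "5", "6", 2), ("13", "5", "6", 1),
        ("14", "8", "7", 2), ("15", "8", "7", 1), ("16", "8", "7", 2),
    ],
}


def make_pedigree(template: str = "gen3_8", n_families: int = 50) -> Pedigree:
    """Replicate a built-in pedigree template across families F1..Fn."""
    if template not in PEDIGREE_TEMPLATES:
        raise ValueError(f"unknown template {template!r}; "
                         f"choose from {sorted(PEDIGREE_TEMPLATES)}")
    rows = PEDIGREE_TEMPLATES[template]
    records = [
        PedigreeRecord(f"F{f + 1}", iid, fa, mo, sex, 0)
        for f in range(n_families)
        for iid, fa, mo, sex in rows
    ]
    return build_pedigree(records)


@dataclass
class SimSpec:
    """Study conditions of a simulation experiment."""

    template: str = "gen3_8"
    n_families: int = 50
    n_genes: int = 200
    variants_per_gene: int = 8
    #: founder-MAF distribution: rare variants Uniform(0.001, 0.05);
    #: a ``common_fraction`` of extra variants Uniform(0.05, 0.5) can be
    #: appended for GRM construction
    maf_rare: tuple[float, float] = (0.001, 0.05)
    maf_common: tuple[float, float] = (0.05, 0.5)
    n_common_variants: int = 0
    h2: float = 0.3
    n_covariates: int = 0
    beta_cov: float = 0.0
    #: causal model: number of causal genes, per-gene fraction of phenotype
    #: variance explained, and fraction of causal variants protective
    n_causal_genes: int = 0
    effect_variance: float = 0.0
    protective_fraction: float = 0.0
    n_replicates: int = 200
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.h2 < 1.0:
            raise ValueError("h2 must be in [0, 1)")
        if self.effect_variance < 0 or not np.isfinite(self.effect_variance):
            raise ValueError("effect variance must be finite and >= 0")


def _stream(seed: int, *counters: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(c) for c in counters)))


def gene_drop(pedigree: Pedigree, founder_mafs: np.ndarray,
              seed: int | np.random.Generator = 0) -> GenotypeMatrix:
    """Drop founder alleles through the pedigree; returns dosages of the
    simulated minor allele in the pedigree's record order."""
    rng = seed if isinstance(seed, np.random.Generator) else _stream(seed, 0)
    p = np.asarray(founder_mafs, dtype=float)
    m = p.size
    haps: dict[tuple[str, str], np.ndarray] = {}
    for key in pedigree.topo_order:
        fa, mo = pedigree.parents(key)
        if fa is None and mo is None:
            haps[key] = (rng.random((2, m)) < p).astype(np.int8)
        else:
            pa = haps[fa]
            ma = haps[mo]
            pick_f = rng.integers(0, 2, m)
            pick_m = rng.integers(0, 2, m)
            haps[key] = np.stack([
                pa[pick_f, np.arange(m)],
                ma[pick_m, np.arange(m)],
            ])
    keys = [r.key for r in pedigree.records]
    dosage = np.array([haps[k].sum(axis=0) for k in keys], dtype=float)
    from .datatypes import VariantRecord
    variants = [VariantRecord("1", j + 1, f"v{j + 1}", "A", "G") for j in range(m)]
    return GenotypeMatrix(dosage, keys, variants)


def simulate_phenotype(pedigree: Pedigree, kcm: RelMatrix, spec: SimSpec,
                       genotypes: GenotypeMatrix | None = None,
                       causal: list[tuple[int, float]] | None = None,
                       seed: int | np.random.Generator = 0) -> PhenotypeFrame:
    """One phenotype replicate under the given simulation conditions.

    ``causal`` lists (variant column, effect size gamma); monomorphic
    causal variants contribute nothing (and a gene-drop realization where
    that happens should be resampled by the caller).
    """
    rng = seed if isinstance(seed, np.random.Generator) else _stream(seed, 1)
    keys = list(kcm.subject_order)
    n = len(keys)
    sigma_g = np.sqrt(spec.h2)
    sigma_e = np.sqrt(1.0 - spec.h2)
    y = np.zeros(n)
    # polygenic term, family by family
    kernel = kcm.kernel
    fams: dict[str, list[int]] = {}
    for i, k in enumerate(keys):
        fams.setdefault(k[0], []).append(i)
    if spec.h2 > 0:
        for rows in fams.values():
            rows_a = np.asarray(rows)
            block = kernel[np.ix_(rows_a, rows_a)]
            L = np.linalg.cholesky(block + 1e-10 * np.eye(len(rows_a)))
            y[rows_a] += sigma_g * (L @ rng.standard_normal(len(rows_a)))
    y += sigma_e * rng.standard_normal(n)
    cov = np.empty((n, 0))
    names: list[str] = []
    if spec.n_covariates > 0:
        cov = rng.standard_normal((n, spec.n_covariates))
        y += cov @ np.full(spec.n_covariates, spec.beta_cov)
        names = [f"cov{i + 1}" for i in range(spec.n_covariates)]
    if causal:
        if genotypes is None:
            raise ValueError("causal effects need the genotype matrix")
        gidx = genotypes.subject_index()
        rows = np.array([gidx[k] for k in keys])
        for j, gamma in causal:
            g = np.nan_to_num(genotypes.dosage[rows, j])
            y += gamma * g
    return PhenotypeFrame(keys, y, "Q1", cov, names, "continuous")


# ---------------------------------------------------------------------------
# Study assembly
# ---------------------------------------------------------------------------

@dataclass
class Study:
    """A simulated dataset plus the cached pieces the tests need."""

    pedigree: Pedigree
    kcm: RelMatrix
    keig: KernelEigen
    genotypes: GenotypeMatrix
    geneset: GeneSet
    founder_mafs: np.ndarray
    freqs: np.ndarray
    mafs: np.ndarray
    gene_cols: dict[str, np.ndarray]
    causal_effects: dict[str, list[tuple[int, float]]]
    _rotated: np.ndarray | None = None

    @property
    def rotated_dosage(self) -> np.ndarray:
        """U^T-rotated dosage matrix, computed once per study."""
        if self._rotated is None:
            self._rotated = self.keig.U.T @ np.nan_to_num(self.genotypes.dosage)
        return self._rotated


def build_study(spec: SimSpec, config: TestConfig | None = None) -> Study:
    """Gene-drop one genotype panel and precompute per-gene structures.

    Genes failing the inclusion rule (fewer than two polymorphic rare
    variants or aggregate MAC below the floor) are excluded here, mirroring
    how fixed genotypes are screened once before replicated phenotypes.
    """
    cfg = config or TestConfig()
    ped = make_pedigree(spec.template, spec.n_families)
    kcm = kinship_matrix(ped)
    keig = KernelEigen(kcm)
    rng = _stream(spec.seed, 0)
    n_rare = spec.n_genes * spec.variants_per_gene
    mafs_rare = rng.uniform(*spec.maf_rare, n_rare)
    mafs_common = rng.uniform(*spec.maf_common, spec.n_common_variants)
    founder_mafs = np.concatenate([mafs_rare, mafs_common])
    geno = gene_drop(ped, founder_mafs, rng)
    freqs = allele_freq(geno, ped)
    mafs = np.minimum(freqs, 1.0 - freqs)

    typed = np.isfinite(geno.dosage)
    counted = np.nansum(geno.dosage, axis=0)
    total = 2.0 * typed.sum(axis=0)
    mac = np.where(freqs <= 0.5, counted, total - counted)

    genes: dict[str, list[int]] = {}
    gene_cols: dict[str, np.ndarray] = {}
    for g in range(spec.n_genes):
        cols = np.arange(g * spec.variants_per_gene, (g + 1) * spec.variants_per_gene)
        keep = cols[(mafs[cols] > 0) & (mafs[cols] <= cfg.rare_maf_max)]
        if len(keep) < cfg.min_variants or mac[keep].sum() < cfg.min_mac:
            continue
        name = f"gene{g + 1}"
        genes[name] = list(keep)
        gene_cols[name] = keep

    causal_effects: dict[str, list[tuple[int, float]]] = {}
    if spec.n_causal_genes > 0 and spec.effect_variance > 0:
        crng = _stream(spec.seed, 2)
        names = sorted(gene_cols, key=lambda s: int(s.removeprefix("gene")))
        for name in names[: spec.n_causal_genes]:
            cols = gene_cols[name]
            direction = np.ones(len(cols))
            n_prot = int(round(spec.protective_fraction * len(cols)))
            if n_prot:
                prot_ix = crng.choice(len(cols), n_prot, replace=False)
                direction[prot_ix] = -1.0
            score = (geno.dosage[:, cols] * direction).sum(axis=1)
            v = float(np.var(score))
            scale = np.sqrt(spec.effect_variance / v) if v > 0 else 0.0
            causal_effects[name] = [(int(c), float(scale * d))
                                    for c, d in zip(cols, direction)]
    return Study(ped, kcm, keig, geno, GeneSet(genes), founder_mafs,
                 freqs, mafs, gene_cols, causal_effects)


def _scan_pvalues(study: Study, y_frame: PhenotypeFrame, methods,
                  cfg: TestConfig, rep: int) -> dict[str, dict[str, float]]:
    """p-values per gene per method for one phenotype replicate."""
    model = FamilyNullModel(study.keig)
    model.fit(y_frame.phenotype, y_frame.covariates)
    Gt = study.rotated_dosage
    out: dict[str, dict[str, float]] = {m: {} for m in methods}
    for gi, (gene, cols) in enumerate(sorted(study.gene_cols.items())):
        if gene not in study.geneset.genes:
            continue
        gmaf = study.mafs[cols]
        w = cfg.weights(gmaf)
        block = score_block(model, Gt[:, cols], w, rotated=True)
        for m in methods:
            if m == "burden":
                out[m][gene] = burden_test(block).p
            elif m == "skat":
                out[m][gene] = skat_test(block).p
            elif m == "skato":
                out[m][gene] = skato_test(block, cfg.rho_grid).p
            elif m == "vt":
                rng = _stream(cfg.seed, 3, rep, gi)
                out[m][gene] = vt_test(block, gmaf, draws=cfg.vt_draws,
                                       rng=rng, method=cfg.vt_method,
                                       two_sided=cfg.vt_two_sided).p
            else:
                raise ValueError(f"unknown method {m!r}")
    return out


@dataclass
class RateTable:
    """method x alpha table of exceedance rates with binomial SEs."""

    rates: dict[str, dict[float, float]]
    ses: dict[str, dict[float, float]]
    n_tests: int

    def summary(self) -> str:
        methods = list(self.rates)
        alphas = sorted(next(iter(self.rates.values())))
        lines = ["alpha\t" + "\t".join(methods)]
        for a in alphas:
            cells = [f"{self.rates[m][a]:.4f} (+/-{self.ses[m][a]:.4f})" for m in methods]
            lines.append(f"{a}\t" + "\t".join(cells))
        return "\n".join(lines)


def _rate_table(pmat: dict[str, np.ndarray], alphas) -> RateTable:
    rates: dict[str, dict[float, float]] = {}
    ses: dict[str, dict[float, float]] = {}
    n = 0
    for m, ps in pmat.items():
        n = ps.size
        rates[m] = {}
        ses[m] = {}
        for a in alphas:
            pi = float(np.mean(ps < a)) if a > 0 else 0.0
            if a >= 1.0:
                pi = 1.0
            rates[m][a] = pi
            ses[m][a] = float(np.sqrt(pi * (1 - pi) / n)) if n else float("nan")
    return RateTable(rates, ses, n)


def run_calibration(spec: SimSpec, methods=("burden", "skat", "skato", "vt"),
                    alphas=(0.1, 0.05, 0.01),
                    config: TestConfig | None = None) -> RateTable:
    """Empirical type-I error over null (gene, replicate) pairs."""
    if spec.n_causal_genes or spec.effect_variance:
        raise ValueError("calibration spec must have zero causal effects")
    cfg = config or TestConfig(seed=spec.seed)
    study = build_study(spec, cfg)
    n_genes = len(study.geneset)
    if n_genes * spec.n_replicates < 100:
        raise ValueError("fewer than 100 null tests; SE would be too large")
    collect: dict[str, list[float]] = {m: [] for m in methods}
    for rep in range(spec.n_replicates):
        y = simulate_phenotype(study.pedigree, study.kcm, spec,
                               seed=_stream(spec.seed, 1, rep))
        ps = _scan_pvalues(study, y, methods, cfg, rep)
        for m in methods:
            collect[m].extend(ps[m].values())
    pmat = {m: np.asarray(v) for m, v in collect.items()}
    return _rate_table(pmat, alphas)


def run_power(spec: SimSpec, methods=("burden", "skat", "skato", "vt"),
              alphas=(0.05,), config: TestConfig | None = None):
    """Per-causal-gene power plus companion null-gene rates.

    Returns ``(power_tables, null_table)`` where ``power_tables`` maps each
    causal gene to its :class:`RateTable`.
    """
    if spec.n_causal_genes < 1:
        raise ValueError("power spec needs at least one causal gene")
    cfg = config or TestConfig(seed=spec.seed)
    study = build_study(spec, cfg)
    causal_names = sorted(study.causal_effects)
    causal_flat = [eff for name in causal_names for eff in study.causal_effects[name]]
    per_gene: dict[str, dict[str, list[float]]] = {
        name: {m: [] for m in methods} for name in causal_names}
    null_collect: dict[str, list[float]] = {m: [] for m in methods}
    for rep in range(spec.n_replicates):
        y = simulate_phenotype(study.pedigree, study.kcm, spec,
                               genotypes=study.genotypes, causal=causal_flat,
                               seed=_stream(spec.seed, 1, rep))
        ps = _scan_pvalues(study, y, methods, cfg, rep)
        for m in methods:
            for gene, p in ps[m].items():
                if gene in per_gene:
                    per_gene[gene][m].append(p)
                else:
                    null_collect[m].append(p)
    power_tables = {
        name: _rate_table({m: np.asarray(v) for m, v in d.items()}, alphas)
        for name, d in per_gene.items()
    }
    null_table = _rate_table(
        {m: np.asarray(v) for m, v in null_collect.items()}, alphas
    ) if any(null_collect.values()) else None
    return power_tables, null_table
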