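"""Gene-level family-based rare-variant association tests.

Every test is a function of the gene's :class:`~famrv.nullmodel.ScoreBlock`
(S, V), where under the null S ~ N(0, V) asymptotically regardless of the
relatedness structure absorbed into V:

* **burden**:  Q_b = (1'S)^2 / (1'V1), chi-square(1);
* **SKAT**:    Q_s = S'S, mixture of chi-squares with the eigenvalues of V;
* **SKAT-O omnibus**: Q_rho = S'[(1-rho)I + rho J]S over a rho grid, the
  minimum per-rho p-value is calibrated by the one-dimensional integral of
  the shared-factor decomposition (the Lee construction), with a
  Bonferroni fallback when the decomposition degenerates;
* **variable threshold (VT)**: the maximal standardized weighted burden
  over MAF inclusion thresholds, its null being the exact multivariate
  normal of the threshold-score vector (randomized quasi-Monte-Carlo
  draws by default, with a Genz rectangle-probability refinement in the
  far tail; plain Monte-Carlo draws optionally).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, multivariate_normal, norm
from scipy.special import ndtri, roots_legendre

from .datatypes import GeneSet, GenotypeMatrix, PhenotypeFrame, RelMatrix, check_aligned
from .impute import impute_for_analysis
from .nullmodel import FamilyNullModel, KernelEigen, ScoreBlock, WeightSpec, score_block
from .qc import allele_freq
from .quadform import liu_quantile, mixture_chi2_pvalue

DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)


@dataclass(frozen=True)
class TestResult:
    stat: float
    p: float
    flag: str = ""
    extra: dict = field(default_factory=dict)


@dataclass
class TestConfig:
    """Knobs of the gene scan (defaults follow the SKAT-o/VT lineage)."""

    __test__ = False  # not a pytest class, despite the name

    methods: tuple[str, ...] = ("burden", "skat", "skato", "vt")
    rho_grid: tuple[float, ...] = DEFAULT_RHO_GRID
    #: draw count for the plain Monte-Carlo VT null; the default "qmc"
    #: method uses a fixed 8192-point randomized Sobol set instead
    vt_draws: int = 1_000_000
    vt_method: str = "qmc"  # "qmc" | "genz" | "mc"
    vt_two_sided: bool = True
    seed: int = 0
    rare_maf_max: float = 0.05
    min_variants: int = 2
    min_mac: int = 4
    weights: WeightSpec = field(default_factory=WeightSpec)

    def __post_init__(self):
        rg = tuple(float(r) for r in self.rho_grid)
        if any(r < 0 or r > 1 for r in rg):
            raise ValueError("rho grid must lie in [0, 1]")
        if len(rg) >= 2 and not (0.0 in rg and 1.0 in rg):
            raise ValueError("rho grid must contain both endpoints 0 and 1")
        if self.vt_draws < 10_000:
            raise ValueError("vt_draws must be at least 1e4")
        self.rho_grid = rg


# ---------------------------------------------------------------------------
# Core tests
# ---------------------------------------------------------------------------

def burden_test(block: ScoreBlock) -> TestResult:
    """Family-based weighted burden score test (chi-square, 1 df)."""
    s1 = float(block.S.sum())
    v1 = float(block.V.sum())
    if v1 <= 1e-14:
        return TestResult(0.0, 1.0, flag="monomorphic")
    q = s1 * s1 / v1
    return TestResult(q, float(chi2.sf(q, df=1)))


def skat_test(block: ScoreBlock) -> TestResult:
    """Family-based SKAT (variance-component) test."""
    lam = np.linalg.eigvalsh(block.V)
    if lam.max(initial=0.0) <= 1e-14:
        return TestResult(0.0, 1.0, flag="monomorphic")
    q = float(block.S @ block.S)
    return TestResult(q, mixture_chi2_pvalue(lam, q))


def _rho_eigen(V: np.ndarray, sqrtV: np.ndarray, rho: float) -> np.ndarray:
    p = V.shape[0]
    if rho == 0.0:
        K = V
    else:
        u = sqrtV.sum(axis=1)  # V^{1/2} 1
        K = (1.0 - rho) * V + rho * np.outer(u, u)
    return np.linalg.eigvalsh(K)


def skato_test(block: ScoreBlock,
               rho_grid=DEFAULT_RHO_GRID) -> TestResult:
    """SKAT-O style omnibus over the rho-indexed burden/SKAT family.

    Returns the omnibus p with ``extra={"min_p_rho", "rho_min", "p_rho"}``.
    With a single-element grid the corresponding endpoint test is returned
    exactly.
    """
    rho_grid = tuple(float(r) for r in rho_grid)
    if len(rho_grid) == 1:
        r = rho_grid[0]
        res = burden_test(block) if r == 1.0 else (
            skat_test(block) if r == 0.0 else None)
        if res is None:
            raise ValueError("single-rho grid must be 0 or 1")
        return TestResult(res.stat, res.p, res.flag, {"rho_min": r, "p_rho": (res.p,)})

    V = block.V
    S = block.S
    p_m = V.shape[0]
    lamV, Q = np.linalg.eigh(V)
    if lamV.max(initial=0.0) <= 1e-14:
        return TestResult(0.0, 1.0, flag="monomorphic")
    sqrtV = (Q * np.sqrt(np.clip(lamV, 0.0, None))) @ Q.T

    ss = float(S @ S)
    s1sq = float(S.sum()) ** 2
    p_rho = []
    lam_rho = []
    for rho in rho_grid:
        q_rho = (1.0 - rho) * ss + rho * s1sq
        lam_r = np.clip(_rho_eigen(V, sqrtV, rho), 0.0, None)
        lam_rho.append(lam_r)
        p_rho.append(mixture_chi2_pvalue(lam_r, q_rho, tol=1e-7))
    p_rho = np.asarray(p_rho)
    t_min = float(p_rho.min())
    rho_min = rho_grid[int(p_rho.argmin())]
    extra = {"min_p_rho": t_min, "rho_min": rho_min, "p_rho": tuple(p_rho)}

    if p_m == 1:
        # every rho gives the same 1-df statistic
        return TestResult(t_min, t_min, extra=extra)

    # shared-factor (Lee) decomposition of the rho family
    grid_adj = np.minimum(np.asarray(rho_grid), 0.999)
    z_mean = sqrtV.sum(axis=1) / p_m
    zm2 = float(z_mean @ z_mean)
    if zm2 <= 1e-14:
        p_val = min(1.0, t_min * len(rho_grid))
        return TestResult(t_min, p_val, flag="degenerate-omnibus", extra=extra)
    cof = (z_mean @ sqrtV) / zm2
    z_item1 = np.outer(z_mean, cof)
    z2 = sqrtV - z_item1
    w1 = z2.T @ z2
    lam = np.linalg.eigvalsh(w1)
    lam = lam[lam > 1e-12 * max(1.0, lam.max(initial=0.0))]
    if lam.size == 0:
        p_val = min(1.0, t_min * len(rho_grid))
        return TestResult(t_min, p_val, flag="degenerate-omnibus", extra=extra)
    var_remain = 4.0 * float(np.sum((z_item1.T @ z_item1) * w1))
    mu_q = lam.sum()
    var_q = 2.0 * (lam ** 2).sum() + var_remain
    tau = (p_m ** 2 * grid_adj + (1.0 - grid_adj) * float(cof @ cof)) * zm2

    q_min = np.array([liu_quantile(t_min, lr) for lr in lam_rho])

    # integrate P(min_rho p_rho <= T | eta1 = x) over x ~ chi2_1 via x = t^2
    nodes, wts = roots_legendre(48)
    t_hi = math.sqrt(40.0)
    t = 0.5 * t_hi * (nodes + 1.0)
    wts = 0.5 * t_hi * wts
    x = t * t
    delta = np.min((q_min[:, None] - tau[:, None] * x[None, :]) / (1.0 - grid_adj)[:, None], axis=0)
    sd_adj = math.sqrt(max(var_q - var_remain, 1e-300) / var_q)
    delta_adj = (delta - mu_q) * sd_adj + mu_q
    tail = mixture_chi2_pvalue(lam, np.maximum(delta_adj, 0.0), tol=1e-7)
    surv = np.where(delta_adj <= 0.0, 1.0, tail)  # P(eta > delta)
    f_vals = 1.0 - surv
    integral = float(np.sum(f_vals * 2.0 * norm.pdf(t) * wts))
    p_val = 1.0 - integral
    p_val = min(p_val, t_min * len(rho_grid))
    p_val = float(np.clip(p_val, t_min, 1.0))
    return TestResult(t_min, p_val, extra=extra)


def vt_test(block: ScoreBlock, mafs: np.ndarray,
            draws: int = 1_000_000, rng: np.random.Generator | None = None,
            method: str = "qmc", two_sided: bool = True) -> TestResult:
    """Variable-threshold test on the maximal standardized weighted burden.

    Thresholds are the distinct MAF values of the gene's variants; at
    threshold T the burden collapses variants with MAF <= T using the
    block's weights. The null distribution of the threshold-score vector
    is exactly N(0, R) with R from the score covariance, and
    P(max |z| >= observed) is evaluated by draws from N(0, R):
    scrambled-Sobol quasi-Monte-Carlo with a Genz rectangle-probability
    refinement in the far tail (``method="qmc"``, default, seeded via
    ``rng``), the Genz integral alone (``method="genz"``), or plain
    Monte-Carlo draws (``method="mc"``).
    """
    mafs = np.asarray(mafs, dtype=float).ravel()
    if mafs.size != block.n_variants:
        raise ValueError("mafs length must match the score block")
    thresholds = np.unique(mafs)
    a_list, b_vals, v_vals, thr_kept = [], [], [], []
    for thr in thresholds:
        a = block.weights * (mafs <= thr)
        var = float(a @ block.raw_cov @ a)
        if var <= 1e-14:
            continue  # degenerate threshold dropped
        a_list.append(a)
        b_vals.append(float(a @ block.raw_score))
        v_vals.append(var)
        thr_kept.append(float(thr))
    if not a_list:
        return TestResult(0.0, 1.0, flag="monomorphic")
    A = np.array(a_list)
    z = np.array(b_vals) / np.sqrt(v_vals)
    best = int(np.argmax(np.abs(z) if two_sided else z))
    stat = float(np.abs(z[best]) if two_sided else z[best])
    chosen = thr_kept[best]
    cov = A @ block.raw_cov @ A.T
    sd = np.sqrt(np.diag(cov))
    R = cov / np.outer(sd, sd)
    d = R.shape[0]
    if d == 1:
        p = float(2.0 * norm.sf(stat)) if two_sided else float(norm.sf(stat))
        return TestResult(stat, min(p, 1.0), extra={"threshold": chosen})
    p_single = float(2.0 * norm.sf(stat) if two_sided else norm.sf(stat))
    if method == "qmc":
        L = np.linalg.cholesky(R + 1e-9 * np.eye(d))
        u = _sobol_base(d)
        shift = (rng or np.random.default_rng(0)).random(d)
        Z = ndtri(np.clip((u + shift) % 1.0, 1e-12, 1 - 1e-12)) @ L.T
        m = np.abs(Z).max(axis=1) if two_sided else Z.max(axis=1)
        p = float(np.mean(m >= stat - 1e-12))
        if p < 30.0 / _N_QMC:
            p = _genz_tail(stat, R, two_sided)
        p = float(np.clip(p, p_single, min(1.0, d * p_single)))
    elif method == "genz":
        p = _genz_tail(stat, R, two_sided)
        p = float(np.clip(p, p_single, min(1.0, d * p_single)))
    elif method == "mc":
        rng = rng or np.random.default_rng()
        L = np.linalg.cholesky(R + 1e-9 * np.eye(d))
        exceed = 0
        chunk = 200_000
        done = 0
        while done < draws:
            k = min(chunk, draws - done)
            Z = rng.standard_normal((k, d)) @ L.T
            m = np.abs(Z).max(axis=1) if two_sided else Z.max(axis=1)
            exceed += int(np.sum(m >= stat - 1e-12))
            done += k
        p = (exceed + 1.0) / (draws + 1.0)
    else:
        raise ValueError(f"unknown VT method {method!r}")
    return TestResult(stat, min(p, 1.0), extra={"threshold": chosen, "n_thresholds": d})


_N_QMC = 8192
_SOBOL_BASE: dict[int, np.ndarray] = {}


def _sobol_base(d: int) -> np.ndarray:
    """Cached unscrambled Sobol points; randomized per call by a
    Cranley-Patterson rotation (uniform shift mod 1), which keeps the
    resulting tail-probability estimate unbiased."""
    if d not in _SOBOL_BASE:
        from scipy.stats import qmc

        _SOBOL_BASE[d] = qmc.Sobol(d, scramble=False).random(_N_QMC)
    return _SOBOL_BASE[d]


def _genz_tail(stat: float, R: np.ndarray, two_sided: bool) -> float:
    """1 - rectangle probability of N(0, R) via Genz's algorithm."""
    d = R.shape[0]
    lower = np.full(d, -stat) if two_sided else np.full(d, -np.inf)
    cdf = multivariate_normal.cdf(
        np.full(d, stat), mean=np.zeros(d), cov=R + 1e-9 * np.eye(d),
        allow_singular=True, lower_limit=lower,
        maxpts=200_000 * d, abseps=1e-7, releps=1e-3,
    )
    return float(np.clip(1.0 - cdf, 0.0, 1.0))


def single_variant_test(null_model: FamilyNullModel, dosage: np.ndarray,
                        rotated: bool = False) -> TestResult:
    """Score test of one variant under the polygenic null model."""
    g = np.asarray(dosage, dtype=float)
    s, C = null_model.quad_forms(g[:, None], rotated=rotated)
    v = float(C[0, 0])
    if v <= 1e-14:
        return TestResult(0.0, 1.0, flag="constant")
    z2 = float(s[0]) ** 2 / v
    return TestResult(z2, float(chi2.sf(z2, df=1)))


# ---------------------------------------------------------------------------
# Gene scan driver
# ---------------------------------------------------------------------------

@dataclass
class GeneTestResult:
    gene: str
    chrom: str
    n_variants: int
    mac: int
    results: dict[str, TestResult]
    skipped: str = ""
    significant: dict[str, bool] = field(default_factory=dict)


def _gene_rng(seed: int, gene_index: int) -> np.random.Generator:
    """Per-gene generator; depends only on (seed, gene index), so the scan
    result is independent of scheduling and thread count."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(gene_index))))


def run_gene_scan(genotypes: GenotypeMatrix, geneset: GeneSet,
                  phenotypes: PhenotypeFrame, kernel: RelMatrix | KernelEigen,
                  config: TestConfig | None = None, pedigree=None,
                  kcm: RelMatrix | None = None,
                  alpha: float = 0.05, threads: int = 1,
                  return_model: bool = False):
    """Scan every gene that passes the inclusion rule (>= min_variants rare
    variants and aggregate MAC >= min_mac) with the requested methods and
    flag Bonferroni-corrected significance over the tested genes."""
    cfg = config or TestConfig()
    check_aligned(genotypes.subject_order, phenotypes.subject_order)
    keig = kernel if isinstance(kernel, KernelEigen) else KernelEigen(kernel)
    if keig.subject_order is not None:
        check_aligned(genotypes.subject_order, keig.subject_order)

    freqs = allele_freq(genotypes, pedigree)
    mafs = np.minimum(freqs, 1.0 - freqs)
    g_imp = impute_for_analysis(genotypes, freqs, kcm=kcm)
    typed = np.isfinite(genotypes.dosage)
    counted = np.nansum(genotypes.dosage, axis=0)
    total = 2.0 * typed.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p_all = np.where(total > 0, counted / np.maximum(total, 1), np.nan)
    mac_all = np.where(p_all <= 0.5, counted, total - counted)

    model = FamilyNullModel(keig, phenotype_kind=phenotypes.kind)
    model.fit(phenotypes.phenotype, phenotypes.covariates)
    Gt_all = keig.U.T @ g_imp.dosage  # rotate once

    def _one_gene(gi: int, gene: str, var_ix) -> GeneTestResult:
        ix = [j for j in var_ix
              if np.isfinite(mafs[j]) and 0.0 < mafs[j] <= cfg.rare_maf_max]
        chrom = genotypes.variant_order[var_ix[0]].chrom if var_ix else "NA"
        mac = int(np.nansum(mac_all[ix])) if ix else 0
        if len(ix) < cfg.min_variants:
            return GeneTestResult(gene, chrom, len(ix), mac, {},
                                  skipped=f"n_variants<{cfg.min_variants}")
        if mac < cfg.min_mac:
            return GeneTestResult(gene, chrom, len(ix), mac, {},
                                  skipped=f"MAC<{cfg.min_mac}")
        gmaf = mafs[ix]
        w = cfg.weights(gmaf)
        block = score_block(model, Gt_all[:, ix], w, rotated=True)
        res: dict[str, TestResult] = {}
        for method in cfg.methods:
            if method == "burden":
                res[method] = burden_test(block)
            elif method == "skat":
                res[method] = skat_test(block)
            elif method == "skato":
                res[method] = skato_test(block, cfg.rho_grid)
            elif method == "vt":
                res[method] = vt_test(block, gmaf, draws=cfg.vt_draws,
                                      rng=_gene_rng(cfg.seed, gi),
                                      method=cfg.vt_method,
                                      two_sided=cfg.vt_two_sided)
            else:
                raise ValueError(f"unknown method {method!r}")
        return GeneTestResult(gene, chrom, len(ix), mac, res)

    items = list(enumerate(sorted(geneset.genes.items())))
    if threads > 1:
        from concurrent.futures import ThreadPoolExecutor

        with ThreadPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(
                lambda t: _one_gene(t[0], t[1][0], t[1][1]), items))
    else:
        results = [_one_gene(gi, gene, var_ix) for gi, (gene, var_ix) in items]
    tested = [r for r in results if not r.skipped]
    if not tested:
        raise ValueError("no gene passed the inclusion rule")
    cutoff = alpha / len(tested)
    for r in tested:
        r.significant = {m: res.p <= cutoff for m, res in r.results.items()}
    return (results, model) if return_model else results


def write_results_table(results: list[GeneTestResult], path,
                        methods=None) -> None:
    """Tab-delimited results with per-method STAT/P columns and FLAG."""
    if methods is None:
        methods = sorted({m for r in results for m in r.results})
    with open(path, "w") as fh:
        cols = ["GENE", "CHR", "N_VAR", "MAC"]
        for m in methods:
            cols += [f"STAT_{m.upper()}", f"P_{m.upper()}", f"SIG_{m.upper()}"]
        cols.append("FLAG")
        fh.write("\t".join(cols) + "\n")
        for r in results:
            row = [r.gene, r.chrom, str(r.n_variants), str(r.mac)]
            for m in methods:
                if m in r.results:
                    tr = r.results[m]
                    row += [f"{tr.stat:.6g}", f"{tr.p:.6g}",
                            "1" if r.significant.get(m) else "0"]
                else:
                    row += ["NA", "NA", "NA"]
            row.append(r.skipped or ";".join(
                f"{m}:{tr.flag}" for m, tr in r.results.items() if tr.flag) or ".")
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# QQ / genomic control
# ---------------------------------------------------------------------------

def qq_and_lambda(p_values):
    """Observed vs expected -log10 p quantiles and the genomic inflation
    factor lambda_GC = median(chi2_1 quantile of 1-p) / 0.4549."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 10:
        raise ValueError("need at least 10 p-values")
    if np.any(p <= 0):
        import warnings
        warnings.warn("p = 0 entries clamped to the machine minimum")
        p = np.maximum(p, np.finfo(float).tiny)
    obs = np.sort(-np.log10(p))[::-1]
    n = p.size
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    stats = chi2.isf(p, df=1)
    lam = float(np.median(stats) / chi2.isf(0.5, df=1))
    table = np.column_stack([exp, obs])
    return table, lam
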