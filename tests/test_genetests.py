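"""Gene-level tests: endpoint identities, population-reduction oracles,
invariances and the scan driver contract."""

import numpy as np
import pytest
from scipy.stats import chi2, norm

from famrv.datatypes import GeneSet, PhenotypeFrame, RelMatrix
from famrv.genetests import (
    TestConfig,
    burden_test,
    qq_and_lambda,
    run_gene_scan,
    single_variant_test,
    skat_test,
    skato_test,
    vt_test,
)
from famrv.nullmodel import FamilyNullModel, KernelEigen, score_block
from famrv.pedigree import kinship_matrix
from famrv.simulate import SimSpec, build_study, make_pedigree, simulate_phenotype


# ---------------------------------------------------------------------------
# Independent population-based oracle (K = I, intercept-only, continuous)
# ---------------------------------------------------------------------------

def ruben_mixture_sf(q, lam, n_terms=20000):
    """Tail probability of a chi-square mixture by Ruben's series -- an
    algorithm independent of the package's characteristic-function
    inversion."""
    lam = np.asarray(lam, float)
    lam = lam[lam > 1e-12 * lam.max()]
    m = lam.size
    beta = 0.90535 * lam.min()
    c = np.empty(n_terms)
    c[0] = np.prod(np.sqrt(beta / lam))
    r = 1 - beta / lam
    d = np.array([0.5 * np.sum(r ** k) for k in range(1, n_terms)])
    for k in range(1, n_terms):
        c[k] = np.dot(c[:k][::-1], d[:k]) / k
    dfs = m + 2 * np.arange(n_terms)
    assert c.sum() == pytest.approx(1.0, abs=1e-10), "series not converged"
    return float(1.0 - np.dot(c, chi2.cdf(q / beta, dfs)))


def population_skat_oracle(y, G, w):
    """Population SKAT from first principles: centered scores, REML-free."""
    n = len(y)
    resid = y - y.mean()
    s2 = resid @ resid / (n - 1)
    s = G.T @ resid / s2
    q = float(np.sum(w * s ** 2))
    Gc = G - G.mean(axis=0)
    V = (np.sqrt(w)[:, None] * (Gc.T @ Gc) * np.sqrt(w)[None, :]) / s2
    lam = np.linalg.eigvalsh(V)
    return ruben_mixture_sf(q, lam[lam > 1e-10 * lam.max()])


def population_burden_oracle(y, G, w):
    n = len(y)
    resid = y - y.mean()
    s2 = resid @ resid / (n - 1)
    c = G @ w
    score = float(c @ resid / s2)
    cc = c - c.mean()
    var = float(cc @ cc / s2)
    return float(chi2.sf(score ** 2 / var, df=1))


def _population_setup(seed=0, n=400, p=5):
    rng = np.random.default_rng(seed)
    G = rng.binomial(2, rng.uniform(0.02, 0.05, p), (n, p)).astype(float)
    y = rng.standard_normal(n)
    keys = [(f"F{i}", "1") for i in range(n)]
    keig = KernelEigen(RelMatrix(0.5 * np.eye(n), "KCM", keys))
    model = FamilyNullModel(keig).fit(y, None)
    return y, G, model


def test_burden_reduces_to_population_score_test():
    y, G, model = _population_setup(1)
    w = np.ones(G.shape[1])
    blk = score_block(model, G, w)
    p_pkg = burden_test(blk).p
    p_oracle = population_burden_oracle(y, G, w)
    assert p_pkg == pytest.approx(p_oracle, abs=1e-6)


def test_skat_reduces_to_population_skat():
    y, G, model = _population_setup(2)
    w = np.ones(G.shape[1])
    blk = score_block(model, G, w)
    p_pkg = skat_test(blk).p
    p_oracle = population_skat_oracle(y, G, w)
    assert p_pkg == pytest.approx(p_oracle, abs=1e-6)


def test_single_variant_reduces_to_trend_score():
    y, G, model = _population_setup(3, p=1)
    res = single_variant_test(model, G[:, 0])
    p_oracle = population_burden_oracle(y, G, np.ones(1))
    assert res.p == pytest.approx(p_oracle, abs=1e-8)


def test_single_variant_constant_dosage_flagged():
    y, G, model = _population_setup(4, p=1)
    res = single_variant_test(model, np.full(len(y), 1.0))
    assert res.p == 1.0 and res.flag == "constant"


# ---------------------------------------------------------------------------
# Endpoint identities and variable-threshold degeneracies
# ---------------------------------------------------------------------------

def _family_block(seed=0, n_var=5):
    study = build_study(SimSpec(n_families=30, n_genes=4, seed=seed))
    y = simulate_phenotype(study.pedigree, study.kcm,
                           SimSpec(n_families=30, h2=0.3, seed=seed),
                           seed=np.random.default_rng(seed))
    model = FamilyNullModel(study.keig).fit(y.phenotype, None)
    gene = sorted(study.gene_cols)[0]
    cols = study.gene_cols[gene][:n_var]
    gmaf = study.mafs[cols]
    from famrv.nullmodel import WeightSpec

    w = WeightSpec()(gmaf)
    return score_block(model, study.genotypes.dosage[:, cols], w), gmaf


def test_skato_endpoints_match_burden_and_skat_exactly():
    blk, _ = _family_block(11)
    assert skato_test(blk, rho_grid=(1.0,)).p == burden_test(blk).p
    assert skato_test(blk, rho_grid=(0.0,)).p == skat_test(blk).p


def test_skato_per_rho_endpoints_in_full_grid():
    blk, _ = _family_block(12)
    res = skato_test(blk)
    p_rho = res.extra["p_rho"]
    assert p_rho[0] == pytest.approx(skat_test(blk).p, rel=1e-6)
    assert p_rho[-1] == pytest.approx(burden_test(blk).p, rel=1e-6)
    # omnibus p is never below the minimum per-rho p
    assert res.p >= res.extra["min_p_rho"] - 1e-12


def test_skato_omnibus_vs_min_p_monte_carlo():
    """Omnibus p agrees with the Monte-Carlo null distribution of the
    minimum per-rho p-value on a fixed 5-variant covariance."""
    blk, _ = _family_block(13, n_var=5)
    res = skato_test(blk)
    rho_grid = (0.0, 0.25, 0.5, 1.0)
    res4 = skato_test(blk, rho_grid=rho_grid)
    # simulate S ~ N(0, V), recompute min-p for each draw
    rng = np.random.default_rng(99)
    V = blk.V
    lamV, Q = np.linalg.eigh(V)
    L = Q * np.sqrt(np.clip(lamV, 0, None))
    n_mc = 30000
    S = rng.standard_normal((n_mc, V.shape[0])) @ L.T
    sqrtV = L @ Q.T
    t_obs = res4.extra["min_p_rho"]
    # per-rho survival evaluated at each draw's statistic via the same
    # eigenvalue route (monotone map, so ranks are what matter)
    from famrv.genetests import _rho_eigen
    from famrv.quadform import mixture_chi2_pvalue

    pmin = np.ones(n_mc)
    for rho in rho_grid:
        qv = (1 - rho) * np.sum(S ** 2, axis=1) + rho * S.sum(axis=1) ** 2
        lam_r = np.clip(_rho_eigen(V, sqrtV, rho), 0, None)
        pv = mixture_chi2_pvalue(lam_r, qv, tol=1e-7)
        pmin = np.minimum(pmin, pv)
    p_mc = float(np.mean(pmin <= t_obs))
    se = np.sqrt(max(p_mc * (1 - p_mc), 1e-9) / n_mc)
    assert res4.p == pytest.approx(p_mc, abs=max(3 * se, 0.01))


def test_vt_single_threshold_equals_two_sided_burden():
    blk, gmaf = _family_block(14)
    one_maf = np.full_like(gmaf, 0.03)
    res = vt_test(blk, one_maf, method="qmc", rng=np.random.default_rng(0))
    z2 = res.stat ** 2
    p_burden = 2 * norm.sf(abs(res.stat))
    assert res.p == pytest.approx(p_burden, abs=1e-12)


def test_vt_duplicated_variant_collapses():
    """Two identical columns at one threshold equal one column with doubled
    weight (statistic identical)."""
    y, G, model = _population_setup(6, p=2)
    G[:, 1] = G[:, 0]
    blk = score_block(model, G, np.ones(2))
    mafs = np.full(2, 0.04)
    res = vt_test(blk, mafs, method="qmc", rng=np.random.default_rng(1))
    blk1 = score_block(model, G[:, :1], np.array([2.0]))
    res1 = vt_test(blk1, mafs[:1], method="qmc", rng=np.random.default_rng(1))
    assert res.stat == pytest.approx(res1.stat, rel=1e-10)


def test_vt_methods_agree():
    blk, gmaf = _family_block(15)
    p_qmc = vt_test(blk, gmaf, method="qmc", rng=np.random.default_rng(3)).p
    p_genz = vt_test(blk, gmaf, method="genz").p
    p_mc = vt_test(blk, gmaf, method="mc", draws=100000,
                   rng=np.random.default_rng(4)).p
    assert p_qmc == pytest.approx(p_genz, abs=0.02)
    assert p_mc == pytest.approx(p_genz, abs=0.02)


def test_location_scale_invariance_of_pvalues():
    study = build_study(SimSpec(n_families=30, n_genes=3, seed=21))
    spec = SimSpec(n_families=30, h2=0.3, seed=21)
    y0 = simulate_phenotype(study.pedigree, study.kcm, spec,
                            seed=np.random.default_rng(21)).phenotype
    gene = sorted(study.gene_cols)[0]
    cols = study.gene_cols[gene]
    gmaf = study.mafs[cols]
    from famrv.nullmodel import WeightSpec

    w = WeightSpec()(gmaf)
    G = study.genotypes.dosage[:, cols]
    ps = {}
    for label, y in (("base", y0), ("affine", 3.7 * y0 + 11.0)):
        model = FamilyNullModel(study.keig).fit(y, None)
        blk = score_block(model, G, w)
        ps[label] = (burden_test(blk).p, skat_test(blk).p, skato_test(blk).p)
    for a, b in zip(ps["base"], ps["affine"]):
        assert a == pytest.approx(b, abs=1e-10)


# ---------------------------------------------------------------------------
# Scan driver
# ---------------------------------------------------------------------------

def _scan_inputs(seed=31):
    study = build_study(SimSpec(n_families=25, n_genes=6, seed=seed))
    spec = SimSpec(n_families=25, h2=0.3, seed=seed)
    ph = simulate_phenotype(study.pedigree, study.kcm, spec,
                            seed=np.random.default_rng(seed))
    return study, ph


def test_gene_scan_inclusion_rule(make_genotypes):
    study, ph = _scan_inputs()
    genes = dict(study.geneset.genes)
    first = sorted(genes)[0]
    genes["single_variant_gene"] = genes[first][:1]
    results = run_gene_scan(study.genotypes, GeneSet(genes), ph, study.kcm,
                            TestConfig(seed=1), kcm=study.kcm)
    by_name = {r.gene: r for r in results}
    assert by_name["single_variant_gene"].skipped == "n_variants<2"
    tested = [r for r in results if not r.skipped]
    assert len(tested) == len(study.geneset)
    for r in tested:
        assert r.n_variants >= 2 and r.mac >= 4
        for m, tr in r.results.items():
            assert 0 < tr.p <= 1


def test_gene_scan_deterministic_and_thread_invariant(tmp_path):
    from famrv.genetests import write_results_table

    study, ph = _scan_inputs(32)
    cfg = TestConfig(seed=7, vt_draws=20000)
    r1 = run_gene_scan(study.genotypes, study.geneset, ph, study.kcm, cfg,
                       kcm=study.kcm)
    r2 = run_gene_scan(study.genotypes, study.geneset, ph, study.kcm, cfg,
                       kcm=study.kcm)
    r4 = run_gene_scan(study.genotypes, study.geneset, ph, study.kcm, cfg,
                       kcm=study.kcm, threads=4)
    paths = []
    for tag, res in (("a", r1), ("b", r2), ("c", r4)):
        path = tmp_path / f"{tag}.tsv"
        write_results_table(res, path)
        paths.append(path.read_bytes())
    assert paths[0] == paths[1] == paths[2]


def test_gene_scan_empty_geneset_raises():
    study, ph = _scan_inputs(33)
    empty = GeneSet({"nothing": []})
    with pytest.raises(ValueError, match="inclusion"):
        run_gene_scan(study.genotypes, empty, ph, study.kcm, TestConfig(seed=1))


# ---------------------------------------------------------------------------
# QQ / lambda
# ---------------------------------------------------------------------------

def test_lambda_gc_uniform_null():
    rng = np.random.default_rng(18)
    _table, lam = qq_and_lambda(rng.random(10**4))
    assert lam == pytest.approx(1.0, abs=0.03)


def test_lambda_gc_definition_and_monotonicity():
    p = np.full(100, 0.5)
    _t, lam = qq_and_lambda(p)
    assert lam == pytest.approx(1.0, abs=1e-12)
    rng = np.random.default_rng(18)
    p = rng.random(1000)
    _t, lam1 = qq_and_lambda(p)
    _t, lam2 = qq_and_lambda(p / 2)
    assert lam2 > lam1


def test_lambda_gc_requires_enough_pvalues():
    with pytest.raises(ValueError):
        qq_and_lambda([0.5] * 5)


def test_single_variant_null_inflation():
    """Genome-wide null single-variant scan has lambda_GC near 1."""
    ped = make_pedigree("gen3_8", 40)
    kcm = kinship_matrix(ped)
    keig = KernelEigen(kcm)
    rng = np.random.default_rng(55)
    from famrv.simulate import gene_drop

    geno = gene_drop(ped, rng.uniform(0.1, 0.5, 3000), rng)
    spec = SimSpec(n_families=40, h2=0.4, seed=5)
    y = simulate_phenotype(ped, kcm, spec, seed=rng)
    model = FamilyNullModel(keig).fit(y.phenotype, None)
    Gt = keig.U.T @ geno.dosage
    ps = []
    for j in range(3000):
        ps.append(single_variant_test(model, Gt[:, j], rotated=True).p)
    _t, lam = qq_and_lambda(np.array(ps))
    assert 0.95 <= lam <= 1.05
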