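"""Quality-control statistics and the filtering engine."""

from fractions import Fraction
from math import factorial

import numpy as np
import pytest

from famrv.datatypes import PedigreeRecord, VariantRecord
from famrv.pedigree import build_pedigree, kinship_matrix
from famrv.qc import (
    QCThresholds,
    allele_freq,
    apply_filters,
    fixation_index,
    hwe_exact,
    inbreeding_coefficient,
    tstv_ratio,
    variant_stats,
)
from famrv.simulate import gene_drop, make_pedigree


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test vs exact rational enumeration
# ---------------------------------------------------------------------------

def hwe_exact_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact-rational enumeration of the conditional het-count
    distribution; independent of the package implementation."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_a = 2 * n_hom_alt + n_het  # alt allele count
    probs = {}
    for het in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        hom_a = (n_a - het) // 2
        hom_r = n - het - hom_a
        if hom_r < 0 or hom_a < 0:
            continue
        # P(het | n, n_a) = 2^het * n! / (hom_r! het! hom_a!)
        #                   * n_a! (2n - n_a)! / (2n)!   (exact rational)
        num = (Fraction(2) ** het
               * Fraction(factorial(n), factorial(hom_r) * factorial(het)
                          * factorial(hom_a))
               * Fraction(factorial(n_a) * factorial(2 * n - n_a),
                          factorial(2 * n)))
        probs[het] = num
    obs = probs[n_het]
    p = sum(v for v in probs.values() if v <= obs)
    return float(min(p, 1))


@pytest.mark.parametrize("counts", [
    (25, 50, 25), (0, 100, 0), (57, 14, 50), (10, 1, 0), (0, 0, 7),
    (3, 3, 3), (100, 1, 99),
])
def test_hwe_exact_matches_enumeration(counts):
    assert hwe_exact(*counts) == pytest.approx(hwe_exact_oracle(*counts), abs=1e-12)


def test_hwe_exact_sweep_up_to_200():
    """Systematic sweep of founder genotype configurations with N <= 200."""
    for n in range(1, 201, 13):
        for n_alt in range(0, 2 * n + 1, max(1, n // 3)):
            n_het = min(n_alt, 2 * n - n_alt) % 2 + min(n_alt, 2 * n - n_alt) // 2
            # pick a feasible het count of the right parity
            het = n_het if (n_het - n_alt) % 2 == 0 else max(n_het - 1, n_alt % 2)
            hom_a = (n_alt - het) // 2
            hom_r = n - het - hom_a
            if hom_r < 0 or hom_a < 0 or het < 0:
                continue
            assert hwe_exact(hom_r, het, hom_a) == pytest.approx(
                hwe_exact_oracle(hom_r, het, hom_a), abs=1e-12)


def test_hwe_monomorphic_and_empty():
    assert hwe_exact(50, 0, 0) == 1.0
    assert hwe_exact(0, 0, 0) == 1.0
    assert hwe_exact(0, 100, 0) < 1e-20  # extreme heterozygote excess


# ---------------------------------------------------------------------------
# Variant / subject statistics
# ---------------------------------------------------------------------------

def test_variant_stats_trivial_example(make_genotypes):
    g = make_genotypes([[0.0], [1.0], [2.0], [np.nan]])
    st = variant_stats(g)[0]
    assert st.maf == pytest.approx(0.5)
    assert st.mac == 3
    assert st.call_rate == pytest.approx(0.75)


def test_all_missing_variant(make_genotypes):
    g = make_genotypes([[np.nan], [np.nan]])
    st = variant_stats(g)[0]
    assert st.call_rate == 0.0 and np.isnan(st.maf)


def test_founder_preferring_maf_recovery():
    ped = make_pedigree("gen3_8", 50)
    rng = np.random.default_rng(21)
    geno = gene_drop(ped, np.full(300, 0.1), rng)
    p = allele_freq(geno, ped)
    assert abs(np.mean(p) - 0.1) < 0.01
    assert np.all(np.abs(p - 0.1) < 0.1)


def test_tstv_ratio():
    recs = [VariantRecord("1", 1, "a", "A", "G"),
            VariantRecord("1", 2, "b", "T", "C"),
            VariantRecord("1", 3, "c", "C", "A")]
    assert tstv_ratio(recs) == pytest.approx(2.0)
    assert tstv_ratio([VariantRecord("1", 1, "d", "A", "T")]) == 0.0
    assert np.isinf(tstv_ratio(recs[:2]))


def test_tstv_simulated_transition_fraction():
    rng = np.random.default_rng(9)
    pairs_ts = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]
    pairs_tv = [("A", "T"), ("A", "C"), ("G", "C"), ("G", "T")]
    recs = []
    for i in range(3000):
        ref, alt = pairs_ts[rng.integers(4)] if rng.random() < 2 / 3 else \
            pairs_tv[rng.integers(4)]
        recs.append(VariantRecord("1", i + 1, f"v{i}", ref, alt))
    assert tstv_ratio(recs) == pytest.approx(2.0, abs=0.2)


def test_inbreeding_coefficient_edges():
    p = np.full(100, 0.5)
    # expected het = 50; observed het = 50 -> F = 0
    d = np.array([1.0] * 50 + [0.0] * 25 + [2.0] * 25)
    assert inbreeding_coefficient(d, p) == pytest.approx(0.0)
    # no heterozygotes -> F = 1
    assert inbreeding_coefficient(np.array([0.0, 2.0] * 50), p) == pytest.approx(1.0)


def test_inbreeding_full_sib_mating_offspring():
    recs = [
        PedigreeRecord("F1", "a", "0", "0", 1, 0),
        PedigreeRecord("F1", "b", "0", "0", 2, 0),
        PedigreeRecord("F1", "s1", "a", "b", 1, 0),
        PedigreeRecord("F1", "s2", "a", "b", 2, 0),
        PedigreeRecord("F1", "x", "s1", "s2", 1, 0),
    ]
    ped = build_pedigree(recs)
    rng = np.random.default_rng(31)
    p = rng.uniform(0.2, 0.5, 5000)
    geno = gene_drop(ped, p, rng)
    i = geno.subject_index()[("F1", "x")]
    f = inbreeding_coefficient(geno.dosage[i], p)
    # parents are full sibs: E[F] = phi(s1, s2) = 0.25
    assert f == pytest.approx(0.25, abs=0.05)


def test_fixation_index_island_model(make_genotypes):
    rng = np.random.default_rng(17)
    fst_true = 0.05
    m, n_per = 2000, 300
    p0 = rng.uniform(0.2, 0.8, m)
    a = p0 * (1 - fst_true) / fst_true
    b = (1 - p0) * (1 - fst_true) / fst_true
    rows = []
    labels = []
    for pop in range(2):
        pk = rng.beta(a, b)
        rows.append((rng.random((n_per, m, 2)) < pk[None, :, None]).sum(2))
        labels += [pop] * n_per
    d = np.vstack(rows).astype(float)
    keys = [(f"P{l}", f"s{i}") for i, l in enumerate(labels)]
    _, gw = fixation_index(make_genotypes(d, keys=keys), labels)
    assert gw == pytest.approx(fst_true, abs=0.01)


def test_fixation_index_extremes(make_genotypes):
    # same frequencies -> Fst ~ 0; fixed opposite alleles -> Fst ~ 1
    rng = np.random.default_rng(2)
    d = rng.binomial(2, 0.4, (400, 500)).astype(float)
    labels = [0] * 200 + [1] * 200
    keys = [(f"P{l}", f"s{i}") for i, l in enumerate(labels)]
    _, gw0 = fixation_index(make_genotypes(d, keys=keys), labels)
    assert abs(gw0) < 0.01
    d1 = np.vstack([np.zeros((50, 100)), np.full((50, 100), 2.0)])
    keys1 = [("P0", f"s{i}") for i in range(50)] + [("P1", f"s{i}") for i in range(50)]
    _, gw1 = fixation_index(make_genotypes(d1, keys=keys1), [0] * 50 + [1] * 50)
    assert gw1 == pytest.approx(1.0, abs=1e-6)


# ---------------------------------------------------------------------------
# Filtering engine
# ---------------------------------------------------------------------------

def test_apply_filters_counts_and_order(make_genotypes):
    rng = np.random.default_rng(4)
    d = rng.binomial(2, 0.3, (20, 40)).astype(float)
    d[0:3, 0] = np.nan  # variant 0 call rate 0.85
    d[3:6, 1] = np.nan  # variant 1 call rate 0.85
    # each affected subject misses 1/40 = call rate 0.975: kept
    g = make_genotypes(d, keys=[(f"F{i}", "1") for i in range(20)])
    filtered, rep = apply_filters(g, thresholds=QCThresholds())
    assert rep.removed_subjects["call_rate"] == 0
    assert rep.removed_variants["call_rate"] == 2
    assert filtered.n_variants == 38


def test_apply_filters_disabled_is_identity(make_genotypes):
    rng = np.random.default_rng(4)
    d = rng.binomial(2, 0.3, (10, 5)).astype(float)
    d[0, 0] = np.nan
    g = make_genotypes(d)
    th = QCThresholds(hwe_p_min=None, variant_call_rate_min=None,
                      variant_mendel_max=None, subject_call_rate_min=None,
                      subject_mendel_max=None)
    filtered, _ = apply_filters(g, thresholds=th)
    np.testing.assert_array_equal(filtered.dosage, g.dosage)


def test_subject_removed_before_variant_stats(make_genotypes):
    rng = np.random.default_rng(8)
    d = rng.binomial(2, 0.3, (10, 10)).astype(float)
    d[0, :6] = np.nan          # subject 0: 60% missing -> removed first
    d[0, 6] = np.nan           # variant 6 missing only in subject 0
    g = make_genotypes(d, keys=[(f"F{i}", "1") for i in range(10)])
    filtered, rep = apply_filters(g, thresholds=QCThresholds())
    assert rep.removed_subjects["call_rate"] == 1
    # after dropping subject 0, variant 6 regains call rate 1.0
    assert filtered.n_variants == 10


def test_filtering_idempotent(make_genotypes):
    rng = np.random.default_rng(12)
    d = rng.binomial(2, 0.2, (20, 40)).astype(float)
    d[0, 10:] = np.nan      # subject 0 call rate 0.25: removed
    d[10:13, 5] = np.nan    # variant 5 call rate < 0.95 after that: removed
    g = make_genotypes(d, keys=[(f"F{i}", "1") for i in range(20)])
    th = QCThresholds()
    once, _ = apply_filters(g, thresholds=th)
    twice, rep2 = apply_filters(once, thresholds=th)
    np.testing.assert_array_equal(once.dosage, twice.dosage)
    assert all(v == 0 for v in rep2.removed_subjects.values())
    assert all(v == 0 for v in rep2.removed_variants.values())


def test_statistics_invariant_to_orders(make_genotypes):
    rng = np.random.default_rng(14)
    d = rng.binomial(2, 0.3, (12, 8)).astype(float)
    g = make_genotypes(d, keys=[(f"F{i}", "1") for i in range(12)])
    st = variant_stats(g)
    perm = rng.permutation(12)
    g2 = make_genotypes(d[perm], keys=[(f"F{i}", "1") for i in perm])
    st2 = variant_stats(g2)
    for a, b in zip(st, st2):
        assert a.maf == pytest.approx(b.maf)
        assert a.hwe_p == pytest.approx(b.hwe_p)
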