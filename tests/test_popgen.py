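"""HWE nested LRT, equality-proportion test, rare alleles, membership."""

import numpy as np
import pytest

from hlaimpute import (
    LocusGenotype,
    SimConfig,
    equality_proportion_test,
    flag_rare_alleles,
    generate,
    genotype_distribution,
    haplotype_membership,
    hwe_nested_lrt,
    impute_top,
    sample_population,
)
from conftest import allele, hap


def draw_genotypes(rng, p, n, F=0.0):
    k = len(p)
    a = rng.choice(k, size=n, p=p)
    b = rng.choice(k, size=n, p=p)
    if F > 0:
        b = np.where(rng.random(n) < F, a, b)
    alleles = [allele("A", 1, i + 1) for i in range(k)]
    return [LocusGenotype((alleles[i], alleles[j])) for i, j in zip(a, b)]


def test_perfect_hwe_proportions_give_null_fit():
    """Counts 36/48/16 are exactly HWE for p=0.6: statistic ~ 0, p ~ 1."""
    a, b = allele("A", 1, 1), allele("A", 1, 2)
    gts = ([LocusGenotype((a, a))] * 36 + [LocusGenotype((a, b))] * 48
           + [LocusGenotype((b, b))] * 16)
    res = hwe_nested_lrt(gts)
    assert res.statistic == pytest.approx(0.0, abs=1e-6)
    assert res.p_value == pytest.approx(1.0, abs=1e-3)
    assert res.f_hat == pytest.approx(0.0, abs=1e-3)
    assert res.allele_freqs[a] == pytest.approx(0.6)


def test_lrt_statistic_nonnegative(rng):
    for _ in range(30):
        p = rng.dirichlet(np.ones(3) * 2)
        res = hwe_nested_lrt(draw_genotypes(rng, p, 80))
        assert res.statistic >= -1e-9
        assert 0.0 <= res.p_value <= 1.0


def test_monomorphic_locus_rejected():
    a = allele("A", 1, 1)
    with pytest.raises(ValueError):
        hwe_nested_lrt([LocusGenotype((a, a))] * 10)


def test_inbreeding_coefficient_estimate_is_consistent(rng):
    p = np.array([0.4, 0.35, 0.25])
    f_abs = {}
    for n in (500, 5000):
        ests = [abs(hwe_nested_lrt(draw_genotypes(rng, p, n)).f_hat)
                for _ in range(10)]
        f_abs[n] = np.mean(ests)
    assert f_abs[5000] < f_abs[500]
    assert f_abs[5000] < 0.02


def test_lrt_detects_inbreeding(rng):
    p = np.array([0.35, 0.3, 0.2, 0.15])
    res = hwe_nested_lrt(draw_genotypes(rng, p, 400, F=0.3))
    assert res.f_hat == pytest.approx(0.3, abs=0.12)
    assert res.p_value < 0.01


def test_hwe_on_ambiguous_input_matches_unambiguous_limit(rng):
    """Feeding singleton AlleleSets must reproduce the plain path."""
    from hlaimpute import AlleleSet

    gts = draw_genotypes(rng, np.array([0.5, 0.3, 0.2]), 120)
    amb = [
        (AlleleSet("A", frozenset({g.alleles[0]}), "explicit"),
         AlleleSet("A", frozenset({g.alleles[1]}), "explicit"))
        for g in gts
    ]
    r1, r2 = hwe_nested_lrt(gts), hwe_nested_lrt(amb)
    assert r1.loglik_hwe == pytest.approx(r2.loglik_hwe, abs=1e-6)
    assert r1.statistic == pytest.approx(r2.statistic, abs=1e-3)


# -- equality proportion test ----------------------------------------------


def test_sample_vs_itself_is_never_significant():
    counts = {"A": {"A*01": 50, "A*02": 150, "A*03": 88}}
    n = 144
    ref = {"A": {g: c / (2 * n) for g, c in counts["A"].items()}}
    res = equality_proportion_test(counts, n, ref, n)
    assert all(r.z == pytest.approx(0.0) and r.p == pytest.approx(1.0)
               for r in res.rows)
    assert not any(r.significant for r in res.rows)


def test_swapping_sample_and_reference_flips_z():
    c_a = {"A": {"A*01": 60, "A*02": 228}}
    c_b = {"A": {"A*01": 90, "A*02": 198}}
    n = 144
    fa = {"A": {g: c / (2 * n) for g, c in c_a["A"].items()}}
    fb = {"A": {g: c / (2 * n) for g, c in c_b["A"].items()}}
    r_ab = equality_proportion_test(c_a, n, fb, n)
    r_ba = equality_proportion_test(c_b, n, fa, n)
    for x, y in zip(r_ab.rows, r_ba.rows):
        assert x.z == pytest.approx(-y.z)
        assert x.p == pytest.approx(y.p)


def test_zero_on_both_sides_is_skipped():
    counts = {"A": {"A*01": 10, "A*02": 0}}
    ref = {"A": {"A*01": 1.0, "A*02": 0.0}}
    res = equality_proportion_test(counts, 5, ref, 100)
    assert ("A", "A*02") in res.skipped
    assert res.n_tested == 1


def test_family_wise_error_controlled(rng):
    """Samples drawn from the reference distribution: after Bonferroni,
    any rejection at all happens in <= ~alpha of 500 replicates."""
    p = np.array([0.4, 0.25, 0.2, 0.1, 0.05])
    groups = [f"A*{k + 1:02d}" for k in range(5)]
    ref = {"A": dict(zip(groups, p))}
    n, n_ref = 144, 20000
    fw = 0
    for _ in range(500):
        draws = rng.multinomial(2 * n, p)
        counts = {"A": dict(zip(groups, draws.tolist()))}
        res = equality_proportion_test(counts, n, ref, n_ref, alpha=0.05)
        fw += any(r.significant for r in res.rows)
    rate = fw / 500
    assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 500)


# -- rare alleles -----------------------------------------------------------


def test_rare_allele_flags_match_linear_scan(rng):
    pop = generate(SimConfig(loci=("A", "B"), alleles_per_locus=4,
                             n_haplotypes=10, groups_per_locus=2,
                             n_donors=40, seed=50, rare_allele_rate=0.2))
    from hlaimpute import allele_frequencies

    ref = {}
    for locus in ("A", "B"):
        ref.update(allele_frequencies(pop.generating_table, locus))
    report = flag_rare_alleles(pop.truth, ref, threshold=0.01)
    # independent scan
    expected = set()
    for d, g in pop.truth:
        for lg in g.genotypes:
            if any(ref.get(a, 0.0) < 0.01 for a in lg.alleles):
                expected.add(d)
    assert set(report.per_donor) == expected
    assert report.fraction_flagged == pytest.approx(len(expected) / 40)
    # injected novel alleles are always flagged
    assert pop.rare_injected <= set(report.per_donor)


def test_all_common_alleles_no_flags():
    truths = [("D1", None)]
    from hlaimpute import LocusGenotype, MultiLocusUnphasedGenotype
    g = MultiLocusUnphasedGenotype(
        (LocusGenotype((allele("A", 1, 1), allele("A", 1, 2))),)
    )
    ref = {allele("A", 1, 1): 0.6, allele("A", 1, 2): 0.4}
    report = flag_rare_alleles([("D1", g)], ref, threshold=0.001)
    assert report.n_flagged == 0
    with pytest.raises(ValueError):
        flag_rare_alleles([("D1", g)], ref, threshold=1.5)


# -- haplotype membership ---------------------------------------------------


def test_membership_all_reported_with_generating_table():
    pop = generate(SimConfig(loci=("A", "B"), alleles_per_locus=4,
                             n_haplotypes=10, groups_per_locus=2,
                             n_donors=30, seed=51))
    rep = haplotype_membership(pop.ambiguous,
                               set(pop.generating_table.haplotypes),
                               [pop.generating_table])
    assert rep.fractions["both_reported"] == pytest.approx(1.0)


def test_withheld_carriers_are_partial_or_none():
    pop = generate(SimConfig(loci=("A", "B"), alleles_per_locus=4,
                             n_haplotypes=12, groups_per_locus=2,
                             n_donors=60, seed=52, novel_haplotype_rate=0.4))
    universe = set(pop.generating_table.haplotypes)
    rep = haplotype_membership(pop.ambiguous, universe, [pop.published_table])
    from hlaimpute import enumerate_explanations

    checked = 0
    for d, typing in pop.ambiguous:
        e = enumerate_explanations(typing, universe)
        only_withheld = e.pairs and all(
            h1 in pop.withheld or h2 in pop.withheld for h1, h2 in e.pairs
        )
        if only_withheld:
            checked += 1
            assert rep.per_donor[d] != "both_reported"
    assert abs(sum(rep.fractions.values()) - 1.0) < 1e-12


def test_none_reported_donors_are_imputed_incorrectly():
    """Donors with no reported haplotype pair cannot be imputed
    correctly from the published table."""
    pop = generate(SimConfig(loci=("A", "B", "C"), alleles_per_locus=4,
                             n_haplotypes=15, groups_per_locus=2,
                             n_donors=80, seed=53, novel_haplotype_rate=0.35))
    universe = set(pop.generating_table.haplotypes)
    correctness = {}
    for (d, typing), (_, g) in zip(pop.ambiguous, pop.truth):
        r = impute_top(genotype_distribution(typing, pop.published_table, d))
        correctness[d] = (r.top == g) and not r.unexplainable
    rep = haplotype_membership(pop.ambiguous, universe, [pop.published_table],
                               correctness=correctness)
    for d, cls in rep.per_donor.items():
        if cls == "none_reported":
            assert correctness[d] is False
    assert rep.crosstab  # populated when correctness supplied
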