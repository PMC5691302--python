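"""Explanation enumeration and EM haplotype-frequency estimation."""

import itertools

import numpy as np
import pytest

from hlaimpute import (
    HaplotypeFrequencyTable,
    SimConfig,
    allele_frequencies,
    em_estimate,
    enumerate_explanations,
    generate,
    unphase,
)
from conftest import allele, hap, typing_from_sets, unambiguous_typing, random_instance


def brute_force_pairs(typing, universe):
    """Independent oracle: test every unordered pair by checking, at
    each locus, both slot assignments explicitly."""
    universe = sorted(set(universe))
    out = []
    for h1, h2 in itertools.combinations_with_replacement(universe, 2):
        ok = True
        for s1, s2 in typing.slots:
            a, b = h1.at(s1.locus), h2.at(s1.locus)
            if not ((a in s1.candidates and b in s2.candidates)
                    or (a in s2.candidates and b in s1.candidates)):
                ok = False
                break
        if ok:
            out.append((h1, h2))
    return set(out)


def test_textbook_phase_ambiguity():
    """Double heterozygote at two loci: exactly the two phase pairs."""
    h = {ab: hap(("A", 1, ab[0]), ("B", 7, ab[1])) for ab in
         [(1, 1), (1, 2), (2, 1), (2, 2)]}
    typing = typing_from_sets(
        ("A", {allele("A", 1, 1)}, {allele("A", 1, 2)}),
        ("B", {allele("B", 7, 1)}, {allele("B", 7, 2)}),
    )
    e = enumerate_explanations(typing, set(h.values()))
    assert set(e.pairs) == {
        tuple(sorted((h[(1, 1)], h[(2, 2)]))),
        tuple(sorted((h[(1, 2)], h[(2, 1)]))),
    }


def test_homozygous_typing_has_single_explanation():
    h1 = hap(("A", 1, 1), ("B", 7, 1))
    typing = unambiguous_typing(unphase(h1, h1))
    e = enumerate_explanations(typing, {h1, hap(("A", 1, 2), ("B", 7, 2))})
    assert e.pairs == ((h1, h1),)


def test_enumeration_matches_brute_force(rng):
    for _ in range(200):
        table, typing, _ = random_instance(rng)
        e = enumerate_explanations(typing, set(table.haplotypes))
        assert set(e.pairs) == brute_force_pairs(typing, table.haplotypes)


def test_truth_pair_is_always_an_explanation(rng):
    for _ in range(100):
        table, typing, (h1, h2) = random_instance(rng)
        e = enumerate_explanations(typing, set(table.haplotypes))
        assert tuple(sorted((h1, h2))) in set(e.pairs)


def test_em_equals_counting_on_single_locus_data(rng):
    """With one locus there is no phase and no ambiguity: the MLE is
    the plain allele count."""
    alleles = [hap(("A", 1, k)) for k in (1, 2, 3)]
    draws = rng.choice(3, size=(60, 2), p=[0.5, 0.3, 0.2])
    typings = [unambiguous_typing(unphase(alleles[i], alleles[j]))
               for i, j in draws]
    res = em_estimate(typings, universe=set(alleles))
    counts = np.bincount(draws.ravel(), minlength=3) / 120
    for k, a in enumerate(alleles):
        assert res.table.frequency(a) == pytest.approx(counts[k], abs=1e-9)


def test_em_loglik_trace_is_monotone(rng):
    for _ in range(20):
        table, _, _ = random_instance(rng, n_loci=2, n_haps=4)
        donors = [unphase(*_draw_pair(rng, table)) for _ in range(15)]
        typings = [unambiguous_typing(g) for g in donors]
        res = em_estimate(typings, universe=set(table.haplotypes))
        trace = np.array(res.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9)


def _draw_pair(rng, table):
    i = rng.choice(len(table), p=table.frequencies)
    j = rng.choice(len(table), p=table.frequencies)
    return table.haplotypes[i], table.haplotypes[j]


def grid_search_loglik(typings, haps, resolution=1e-3):
    """Exhaustive likelihood maximization over the 2-simplex for a
    3-haplotype universe (independent of the EM path)."""
    explanations = []
    idx = {h: k for k, h in enumerate(haps)}
    for t in typings:
        e = enumerate_explanations(t, set(haps))
        explanations.append(
            [(idx[a], idx[b], 1.0 if a == b else 2.0) for a, b in e.pairs]
        )
    f1 = np.arange(0.0, 1.0 + resolution / 2, resolution)
    best = -np.inf
    for x1 in f1:
        x2 = np.arange(0.0, 1.0 - x1 + resolution / 2, resolution)
        f = np.stack([np.full_like(x2, x1), x2, 1.0 - x1 - x2])
        ll = np.zeros(x2.size)
        for pairs in explanations:
            mass = np.zeros(x2.size)
            for i, j, c in pairs:
                mass += c * f[i] * f[j]
            with np.errstate(divide="ignore"):
                ll += np.log(np.maximum(mass, 0.0))  # grid edges can be -1e-18
        m = ll.max()
        if m > best:
            best = m
    return best


def test_em_attains_grid_search_maximum(rng):
    haps = [hap(("A", 1, 1), ("B", 7, 1)), hap(("A", 1, 2), ("B", 7, 2)),
            hap(("A", 1, 1), ("B", 7, 2))]
    table = HaplotypeFrequencyTable(haps, [0.5, 0.3, 0.2])
    typings = [unambiguous_typing(unphase(*_draw_pair(rng, table)))
               for _ in range(12)]
    res = em_estimate(typings, universe=set(haps), tol=1e-12, max_iter=5000)
    grid_best = grid_search_loglik(typings, haps, resolution=1e-3)
    assert res.log_likelihood >= grid_best - 1e-6


def test_em_recovery_improves_with_sample_size():
    cfg = dict(loci=("A", "B", "C", "DRB1", "DQB1"), alleles_per_locus=4,
               n_haplotypes=25, groups_per_locus=2, mask_scheme="none")
    rmse = {}
    for n in (100, 2000):
        pop = generate(SimConfig(**cfg, n_donors=n, seed=21))
        res = em_estimate([t for _, t in pop.ambiguous],
                          universe=set(pop.generating_table.haplotypes))
        err = [res.table.frequency(h) - f for h, f in pop.generating_table.items()]
        rmse[n] = float(np.sqrt(np.mean(np.square(err))))
    assert rmse[2000] < rmse[100]
    assert rmse[2000] < 0.01


def test_unexplainable_donors_are_excluded_with_count():
    h1 = hap(("A", 1, 1), ("B", 7, 1))
    h2 = hap(("A", 1, 2), ("B", 7, 2))
    good = unambiguous_typing(unphase(h1, h1))
    orphan = unambiguous_typing(
        unphase(hap(("A", 1, 3), ("B", 7, 3)), hap(("A", 1, 3), ("B", 7, 3)))
    )
    res = em_estimate([good, orphan], universe={h1, h2})
    assert res.n_excluded == 1
    with pytest.raises(ValueError):
        em_estimate([orphan], universe={h1, h2})


def test_allele_frequencies_marginalize():
    t = HaplotypeFrequencyTable(
        [hap(("A", 1, 1), ("B", 7, 1)), hap(("A", 1, 1), ("B", 7, 2)),
         hap(("A", 1, 2), ("B", 7, 1))],
        [0.3, 0.2, 0.5],
    )
    fa = allele_frequencies(t, "A")
    assert fa[allele("A", 1, 1)] == pytest.approx(0.5)
    for locus in t.loci:
        assert sum(allele_frequencies(t, locus).values()) == pytest.approx(1.0)
    with pytest.raises(KeyError):
        allele_frequencies(t, "DQB1")
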