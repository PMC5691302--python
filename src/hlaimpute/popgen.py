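"""Population-genetic verification of a typed donor sample.

Contains the nested likelihood-ratio test of Hardy-Weinberg
equilibrium against a one-parameter inbreeding alternative, the
two-sample equality-proportion test comparing sample allele-group
frequencies with a reference population, rare-allele flagging, and the
classification of donors by whether their possible haplotype pairs
were previously reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import optimize, stats

from .em import Haplotype, HaplotypeFrequencyTable, enumerate_explanations
from .model import Allele, AlleleSet, LocusGenotype, MultiLocusUnphasedGenotype


# ---------------------------------------------------------------------------
# Nested likelihood-ratio test of HWE


@dataclass
class HWETestResult:
    locus: str
    loglik_hwe: float
    loglik_alt: float
    statistic: float
    df: int
    p_value: float
    f_hat: float
    allele_freqs: dict[Allele, float]


def _genotype_groups(genotypes):
    """Normalize input (LocusGenotype or AlleleSet pairs) into grouped
    candidate-pair index arrays.

    Returns (alleles, groups) where each group is (ii, jj, multiplicity)
    over candidate unordered allele pairs for identically-typed donors.
    """
    donors = []
    alleles: set[Allele] = set()
    for g in genotypes:
        if isinstance(g, LocusGenotype):
            pairs = frozenset({tuple(sorted(g.alleles))})
            alleles.update(g.alleles)
        else:
            s1, s2 = g
            cand = set()
            for a in s1.candidates:
                for b in s2.candidates:
                    cand.add((a, b) if a <= b else (b, a))
            pairs = frozenset(cand)
            alleles.update(s1.candidates)
            alleles.update(s2.candidates)
        donors.append(pairs)
    allele_list = sorted(alleles)
    idx = {a: k for k, a in enumerate(allele_list)}
    grouped: dict[frozenset, int] = {}
    for pairs in donors:
        grouped[pairs] = grouped.get(pairs, 0) + 1
    groups = []
    for pairs, mult in grouped.items():
        ii = np.array([idx[p[0]] for p in pairs], dtype=np.intp)
        jj = np.array([idx[p[1]] for p in pairs], dtype=np.intp)
        groups.append((ii, jj, mult))
    return allele_list, groups


def _loglik_groups(groups, p, f):
    """Observed-data log-likelihood under the inbreeding model."""
    total = 0.0
    for ii, jj, mult in groups:
        het = ii != jj
        P = np.where(
            het,
            2.0 * p[ii] * p[jj] * (1.0 - f),
            p[ii] * p[ii] * (1.0 - f) + p[ii] * f,
        )
        mass = P.sum()
        if mass <= 0.0:
            return -np.inf
        total += mult * math.log(mass)
    return total


def _hwe_freqs_em(groups, k, tol=1e-12, max_iter=500):
    """MLE allele frequencies under HWE (F=0), EM over ambiguity.

    For unambiguous data every donor has a single candidate pair and
    this reduces to plain allele counting in one iteration.
    """
    p = np.full(k, 1.0 / k)
    n_donors = sum(m for _, _, m in groups)
    prev = -np.inf
    for _ in range(max_iter):
        counts = np.zeros(k)
        ll = 0.0
        for ii, jj, mult in groups:
            pr = np.where(ii == jj, p[ii] * p[jj], 2.0 * p[ii] * p[jj])
            tot = pr.sum()
            if tot <= 0:
                w = np.full(pr.size, 1.0 / pr.size)
                ll += -np.inf
            else:
                w = pr / tot
                ll += mult * math.log(tot)
            np.add.at(counts, ii, mult * w)
            np.add.at(counts, jj, mult * w)
        p = counts / (2.0 * n_donors)
        if abs(ll - prev) < tol:
            break
        prev = ll
    return p, _loglik_groups(groups, p, 0.0)


def _fit_alt_counts(I, J, N, k, p0):
    """Joint MLE of (p, F) for unambiguous genotype cell counts, by
    L-BFGS on (softmax logits, F) with the analytic gradient."""

    def negll_grad(x):
        theta = np.append(x[:-1], 0.0)
        theta -= theta.max()
        e = np.exp(theta)
        p = e / e.sum()
        f = x[-1]
        if f >= 1.0 or f <= float(np.max(-p / (1.0 - p))):
            return 1e12, np.zeros_like(x)
        het = I != J
        P = np.where(het, 2 * p[I] * p[J] * (1 - f), p[I] * p[I] * (1 - f) + p[I] * f)
        if np.any(P <= 0):
            return 1e12, np.zeros_like(x)
        w = N / P
        gp = np.zeros(k)
        np.add.at(gp, I, np.where(het, w * 2 * p[J] * (1 - f), w * (2 * p[I] * (1 - f) + f)))
        np.add.at(gp, J, np.where(het, w * 2 * p[I] * (1 - f), 0.0))
        gtheta = p * (gp - float(p @ gp))
        gf = float((w * np.where(het, -2 * p[I] * p[J], p[I] - p[I] * p[I])).sum())
        return -float((N * np.log(P)).sum()), -np.append(gtheta[:-1], gf)

    n_het = float(N[I != J].sum())
    exp_het = 1.0 - float((p0 ** 2).sum())
    f0 = 0.0 if exp_het <= 0 else float(
        np.clip(1.0 - n_het / N.sum() / exp_het, -0.5, 0.9)
    )
    p_safe = np.clip(p0, 1e-10, None)
    x0 = np.append(np.log(p_safe[:-1] / p_safe[-1]), f0)
    best = None
    for start in (x0, np.append(x0[:-1], 0.0)):
        r = optimize.minimize(
            negll_grad, start, jac=True, method="L-BFGS-B",
            options={"maxiter": 300, "ftol": 1e-13, "gtol": 1e-9},
        )
        if best is None or r.fun < best.fun:
            best = r
    theta = np.append(best.x[:-1], 0.0)
    theta -= theta.max()
    e = np.exp(theta)
    return -float(best.fun), e / e.sum(), float(best.x[-1])


def hwe_nested_lrt(genotypes, locus: str | None = None) -> HWETestResult:
    """Nested likelihood-ratio test of HWE at one locus.

    ``genotypes`` is a list of :class:`LocusGenotype` (unambiguous) or
    of ``(AlleleSet, AlleleSet)`` pairs (ambiguous typings, handled by
    summing the likelihood over candidate allele pairs).

    The null model is random union of gametes with allele frequencies
    p; the alternative adds a single inbreeding coefficient F with
    genotype probabilities ``P(ii) = p_i^2 (1-F) + p_i F`` and
    ``P(ij) = 2 p_i p_j (1-F)``.  F ranges over its full feasible
    interval — negative values (down to ``-p_i/(1-p_i)``) encode excess
    heterozygosity — so the statistic is asymptotically chi-square with
    one degree of freedom rather than a boundary mixture.
    """
    if not genotypes:
        raise ValueError("no genotypes")
    alleles, groups = _genotype_groups(genotypes)
    k = len(alleles)
    if locus is None:
        locus = alleles[0].locus
    if k < 2:
        raise ValueError(f"monomorphic locus {locus}: HWE test undefined")

    p0, ll0 = _hwe_freqs_em(groups, k)

    unambiguous = all(ii.size == 1 for ii, _, _ in groups)
    if unambiguous:
        I = np.array([int(ii[0]) for ii, _, _ in groups], dtype=np.intp)
        J = np.array([int(jj[0]) for _, jj, _ in groups], dtype=np.intp)
        N = np.array([m for _, _, m in groups], dtype=float)
        ll_alt, _, f_hat = _fit_alt_counts(I, J, N, k, p0)
        ll_alt = max(ll_alt, ll0)
    else:
        # Ambiguous typings: derivative-free maximization over
        # (softmax logits, F) of the candidate-pair-summed likelihood.
        n_donors = sum(m for _, _, m in groups)
        obs_het = 0.0
        for ii, jj, mult in groups:
            pr = np.where(ii == jj, p0[ii] * p0[jj], 2.0 * p0[ii] * p0[jj])
            tot = pr.sum()
            if tot > 0:
                obs_het += mult * float(pr[ii != jj].sum() / tot)
        exp_het = 1.0 - float((p0 ** 2).sum())
        f0 = 0.0 if exp_het <= 0 else 1.0 - obs_het / n_donors / exp_het

        def unpack(x):
            theta = np.append(x[:-1], 0.0)
            theta -= theta.max()
            e = np.exp(theta)
            return e / e.sum(), x[-1]

        def neg_ll(x):
            p, f = unpack(x)
            if f >= 1.0 or f <= float(np.max(-p / (1.0 - p))):
                return 1e12
            ll = _loglik_groups(groups, p, f)
            return 1e12 if not np.isfinite(ll) else -ll

        p_safe = np.clip(p0, 1e-10, None)
        x0 = np.append(np.log(p_safe[:-1] / p_safe[-1]), np.clip(f0, -0.5, 0.9))
        best = optimize.minimize(
            neg_ll, x0, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-10},
        )
        # Second start at F=0 guards against a bad moment start.
        alt = optimize.minimize(
            neg_ll, np.append(x0[:-1], 0.0), method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-10},
        )
        if alt.fun < best.fun:
            best = alt
        _, f_hat = unpack(best.x)
        ll_alt = max(-best.fun, ll0)
    stat = max(0.0, 2.0 * (ll_alt - ll0))
    return HWETestResult(
        locus=locus,
        loglik_hwe=ll0,
        loglik_alt=ll_alt,
        statistic=stat,
        df=1,
        p_value=float(stats.chi2.sf(stat, 1)),
        f_hat=float(f_hat),
        allele_freqs={a: float(p0[i]) for i, a in enumerate(alleles)},
    )


# ---------------------------------------------------------------------------
# Equality-proportion test against a reference population


@dataclass
class ProportionTestRow:
    locus: str
    group: str
    count_sample: int
    copies_sample: int
    freq_sample: float
    freq_reference: float
    z: float
    p: float
    minus_log10_p: float
    significant: bool


@dataclass
class ProportionTestResult:
    rows: list[ProportionTestRow]
    alpha: float
    bonferroni_alpha: float
    n_tested: int
    skipped: list[tuple[str, str]]


def equality_proportion_test(
    sample_counts: Mapping[str, Mapping[str, int]],
    n_sample: int,
    reference_freqs: Mapping[str, Mapping[str, float]],
    n_reference: int,
    alpha: float = 0.05,
) -> ProportionTestResult:
    """Two-sample proportion z-tests on allele-group frequencies.

    ``sample_counts[locus][group]`` are gene-copy counts out of
    ``2 * n_sample`` copies; the reference side contributes
    frequencies backed by ``2 * n_reference`` copies.  The Bonferroni
    threshold divides alpha by the total number of groups tested
    across all compared loci (one family-wise threshold for the run).
    """
    c1 = 2 * n_sample
    c2 = 2 * n_reference
    prelim = []
    skipped = []
    for locus in sample_counts:
        groups = set(sample_counts[locus]) | set(reference_freqs.get(locus, {}))
        for g in sorted(groups):
            x1 = int(sample_counts[locus].get(g, 0))
            if x1 > c1:
                raise ValueError(f"count {x1} exceeds {c1} copies at {locus} {g}")
            p2 = float(reference_freqs.get(locus, {}).get(g, 0.0))
            if x1 == 0 and p2 == 0.0:
                skipped.append((locus, g))
                continue
            prelim.append((locus, g, x1, p2))
    m = len(prelim)
    if m == 0:
        raise ValueError("no allele groups to test")
    bonf = alpha / m
    rows = []
    for locus, g, x1, p2 in prelim:
        p1 = x1 / c1
        pooled = (x1 + p2 * c2) / (c1 + c2)
        se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / c1 + 1.0 / c2))
        z = 0.0 if se == 0.0 else (p1 - p2) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            ProportionTestRow(
                locus=locus, group=g, count_sample=x1, copies_sample=c1,
                freq_sample=p1, freq_reference=p2, z=z, p=p,
                minus_log10_p=float(-np.log10(max(p, 1e-300))),
                significant=p < bonf,
            )
        )
    return ProportionTestResult(
        rows=rows, alpha=alpha, bonferroni_alpha=bonf, n_tested=m, skipped=skipped
    )


# ---------------------------------------------------------------------------
# Rare alleles


@dataclass
class RareAlleleReport:
    threshold: float
    per_donor: dict[str, list[Allele]]
    n_flagged: int
    fraction_flagged: float


def flag_rare_alleles(
    truths,
    reference_freqs: Mapping[Allele, float],
    threshold: float = 0.0005,
) -> RareAlleleReport:
    """Flag donors carrying alleles that are rare or absent in the
    reference frequency distribution.

    ``truths`` is a list of ``(donor_id, genotype)``; an allele is rare
    when its reference frequency is below ``threshold`` (absence counts
    as frequency zero).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    per_donor: dict[str, list[Allele]] = {}
    for donor_id, g in truths:
        flagged = []
        for lg in g.genotypes:
            for a in lg.alleles:
                if reference_freqs.get(a, 0.0) < threshold:
                    flagged.append(a)
        if flagged:
            per_donor[str(donor_id)] = flagged
    n = sum(1 for _ in truths)
    return RareAlleleReport(
        threshold=threshold,
        per_donor=per_donor,
        n_flagged=len(per_donor),
        fraction_flagged=len(per_donor) / n if n else 0.0,
    )


# ---------------------------------------------------------------------------
# Haplotype membership against reference tables


@dataclass
class MembershipReport:
    per_donor: dict[str, str]  # both_reported | partial | none_reported
    fractions: dict[str, float]
    crosstab: dict[tuple[str, bool], int]


def haplotype_membership(
    typings,
    universe,
    reference_tables,
    correctness: Mapping[str, bool] | None = None,
) -> MembershipReport:
    """Classify donors by how many haplotypes of their best explanation
    pair were previously reported.

    For each donor, all explanation pairs are delineated against
    ``universe``; a donor is ``both_reported`` when some pair has both
    haplotypes present in the union of the reference tables, ``partial``
    when at best one of the two is, and ``none_reported`` otherwise
    (including donors with no explanation at all).  When per-donor
    imputation ``correctness`` is supplied, a class-by-correctness
    cross-tabulation is included.
    """
    reported: set[Haplotype] = set()
    for t in reference_tables:
        reported.update(t.haplotypes)
    universe = sorted(set(universe) | reported)

    per_donor: dict[str, str] = {}
    for donor_id, typing in typings:
        e = enumerate_explanations(typing, universe, donor_id=str(donor_id))
        best = -1
        for h1, h2 in e.pairs:
            best = max(best, (h1 in reported) + (h2 in reported))
            if best == 2:
                break
        per_donor[str(donor_id)] = {
            2: "both_reported", 1: "partial"
        }.get(best, "none_reported")

    n = len(per_donor)
    fractions = {
        c: sum(1 for v in per_donor.values() if v == c) / n
        for c in ("both_reported", "partial", "none_reported")
    }
    crosstab: dict[tuple[str, bool], int] = {}
    if correctness is not None:
        for donor_id, cls in per_donor.items():
            key = (cls, bool(correctness[donor_id]))
            crosstab[key] = crosstab.get(key, 0) + 1
    return MembershipReport(per_donor=per_donor, fractions=fractions, crosstab=crosstab)
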