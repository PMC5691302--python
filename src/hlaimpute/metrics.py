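"""Imputation accuracy and calibration metrics.

Recall is the fraction of imputed genotypes matching the reference
(sequence-based) genotypes, at single-locus, HLA-class and multi-locus
scope.  Calibration partitions the prediction interval [0, 1] into ten
bins; within each bin the observed fraction of correct imputations is
compared with the mean predicted probability, with normal-approximation
95% confidence bounds.  The weighted city block distance d_w is the
bin-count-weighted L1 distance between observed and expected fractions
— 0 for a perfectly calibrated imputer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .em import HaplotypeFrequencyTable
from .impute import GenotypeDistribution, ImputationResult, genotype_distribution, impute_top
from .model import (
    CLASS_I,
    CLASS_II,
    GGroupMap,
    IDENTITY_GGROUPS,
    MultiLocusUnphasedGenotype,
)


@dataclass
class CalibrationBin:
    lower: float
    upper: float
    n: int = 0
    n_correct: int = 0
    expected: float | None = None  # mean predicted probability in the bin
    observed: float | None = None  # n_correct / n
    ci_lower: float | None = None
    ci_upper: float | None = None

    @property
    def has_ci(self) -> bool:
        return self.ci_lower is not None


def _match_scope(
    res: ImputationResult, truth: MultiLocusUnphasedGenotype, loci
) -> bool:
    if res.unexplainable or res.top is None:
        return False
    return all(res.top.at(l) == truth.at(l) for l in loci)


def _scope_loci(scope: str, available) -> tuple[str, ...]:
    if scope == "all":
        return tuple(available)
    if scope in ("I", "class_I"):
        return tuple(l for l in CLASS_I if l in available)
    if scope in ("II", "class_II"):
        return tuple(l for l in CLASS_II if l in available)
    if scope in available:
        return (scope,)
    raise KeyError(f"unknown scope {scope!r} for loci {tuple(available)}")


def recall(imputed, truth, scope: str = "all") -> float:
    """Fraction of donors whose call matches truth over the scope's loci.

    ``scope`` is a locus name, ``"I"``/``"II"`` for an HLA class, or
    ``"all"``.  Unexplainable donors count as incorrect.  Both sides
    are assumed already G-group standardized.
    """
    if len(imputed) != len(truth):
        raise ValueError("imputed and truth lists differ in length")
    if not imputed:
        raise ValueError("empty input")
    available = None
    n_ok = 0
    for res, t in zip(imputed, truth):
        if available is None:
            available = t.loci
        loci = _scope_loci(scope, available)
        if _match_scope(res, t, loci):
            n_ok += 1
    return n_ok / len(imputed)


def allele_recall(imputed, truth, locus: str) -> float:
    """Secondary per-allele metric: fraction of allele slots matched
    (half credit for one-of-two) at one locus."""
    total = 0
    got = 0
    for res, t in zip(imputed, truth):
        ta = list(t.at(locus).alleles)
        total += 2
        if res.unexplainable or res.top is None:
            continue
        ia = list(res.top.at(locus).alleles)
        for a in ia:
            if a in ta:
                ta.remove(a)
                got += 1
    return got / total


def calibration_bins(imputed, truth, n_bins: int = 10) -> list[CalibrationBin]:
    """Bin top-probability predictions and score each bin.

    Bins are [0, 1/n), ..., [(n-1)/n, 1].  The confidence interval is
    observed ± 1.96·sqrt(observed(1−observed)/n), clipped to [0, 1];
    it is absent for empty bins and when observed is 0 or 1 (the
    normal approximation degenerates).  Unexplainable donors carry no
    probability and are excluded.
    """
    bins = [
        CalibrationBin(lower=k / n_bins, upper=(k + 1) / n_bins)
        for k in range(n_bins)
    ]
    sums = [0.0] * n_bins
    for res, t in zip(imputed, truth):
        if res.unexplainable or res.top is None:
            continue
        p = res.top_probability
        k = min(int(p * n_bins), n_bins - 1)
        b = bins[k]
        b.n += 1
        sums[k] += p
        if all(res.top.at(l) == t.at(l) for l in t.loci):
            b.n_correct += 1
    for k, b in enumerate(bins):
        if b.n == 0:
            continue
        b.expected = sums[k] / b.n
        b.observed = b.n_correct / b.n
        if 0.0 < b.observed < 1.0:
            half = 1.96 * math.sqrt(b.observed * (1.0 - b.observed) / b.n)
            b.ci_lower = max(0.0, b.observed - half)
            b.ci_upper = min(1.0, b.observed + half)
    return bins


def weighted_city_block(bins) -> float:
    """Bin-count-weighted L1 distance between observed and expected
    correct-imputation fractions."""
    N = sum(b.n for b in bins)
    if N == 0:
        raise ValueError("all calibration bins are empty")
    return sum(
        b.n * abs(b.observed - b.expected) for b in bins if b.n > 0
    ) / N


def _marginal_trs(dist: GenotypeDistribution, combo) -> float:
    merged: dict = {}
    for g, p in dist.candidates.items():
        key = g.restrict(combo)
        merged[key] = merged.get(key, 0.0) + p
    return sum(p * p for p in merged.values())


# ---------------------------------------------------------------------------
# End-to-end validation report


#: Locus combinations reported alongside the five single loci: full
#: multi-locus, class I and class II aggregates.
def _default_combos(loci):
    combos = [tuple(loci)]
    ci = tuple(l for l in CLASS_I if l in loci)
    cii = tuple(l for l in CLASS_II if l in loci)
    if len(ci) > 1 and ci != tuple(loci):
        combos.append(ci)
    if len(cii) > 1 and cii != tuple(loci):
        combos.append(cii)
    combos.extend((l,) for l in loci)
    return combos


@dataclass
class ValidationReport:
    n_donors: int
    n_unexplainable: int
    per_locus_recall: dict[str, float]
    per_locus_allele_recall: dict[str, float]
    class_recall: dict[str, float]
    multilocus_recall: float
    bins: list[CalibrationBin]
    d_w: dict[str, float]
    mean_trs: dict[str, float]
    results: list[ImputationResult] = field(default_factory=list, repr=False)

    def to_rows(self):
        rows = [("n_donors", self.n_donors), ("n_unexplainable", self.n_unexplainable)]
        rows += [(f"recall_{l}", v) for l, v in self.per_locus_recall.items()]
        rows += [(f"recall_class_{c}", v) for c, v in self.class_recall.items()]
        rows.append(("recall_multilocus", self.multilocus_recall))
        rows += [(f"d_w[{k}]", v) for k, v in self.d_w.items()]
        rows += [(f"mean_trs[{k}]", v) for k, v in self.mean_trs.items()]
        return rows


def impute_all(typings, table: HaplotypeFrequencyTable):
    """Impute a cohort, caching by typing (masked typings repeat often)."""
    cache: dict = {}
    dists: list[GenotypeDistribution] = []
    for donor_id, typing in typings:
        hit = cache.get(typing)
        if hit is None:
            hit = genotype_distribution(typing, table)
            cache[typing] = hit
        dists.append(
            GenotypeDistribution(str(donor_id), hit.candidates, hit.unnormalized_mass)
        )
    return dists


def validate_imputation(
    typings,
    truths,
    table: HaplotypeFrequencyTable,
    ggroups: GGroupMap = IDENTITY_GGROUPS,
    n_bins: int = 10,
    combos=None,
) -> ValidationReport:
    """Run the full accuracy surface on id-aligned typings and truths.

    ``typings`` is a list of ``(donor_id, AmbiguousMultiLocusTyping)``
    and ``truths`` the matching ``(donor_id, genotype)`` reference
    calls.  Truth and imputed genotypes are both G-group standardized
    before comparison.  Per-combination d_w and mean TRS re-run the
    imputation restricted to each locus subset with the marginalized
    frequency table; per-locus recall projects the multi-locus call.
    """
    ids_t = [str(i) for i, _ in typings]
    ids_g = [str(i) for i, _ in truths]
    if ids_t != ids_g:
        raise ValueError("donor id mismatch between typings and truths")
    loci = table.loci
    truth_std = [ggroups.standardize(g) for _, g in truths]

    dists = impute_all(typings, table)
    results = []
    for d in dists:
        r = impute_top(d)
        if r.top is not None:
            r.top = ggroups.standardize(r.top)
        results.append(r)
    n_unexp = sum(r.unexplainable for r in results)

    per_locus = {l: recall(results, truth_std, l) for l in loci}
    per_locus_allele = {l: allele_recall(results, truth_std, l) for l in loci}
    class_recall = {}
    if any(l in CLASS_I for l in loci):
        class_recall["I"] = recall(results, truth_std, "I")
    if any(l in CLASS_II for l in loci):
        class_recall["II"] = recall(results, truth_std, "II")
    multilocus = recall(results, truth_std, "all")
    bins = calibration_bins(results, truth_std, n_bins=n_bins)

    d_w = {}
    mean_trs = {}
    for combo in combos if combos is not None else _default_combos(loci):
        key = "~".join(combo)
        if combo == tuple(loci):
            sub_bins = bins
            scored = [r.trs for r in results if not r.unexplainable]
        else:
            # d_w per combination: re-run imputation restricted to the
            # subset with the marginalized frequency table, then bin.
            sub_table = table.marginalize(combo)
            sub_typings = [(i, t.restrict(combo)) for i, t in typings]
            sub_dists = impute_all(sub_typings, sub_table)
            sub_results = [impute_top(d) for d in sub_dists]
            for r in sub_results:
                if r.top is not None:
                    r.top = ggroups.standardize(r.top)
            sub_truth = [t.restrict(combo) for t in truth_std]
            sub_bins = calibration_bins(sub_results, sub_truth, n_bins=n_bins)
            # TRS per combination: marginalize each donor's multi-locus
            # distribution (candidates identical on the subset merge, so
            # the subset TRS is never below the multi-locus TRS).
            scored = [
                _marginal_trs(d, combo) for d in dists if not d.unexplainable
            ]
        d_w[key] = weighted_city_block(sub_bins)
        mean_trs[key] = sum(scored) / len(scored) if scored else float("nan")

    return ValidationReport(
        n_donors=len(results),
        n_unexplainable=n_unexp,
        per_locus_recall=per_locus,
        per_locus_allele_recall=per_locus_allele,
        class_recall=class_recall,
        multilocus_recall=multilocus,
        bins=bins,
        d_w=d_w,
        mean_trs=mean_trs,
        results=results,
    )
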