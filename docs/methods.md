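# Methods

This note documents the models, estimators, defaults and numerical
conventions implemented in `hlaimpute`, and what the synthetic-data
experiments do and do not demonstrate.

## Imputation model

An observed typing at locus ℓ is an unordered pair of candidate allele
sets (S₁, S₂): each set is a singleton (explicit two-field typing), all
table alleles in a first-field group, or a multiple-allele-code
expansion intersected with the table's allele universe. A phased
haplotype pair (h_i, h_j) *explains* the typing when at every locus the
unordered allele pair {h_i[ℓ], h_j[ℓ]} uses each observed set exactly
once. Under Hardy-Weinberg equilibrium the pair has prior probability
2·f_i·f_j (i ≠ j) or f_i² (i = j), where f is the haplotype frequency
table. Pairs collapsing to the same unphased genotype are summed and
the result renormalized over the candidate set; the renormalized
distribution feeds both the top call and the typing resolution score.
The unnormalized population mass is retained on the distribution object
for callers who want it.

Conventions:

- Exact probability ties on the top call are broken by lexicographic
  order of the genotype string, so runs are deterministic.
- A typing with no explaining pair is an *unexplainable* result — an
  explicit flagged object, never an exception or a silent drop. Such
  donors count as incorrect in recall denominators and are excluded
  from TRS averages and calibration bins (they carry no probability);
  their count is reported.
- Truth and imputed genotypes are both G-group standardized before
  comparison. Alleles absent from the G-group map standardize to
  themselves, since the source format lists only groups that are
  actually ambiguous at the peptide-binding-domain exons.

## Typing resolution score

TRS is the Simpson-type concentration index Σ p_g² over the
renormalized candidate distribution: 1 iff a single candidate, 1/k for
k equiprobable candidates, low values meaning high residual ambiguity.
Per-locus and per-class TRS are obtained by *marginalizing* each
donor's multi-locus distribution to the locus subset (candidates
identical on the subset merge before squaring). Marginalization can
only merge candidates, so subset TRS ≥ multi-locus TRS donor by donor
— the pattern expected of any coherent ambiguity summary.

## Calibration and the weighted city block distance

The prediction interval [0,1] is split into ten bins [0, 0.1), …,
[0.9, 1.0]. Within each bin, `observed` is the fraction of calls
matching truth and `expected` the mean predicted probability. The 95%
bound is the normal approximation observed ± 1.96·√(obs(1−obs)/n),
clipped to [0,1] and *absent* (not zero-width) when the bin is empty or
observed ∈ {0, 1}, where the approximation degenerates. The summary

d_w = Σ_b (n_b / N) · |observed_b − expected_b|

is the bin-count-weighted L1 (city block) distance; it is 0 iff
observed equals expected in every non-empty bin and bounded by 1.
Per-combination d_w rows (single loci, A~B~C, DRB1~DQB1, all five) are
produced by re-running the imputation restricted to the locus subset
with the frequency table marginalized onto it, then binning.

Per-locus *recall*, in contrast, projects the multi-locus top call to
the locus, because the study design calls one multi-locus genotype per
donor and asks how often each locus component is right. A secondary
per-allele (half-credit) recall is reported alongside.

## EM haplotype-frequency estimation

The likelihood of a donor's typing is the sum of HWE priors over its
explanation pairs; the EM algorithm weights each pair by its current
probability within the donor (E step) and sets each frequency to half
the expected per-donor haplotype count (M step). The log-likelihood is
non-decreasing every iteration and is asserted to be in the tests.

- Initialization is uniform over haplotypes appearing in at least one
  explanation; a seed switches to a random Dirichlet start for
  multi-start exploration. The default is one deterministic run — at
  these problem sizes the likelihood is well-behaved, and
  reproducibility is worth more than a residual-risk restart.
- Convergence: log-likelihood gain < 1e-8 (default), max 1000
  iterations. Frequencies below 1e-12 are pruned at convergence and
  the rest renormalized.
- When no universe is supplied, it defaults to the union over donors
  of haplotypes buildable from a single donor's own allele sets. The
  full Cartesian product over the cohort is intractable at five loci,
  and haplotypes no donor could carry cannot gain mass from the data.
- Donors with zero explanations are excluded and counted; estimation
  with no explainable donor at all is an error.
- Identifiability: first-field-masked data constrains only group-level
  structure. Within a masked group the likelihood has flat ridges
  (e.g. all-group-homozygous donors are explained equally well by any
  split between two within-group haplotypes), and the EM then returns
  one point on the ridge determined by its start. Parameter-recovery
  claims in the tests therefore use unmasked (phase-ambiguous only)
  data.

## Nested likelihood-ratio test of HWE

Null: genotype probabilities from random union of gametes with allele
frequencies p (estimated by counting, or by EM over candidate allele
pairs when typings are ambiguous). Alternative: one extra inbreeding
parameter F with P(ii) = p_i²(1−F) + p_i·F and P(ij) = 2p_i p_j(1−F).
The statistic 2·(ℓ_alt − ℓ_null) is referred to the χ²(1) upper tail.

F ranges over its full feasible interval (max_i −p_i/(1−p_i), 1):
negative values encode excess heterozygosity. Restricting F to [0, 1]
would place the null on the boundary and turn the reference
distribution into a ½δ₀ + ½χ²(1) mixture (halving the nominal size);
the two-sided parametrization keeps the statistic asymptotically
χ²(1). The alternative is maximized by L-BFGS on (softmax logits, F)
with the analytic gradient for unambiguous data, and by Nelder-Mead on
the candidate-pair-summed likelihood for ambiguous data; a second
start at F = 0 guards against a poor moment start, and the statistic
is clipped at 0 (the models nest).

**Small-sample validity.** The χ²(1) approximation is accurate when
the feasible F interval is wide relative to the sampling error of F̂
(≈ 1/√n) and expected genotype-cell counts are not tiny. The
operating-characteristics study therefore uses a 4-allele spectrum
(0.35/0.30/0.20/0.15) at n = 144: the bound −p_min/(1−p_min) = −0.176
sits beyond 2 SD of F̂ and every expected cell count is ≥ 3. With very
rare alleles (p_min ≤ 0.05) the bound truncates the negative-F side
and the test becomes measurably conservative (empirically ≈ 0.04 at
nominal 0.05) — a known limitation, not corrected for.

## Population comparison procedures

- **Equality-proportion test**: per allele group, a two-sample
  proportion z-test on gene copies (2n per side), two-sided p from the
  pooled-variance normal approximation. The Bonferroni threshold
  divides α by the total number of groups tested across all loci in
  the run — one family-wise threshold. Groups with zero copies on both
  sides are skipped and logged.
- **Rare alleles**: an allele is rare when its reference frequency is
  below a threshold (default 5e-4, configurable; absence counts as 0);
  a donor is flagged when carrying at least one rare allele.
- **Haplotype membership**: all explanation pairs are delineated
  against a supplied universe; a donor is `both_reported` when some
  pair has both haplotypes in the union of the reference tables,
  `partial` at best one of two, `none_reported` otherwise (including
  donors with no explanation). Optionally cross-tabulated against
  per-donor imputation correctness.

## Synthetic population generator

The generator emulates the statistical structure of a registry
validation study; it does **not** model real HLA allele spectra,
linkage disequilibrium between specific alleles, or admixture.

Defaults (one value per study condition, fixed once):

| parameter | default | meaning |
|---|---|---|
| loci | A, B, C, DRB1, DQB1 | canonical five-locus panel |
| n_donors | 144 | study-scale donor panel |
| alleles_per_locus | 8 | two-field alleles per locus |
| groups_per_locus | 4 | first-field groups (2 alleles per group) |
| n_haplotypes | 120 | haplotypes with nonzero frequency |
| concentration | 0.2 | symmetric Dirichlet; small values give the steeply skewed spectra typical of HLA haplotype tables |
| inbreeding_f | 0 | HWE sampling; F>0 draws identical pairs with probability F (whole-haplotype IBD, matching the HWE-test alternative) |
| mask_scheme | first_field | also `mac_like` (random in-group subsets behind generated codes, subset size 2 by default — the real recruitment-kit ambiguity is unquantified) and `none` |
| novel_haplotype_rate | 0 | withheld-haplotype mass is rate/2, taken from the rare end, since a donor carries two haplotypes |
| rare_allele_rate | 0 | per-donor Bernoulli chance of carrying one novel allele absent from the pool |

Alleles are named systematically (`A*01:01`, `A*01:02`, …) and binned
consecutively into first-field groups, so group structure — and hence
masking entropy — is controlled directly. All randomness flows from
the config seed; identical configs give identical populations.

Masked typings always contain the truth genotype by construction (for
donors carrying injected novel alleles, the donor's own alleles are
added to the expansion universe; the imputer then reports them
unexplainable, which is the realistic outcome). Consequently, passing
tests show the pipeline is correct and calibrated *when the prior is
right*; they do not show that any real frequency table fits any real
population — quantifying that mismatch is precisely what the metrics
are for.

## Problem sizes used in the checked experiments

Oracle-equivalence checks run 1000 random instances with ≤ 4
haplotypes over ≤ 3 loci against brute-force enumeration. EM is checked
against an exhaustive 2-simplex grid search at resolution 1e-3
(3 haplotypes, 12 donors) and for parameter recovery at n = 2000
donors (RMSE < 0.01). Calibration soundness uses 5000 donors per
replicate over 50 seeds (d_w < 0.05; expected fraction inside the 95%
bound in ≥ 8 of 10 bins). The HWE test's size is estimated from 2000
null replicates at n = 144 and its power at F = 0.3. These sizes keep
every Monte-Carlo standard error small relative to the tolerance being
asserted.

## Known limitations

- Nomenclature covers first two fields plus a G-group marker; third or
  fourth fields and expression suffixes (N/L/Q) are out of scope.
- No bootstrap or asymptotic uncertainty on EM frequency estimates.
- The HWE alternative is a single whole-genome F; locus-specific or
  genotype-specific disequilibrium models are not implemented.
- Reference "previously reported" tables are whatever the caller
  supplies; no bundled registry data.
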