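# Methods

This note records the scientific and numerical choices behind the package:
what each component computes, the conventions adopted where the underlying
field definitions leave room, what the synthetic generator does and does not
emulate, and the known limitations.

## Use value

The unit of counting is the *use report*: one citation by one respondent of
one specific use. We count a respondent's reports as **distinct
(use label, plant part) pairs**, collapsing duplicate rows. The per-
respondent index `UV_j` is therefore reproducible from any row ordering and
robust to accidental double entry; the species-level `UV` is its mean over
all `N` respondents, reported with the standard error of the mean
(sample SD / √N).

Disaggregation by use category or plant part restricts the numerator to
qualifying reports but keeps the full-`N` denominator. This makes category
use values **additive**: they sum exactly to the overall UV (a property the
test suite checks on random datasets). Disaggregation by a respondent
factor instead partitions respondents and averages `UV_j` within levels.

## Informant agreement ratio

`IAR = (nr − na) / (nr − 1)` for a scope with `nr` citations over `na`
distinct plant parts; undefined for `nr = 1` and serialised as `"NA"`.
Display rounding is **half-up to two decimals**. Published versions of this
table sometimes truncate instead (e.g. 90/94 = 0.9574 shown as 0.95);
comparisons in the tests use only cells where both conventions agree.

## KMTO coding

Kernel, Mutation, Type and Order are coded per knowledge-source relation as
described in `ethnosurvey.kmto`. The conventions for relations the
framework's definitions leave open are isolated in one table
(`_RELATION_CODES`):

* spouse → internal, horizontal (same generation, inside the household);
* cousin → internal, horizontal; uncle/aunt → internal, **vertical with
  order 0** — orders 1–2 are reserved for progenitors and grandparents, so
  this is the single relation whose path falls outside the 16 structurally
  valid ones and carries `structurally_valid=False`;
* self-learning → internal, transversal, with a same-sex "transition"
  mutation by convention (source = self);
* community-type sources (friend, community, healer) are external and
  horizontal, and carry whatever transmitter gender the informant reported
  — nothing is inferred.

Both the full 36-path product and the 16-path structurally constrained
enumeration are exposed; neither is silently preferred.

Attribute-level proportion tests tally over an attribute's **full state
space**, so a never-observed state contributes a zero cell (evidence
against equal proportions) instead of silently shrinking the test.

## Statistical harness

* Equal-proportions and independence chi-squares are Pearson statistics
  without continuity correction.
* The independence test falls back to Fisher's exact test whenever **any**
  expected cell count is below 5 — exact for 2×2; for larger tables a
  Monte-Carlo p over 10⁵ Patefield-sampled tables with fixed margins and a
  fixed seed, using the conditional table probability as the ordering
  statistic and the add-one correction `(hits + 1)/(B + 1)`.
* Count models are log-link Poisson GLMs fitted by IRLS (statsmodels
  backend, parameter tolerance 1e-8, 100 iterations; non-convergence raises
  with the deviance trace). The Pearson dispersion
  `Σ r_P² / (n − p)` is always reported; when it exceeds the threshold
  (default 1.5, configurable) standard errors are scaled by √dispersion and
  the fit is labelled quasi-Poisson. Point estimates are identical under
  both families. The recorded deviance trace starts at the first true
  coefficient iterate (the backend's first two history entries are
  initialisation placeholders).
* Spearman p-values use an exact permutation distribution for n ≤ 10
  (all n! rank pairings, evaluated vectorised) and the usual approximation
  above; Pearson via the standard t reference.
* Fisher's r-to-z comparison uses
  `Z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))` with a two-sided
  normal p. One published Z value for a between-group comparison is not
  recoverable from the printed r and group sizes under this standard
  formula (the subset sizes actually used are unstated); the implementation
  makes no attempt to match it.

## Trees

Classification trees (binary outcomes) split greedily on the decrease of
the Gini impurity sum; regression trees on the between-node sum-of-squares
reduction. Categorical features are bipartitioned after ordering levels by
positive-class rate / mean response — exact for binary outcomes and squared
error, and checked in the tests against exhaustive bipartition oracles for
up to 8 levels. Defaults copy the conventional values of the rpart family:
`min_split` 20, `min_bucket` ⌈min_split/3⌉, `cp` 0.01 (as a fraction of the
root impurity a split must recover), `max_depth` 30. Ties in split quality
are broken by (feature name, partition) enumeration order, making fits
platform-deterministic.

Pruning is weakest-link cost-complexity: the nested subtree sequence is
indexed by `g(t) = (R(t) − R(T_t))/(|leaves| − 1)` with risk `R` measured
as misclassification count (classification) or SSE (regression); seeded
10-fold cross-validation evaluates the sequence at geometric-mean alphas
and the tree is pruned at the larger of the CV-optimal alpha and
`cp · R(root)`. `cp = 0` leaves the tree untouched; `cp = ∞` collapses it
to the root. Unseen categorical levels at prediction time are routed to
the side that held the training majority, with a warning. Missing-value
handling and surrogate splits are out of scope (the generator emits
complete data).

## Synthetic generator

The generator emulates the published study design so the full pipeline is
exercisable end to end:

* **Respondents.** Group sizes fixed at the documented values (sum 510);
  gender, age class, schooling, activity, religion and migratory status
  drawn per group from the documented percentage table (columns
  renormalised where printed rounding leaves them at 99.9x %). Ages are
  uniform within the age-class bounds (young 18–29, adult 30–59,
  old 60–90): the bounds are documented, the interior is not.
* **Ownership.** Bernoulli at 366/510; owners draw
  `1 + NB(mean − 1, k)` trees (negative binomial, shape k = 1 by default —
  the same overdispersion the count models are built to absorb; k = 0
  selects Poisson). Akan (14.15) and Holli (1.68) means are documented;
  the remaining groups are plausible calibrations following the
  Ghana-owns-more narrative and are **not** published values.
* **Use reports.** Non-medicinal categories are cited at most once per
  respondent (Bernoulli at the category propensity: sweetener 497/510,
  sales 112/510, social 128/510, magico-spiritual 176/353 within Benin
  only, firewood 1/53 among the Ewe only); the medicinal citation count is
  Poisson with mean 341/510, drawn without replacement over body systems.
  Specific uses are drawn proportionally to documented citation counts and
  parts uniformly from each use's admissible part list, so agreement
  ratios and part constraints are recoverable. The per-country category
  split is documented; the per-group fine structure is only published
  graphically and is an order-of-magnitude calibration here.
* **Cultivation outcomes.** Willingness follows a tree-structured rule
  (Akan/Ga-adangbe largely unwilling; taboo-aware respondents strongly
  willing; otherwise market perception interacting with schooling) whose
  raw probabilities are rescaled on the realised sample so the expected
  marginal equals 45 % — giving the driver trees recoverable structure
  rather than an unconditional coin flip. Willing respondents draw acreage
  from a gamma (shape 4 by default; shape 0 degenerates to the exact mean)
  centred on the documented (schooling × growth-perception) leaf means
  0.2 / 0.4 / 0.83 / 1.8 ha, and price on the activity/age/group strata
  1.4 / 0.41 / 2.1 / 0.46 USD (one published price is typographically
  ambiguous between 0.4 and 0.46; the generator uses 0.41).

What the generator does **not** emulate: free-text content (local names,
recipes), spatial structure, interviewer effects, missingness, or
correlations between demographics beyond the per-group marginals. Passing
recovery tests on this generator therefore demonstrates that the
estimators and trees recover the structure they were designed for at the
study's sample sizes — not that they would be unbiased on real field data
with those extra complications.

## Problem sizes and reproducibility

Recovery checks run at the study scale (one 510-respondent dataset for
marginals) or pooled over ten seeded replicates (≈2 300 willing
respondents) for tree leaf-mean recovery — enough for the 3-SE and 15 %
bands used in the tests while keeping the whole suite under half a minute.
Every stochastic component takes a `numpy` Generator seeded through stable
per-stage labels derived from one root seed; identical configuration and
seed reproduce identical CSV/JSON artifacts byte for byte, and the pipeline
manifest records the seed, a configuration hash and per-file checksums.

## Known limitations

* Classification trees support binary outcomes only (the one classified
  target is binary); multiclass Gini ordering loses the bipartition
  optimality guarantee and is not offered.
* The Monte-Carlo Fisher p is a simulation estimate (SE ≈ 0.0015 at
  p = 0.5 with 10⁵ draws); exact network algorithms for general r×c tables
  are out of scope.
* Several published whole-survey statistics (the overall UV of 2.45,
  printed χ²/t values, full tree topologies) depend on the raw
  510-respondent data, which is not deposited; they are covered here by
  calibration targets and structural-recovery checks, not by exact
  replication.
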