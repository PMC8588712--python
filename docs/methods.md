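# Methods

## The estimand and the decision rule

For a categorical dataset with exactly one incompletely observed variable
`X`, define the missing indicator `M = 1{X missing}`. The *missing data
structure* is the Bayesian-network DAG over `M` and the fully observed
variables. Its interpretation follows directly from the Markov properties:
an arc between `M` and another variable encodes conditional dependence of
the missingness on that variable, and the absence of any arc incident to
`M` encodes MCAR. The mechanism verdict is therefore a function of two
things only: the skeleton adjacencies of `M`, and whether the learned
structure passed credibility assessment.

| credible? | `M` adjacent to anything? | verdict |
|---|---|---|
| no | — | INCONCLUSIVE (structure cannot be trusted) |
| yes | no | MCAR |
| yes | yes | NOT_MCAR_MAR_OR_MNAR |

MAR cannot be separated from MNAR: dependence of `M` on the unobserved
values of `X` is not testable because those values are never seen. The
package does not attempt it, and multivariate missingness (two or more
incomplete variables) is rejected with an explicit error rather than
approximated.

## Structure learning

Greedy hill climbing from the empty graph: at each iteration every
admissible single-arc addition, deletion and reversal is scored, and the
operation with the largest improvement above `improvement_epsilon`
(default 1e-9) is applied; the search stops at a local optimum. Candidate
operations are enumerated in a fixed order (additions, then deletions,
then reversals; lexicographic by parent then child within each class) and
ties go to the first candidate, so learning is fully deterministic for a
given dataset and configuration. No restarts or tabu list are used; on
the small variable sets this method targets, the plain search already
attains the exhaustive-search optimum essentially always (verified by
enumeration over all 25 three-node DAGs in the test suite).

The default score is the BIC for multinomial families,
`log L − (ln n)/2 · (r−1)q` per node, which is decomposable (only the
touched families are rescored, with a per-family memo) and
score-equivalent (Markov-equivalent DAGs score identically, so learned
orientations within a class are tie-break artifacts). A BDeu score with
configurable equivalent sample size (default 1) is available via
`ScoreConfig(score_name="bdeu")`. Zero-count configurations contribute
zero log-likelihood; the BIC penalty always counts the full `(r−1)q` free
parameters, including unobserved parent configurations.

Parameter learning is Bayesian: each CPT row is the posterior mean under
a symmetric Dirichlet prior whose total weight (default 1 per family) is
split uniformly over the family's cells, so rows for parent
configurations never observed default to uniform and no row is ever
undefined. Only categorical variables are supported; continuous variables
are out of scope and rejected at the dataset layer, which requires
declared or observed level sets.

CPDAGs are computed as v-structure orientations closed under the Meek
rules R1–R3; R4 only fires when background-knowledge orientations are
present, which never happens when starting from v-structures alone. The
implementation is verified against the skeleton-plus-v-structure
characterisation of Markov equivalence by brute force over all 25
three-node and 543 four-node DAGs.

## Credibility and expert comparison

The bootstrap resamples the prepared dataset's rows with replacement
(resampling rows of the raw table and re-deriving the indicator is the
same operation, since preparation is row-wise), relearns the structure on
each of `N` replicates (default 10,000; tests and the reduced study use
less), and computes each unordered pair's skeleton frequency. The learned
structure is credible iff every one of **its** relations has frequency at
or above the threshold (default 0.90; "more than 90%" is implemented as
`≥`, indistinguishable at bootstrap granularity). Replicates are free to
contain extra relations — credibility asks whether the learned relations
are reproducible, not whether the whole structure is unique. A
whole-structure reading of the assessment can be recovered by comparing
CPDAGs across replicates with `validity`, but relation-level verification
is the implemented rule.

Real-study consistency against an expert structure is, per unordered
pair, the percentage of replicates whose skeleton agrees with the expert
on that pair's presence; inconsistency is its complement.

## The simulator

`generate_complete` draws i.i.d. records of the binary chain
`tumor_type → operation → twoweeks` with

* P(tumor_type = 1) = 0.58,
* P(operation = 1 | tumor_type = 0) = 0.89, P(operation = 1 | tumor_type = 1) = 0.62,
* P(twoweeks = 0 | operation = 1) = 0.51, P(twoweeks = 0 | operation = 0) = 0.65,

so the implied operation marginal is P(op) = 0.7334. Missingness is
imposed only as the indicator — no latent fee values are generated,
because no stage of the method consumes them; `to_raw_with_missing`
materialises a raw-looking `fee` column (observed placeholder / missing
cell) when an end-to-end run through preparation is wanted.

* **MCAR**: indicator i.i.d. Bernoulli(p), p ∈ {0.05, 0.10, 0.15, 0.20}
  in the standard grid.
* **MAR**: group rates `(p1, p2)` for the non-operation / operation
  groups solve `p1 = ratio · p2` (default ratio 2.5) and
  `p1·P(no op) + p2·P(op) = p` in closed form. `P(no op)` is the
  theoretical marginal (0.2666), not the realised sample fraction, so the
  group rates are constants of the scenario rather than per-sample
  quantities.

Each realization uses an independent RNG stream seeded by
`(scenario seed, realization index)`, so any replicate can be regenerated
in isolation. The generator emulates the dependence structure, marginals
and missingness rates of a real clinical cohort but nothing else: no
measurement error, no covariate richness beyond three binaries, and a
perfectly correct categorical model. Passing the simulation tests shows
the method recovers structures of this size and effect strength at
n = 2000; it does not certify behaviour on weaker effects, larger
variable sets, or ordinal/continuous data.

## Performance measures

* **validity** — fraction of replicates whose learned structure equals
  the generating one. The default comparison is CPDAG equality, the
  statistically identifiable target; `skeleton` and exact-`dag` modes
  exist, the latter mainly to probe how tie-breaking orients arcs.
  Direction-specific consistency splits are deliberately not a supported
  comparison target: they are artifacts of candidate enumeration order.
* **simulation consistency** — per pair, the fraction of replicates whose
  presence/absence status matches the truth (skeleton level by default).
* **robustness** — the spread of validity across the four missing rates
  of one mechanism. It is reported as the sample *standard deviation*;
  the sample variance is exposed under `kind="var"`. The sd is the
  headline because it is the reading consistent with the reference
  values this package reconciles (sd of {0.9698, 0.9727, 0.9686, 0.9697}
  → 0.0018; sd of {0.9334, 0.9794, 0.9790, 0.9825} → 0.0235).
* **logistic comparator** — the classical alternative regresses `M` on
  the observed variables (binomial GLM on aggregated covariate patterns,
  i.e. IRLS, via statsmodels) and tests. Its validity uses the global
  likelihood-ratio test at α = 0.05: correct = non-rejection when no
  true relation exists, rejection otherwise. This is the reading under
  which the comparator's MCAR validity sits near 1 − α ≈ 0.95 with three
  predictors. A per-coefficient Wald rule (significant set must equal
  the truly related set) is available; under MAR the two rules differ
  (the global test has power ≈ 1 here) and no attempt is made to tune
  between them.
* **contingency statistics** — 2×2 chi-square uses the Yates continuity
  correction by default; the uncorrected statistic equals the classical
  `n(ad−bc)²/…` formula (property-tested), but the corrected one is the
  default because it is what the reconciled reference values use.

## Problem sizes and numerical choices

The shipped studies use n = 2000 per replicate. The test suite and the
acceptance script run 1,000 replicates per scenario (Monte-Carlo se of a
validity near 0.97 ≈ 0.005, comfortably inside the ±0.02 comparison
bands); the full 10,000-replicate grid is a one-line change
(`default_scenarios(reps=10_000)`) and scales linearly (~10 s per 1,000
replicates per scenario on one core). Calibration checks of the generator
use n = 200,000 and 3-standard-error bands. CPT validity requires rows to
sum to 1 within 1e-9; the logistic fit uses tolerance 1e-8 with at most
50 IRLS iterations, flags |coefficient| > 15 as probable separation, and
drops observed-constant predictors with a warning.

## Known limitations

* Univariate missingness and categorical variables only, by design.
* MAR vs MNAR is not, and cannot be, distinguished.
* Hill climbing is a local search; determinism is guaranteed, global
  optimality is not (it is only verified empirically at the studied
  sizes).
* Credibility is a reproducibility check, not a posterior probability;
  with very small n the bootstrap can be confidently wrong in the same
  direction as the original fit.
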