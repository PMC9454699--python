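# Methods

## Problem and model

Given a cohort of patients with (i) an FPKM-like expression matrix, (ii) a
molecular-subtype label drawn from an ordered vocabulary `S_1 < … < S_K`
(best to worst prognosis), and (iii) right-censored overall survival, the
package searches for a signed gene set whose induced patient ordering
simultaneously respects the subtype order and separates prognosis within
each subtype.

### Chromosome and risk score

A gene set is a ternary vector over the gene universe: `+1` (selected, high
expression adverse), `−1` (selected, low expression adverse), `0`
(unselected). For a `+1` gene patients are ranked ascending by expression,
for a `−1` gene descending, ranks 1-based with average (fractional) ranks at
ties. The risk score of a patient is the unweighted mean of their per-gene
ranks. Two consequences used throughout the tests: each gene's ranks sum to
`n(n+1)/2`, so the mean risk score over patients is always `(n+1)/2`; and
the score depends on expression only through per-gene ranks, so it is
invariant under any strictly increasing per-gene transform. The reported
patient ordering sorts risk ascending with ties broken by clinical-table
position (reproducibility only; the scores themselves handle ties).

### Fitness

`F = stratification + λ · survival`, default `λ = 0.5`.

**Stratification** is Kendall's τ-b between the subtype sequence in risk
order and the same multiset of labels sorted into the subtype order,
`(P − Q)/√((P+Q+T)(P+Q+U))`, where `T`/`U` count pairs tied only in one of
the two sequences (pairs tied in both count in neither). The implementation
delegates to `scipy.stats.kendalltau(variant="b")`; a brute-force O(n²)
pair-enumeration oracle in the test suite checks exact agreement (< 1e-12)
on random sequences. A sequence with a single distinct subtype has a
vanishing denominator and is defined as 0 with a warning. Two analytic
caveats verified against the oracle and asserted in the restricted forms in
which they are true: τ-b of an exactly reversed reference is −1 only when
the subtype-size vector is palindromic (otherwise tied pairs migrate into
`T`/`U`), and reversal antisymmetry holds only for tie-free sequences.

**Risk groups.** For each adjacent subtype pair a one-feature logistic
regression (feature = risk score, label = membership of the worse subtype)
is fitted on the patients of those two subtypes; the boundary is the risk
score at probability 0.5 (`−intercept/slope`). End subtypes are split in 2
by their single adjacent boundary, interior subtypes in up to 3 by both;
patients exactly on a boundary go to the lower-risk side. The fit is a
self-contained Newton-IRLS on centred/scaled scores. Degenerate fits are
resolved deterministically: perfectly separated classes → midpoint of the
gap between the classes; non-positive slope (inverted relation) → midpoint
of the two class medians, logged. The GA only needs a usable split — a bad
ordering is penalised by the score itself, not by the boundary fit.

**Survival.** Every adjacent within-subtype group pair (lower-risk A,
higher-risk B; `2K − 2` pairs in total) contributes `f = c · l`:
`c = +1` iff a two-group Cox fit estimates hazard(B) > hazard(A), and
`l = −log10(p)` of the two-group log-rank test, clipped at `−log10(b)`
(default `b = 0.01`, so `l ∈ (0, 2]`). The clipping bounds the influence of
any single very significant pair, making the score an average of
commensurate terms in `[−2, 2]`. A pair with an empty group or a group with
no observed events is *degenerate* and contributes 0 — prognosis-neutral, so
imperfect chromosomes remain evaluable. The Cox fit is a single-binary-
covariate Newton iteration with step halving on the Breslow partial
likelihood (tolerance 1e-8, max 50 iterations, |log HR| capped at 20 under
monotone likelihood — the cap preserves the sign, which is all `c` needs).
The log-rank tests (two-group and the k-group variant reported per subtype
in validation) are the standard hypergeometric-variance chi-square tests.
These primitives are written in-package because the GA evaluates thousands
of tiny fits per generation; the test suite cross-checks them against
lifelines (log-rank; Cox on tie-free data, where Efron and Breslow
coincide), against a directly maximised Breslow likelihood on tied data, and
against scikit-learn for the logistic boundary.

### Genetic algorithm

Island model: `n_subpopulations × subpop_size` (default 10 × 150;
scaled-down studies in this repository use 4 × 50). Per generation and
island: the `elite_count` (2) best survive unchanged; the rest are produced
by tournament selection (k = 3), uniform crossover (probability 0.9, swap
probability 0.5 per position) and mutation; every `migration_interval` (10)
generations each island's best replaces the worst of the next island on a
ring. One root seed spawns independent per-island RNG streams, so results
are reproducible regardless of evaluation order; fitness is cached by
chromosome content and λ phase.

Mutation hits each position with probability `1/n_genes`; a `0` becomes
`±1` with equal probability, a nonzero drops to `0` with probability 0.7 or
flips sign with 0.3. The drop-favouring kernel is deliberate: resampling
uniformly over `{−1, 0, +1}` drifts chromosomes toward 2/3 density and
destroys the sparse-signature character of the method. Initial chromosomes
draw each gene nonzero with probability 0.03 (the scale of reported
signatures relative to a transcriptome); all-zero chromosomes get one random
nonzero gene.

**Two-phase schedule.** Runs start at `λ = 0` (pure subtype stratification):
with a random initial ordering the group boundaries would be meaningless.
Once the fraction of chromosomes with stratification > 0.75 reaches 0.95 of
the whole population, the survival term activates at the configured λ and
never reverts; caches are invalidated and the patience counter resets.
Termination requires both the survival-active phase and `stagnation_patience`
(10; 5 in the scaled-down studies) generations without best-fitness
improvement (> 1e-12); a `max_generations` cap (1000) guards pathological
configurations. The λ = 0 phase cannot terminate a run — otherwise the
two-phase dynamics could never unfold. The per-generation history additionally
records the best chromosome's survival score before activation (computed for
the trace, not the fitness) and the population fraction above the activation
threshold, so the schedule is auditable from the trace alone.

## Synthetic cohorts

The generator emulates the two premises the method rests on — subtype order
correlated with outcome, and genes whose high *or* low expression is
adverse — without attempting to reproduce any real cohort's marginal
distributions, batch structure or gene–gene correlations. Passing tests
therefore demonstrate correctness of the machinery and recoverability of
planted signal under the model's own assumptions, not performance on real
data.

Defaults (one cohort = one `SimConfig`):

* `n_samples = 300`; four subtypes at proportions 0.54/0.24/0.11/0.11
  (echoing a large breast-cancer cohort's subtype mix);
* 500 genes: 15 planted `+1`, 15 planted `−1`, 470 i.i.d. lognormal noise
  (`n_subtype_genes` adds trend-only genes when nonzero);
* expression lognormal (FPKM-like skew; irrelevant to the rank-based core);
* planted genes trend along the subtype order at `subtype_effect = 0.3` SD
  per subtype step (+1 genes rise, −1 genes fall) *and* drive the hazard.
  The coupling mirrors real signatures (proliferation genes mark both worse
  subtypes and worse prognosis) and is what lets a single gene set satisfy
  both fitness terms. The scale is chosen from the aggregate: a 30-gene
  mean-rank score separates adjacent subtypes by ≈ `0.3·√30 ≈ 1.6` SD,
  which yields overlapping subtype distributions and an oracle
  stratification of ≈ 0.8 — the regime the method is designed for. (Much
  larger effects make subtype separation perfect, every boundary falls in a
  between-subtype gap, and the within-subtype survival machinery goes
  degenerate — a regime that defeats the purpose of the score.)
* hazard: exponential (Weibull shape exposed for PH-preserving stress
  tests) with baseline 2.0/3.0/4.5/6.5 × 10⁻⁴ per day increasing along the
  subtype order, times `exp(η)` with
  `η = prognostic_effect · Σ(direction-aligned gene z-scores)/√30` and
  `prognostic_effect = 1.0` — one SD of the planted signature multiplies the
  hazard by e. Defining the effect per SD of the *aggregate* keeps the
  hazard range realistic regardless of how many genes are planted.
* independent exponential censoring, rate calibrated by bisection so the
  expected censored fraction is `censoring_rate = 0.4` (long-follow-up
  registry regime; enough events at n = 300 for within-subtype tests).

`oracle_chromosome` returns the exactly-planted gene set and serves as an
upper reference in tests; `GroundTruth.latent_risk` stores η for
association checks.

## Validation and ensembles

Only gene directions transfer to a validation cohort: ranks, risk scores,
stratification, boundaries, the survival score and per-subtype k-group
log-rank p-values are recomputed inside that cohort (a validation survival
score requires locally fitted groups). Genes absent from the validation
universe are dropped with a warning; zero overlap is an error.
`ensemble_runs` repeats the GA with seeds derived from one root seed and
aggregates pairwise Spearman correlations of the patient orderings and
per-gene selection counts split by direction; `frequent_genes` filters them
by a minimum count.

## Numerical and design choices

* The τ-b denominator carries the square root of the standard statistic
  (the tie-corrected geometric mean of comparable pair counts); without it
  the quantity would not be bounded by 1.
* Boundaries are fitted per adjacent subtype pair (K − 1 fits), each
  splitting both neighbouring subtypes — the only reading under which end
  subtypes get 2 groups and interior subtypes 3.
* `c` reads the relative hazard of the higher-risk group vs the lower-risk
  group from one two-group fit (reference level = lower-risk group).
* Expression orientation on disk is never guessed (`genes-as-rows` default,
  explicit flag); clinical-table order defines cohort sample order; no
  normalisation is applied before ranking (per-gene monotone transforms
  cannot change any result).
* Run manifests record seed, config digest, input digests and version — no
  wall-clock timestamp, so reruns are byte-identical.
* Scaled-down study sizes used by the tests and the reproduction script
  (cohort 300 × 500, GA 4 × 50 with patience 5, ensembles of 5 runs at
  2 × 40) were chosen as the smallest sizes at which the planted-signal
  properties are comfortably detectable.

## Limitations

* The Cox comparisons are unadjusted (no age/stage covariates), matching the
  method's definition; confounding in real cohorts is out of scope.
* The generator draws genes independently; correlated blocks, batch effects
  and platform effects are not emulated, so transfer results here bound the
  idealised, not the realistic, case.
* A single GA run overfits noise genes alongside the planted signal
  (selection frequency across repeated runs is the intended remedy, as the
  ensembles show).
* With a single distinct subtype the stratification score degenerates to 0;
  the method presupposes K ≥ 2 ordered subtypes.
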