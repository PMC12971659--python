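# Methods

This note documents the models implemented in `oshprior`, the numerical
and design choices behind them, and what the bundled case study and the
synthetic-matrix generator do and do not demonstrate.

## Decision model

A decision problem is an `n × m` matrix `X = [x_ij]` of strictly
positive scores for `n ≥ 2` alternatives against `m ≥ 2` criteria, each
criterion flagged benefit (+1) or cost (−1). Strict positivity is
enforced at load time for every matrix — not only where a formula
immediately needs it — because the weighting and aggregation stages take
reciprocals (`Σ 1/x_ij`), logarithms (`q ln q`) and fractional powers
(`r^w`) of the entries, and a zero admitted anywhere would surface as a
cryptic downstream failure.

Normalization is `r_ij = x_ij / max_i x_ij` for benefit columns and
`min_i x_ij / x_ij` for cost columns, mapping every column onto `(0, 1]`
with the best alternative at 1. It is applied even when all scores share
one uniform scale (as in the bundled 1–9 case study): the appended ideal
and anti-ideal reference rows are defined on the normalized matrix, and
skipping normalization would silently change the benchmarking geometry.
The ideal profile `R⁺` (per-column max of `r`) and anti-ideal profile
`R⁻` (per-column min) are derived from the observed alternatives, not
from theoretical scale bounds: the references are meant to be the best
and worst *attainable* performance in the candidate set.

## Objective weighting

All four schemes operate on the raw matrix `X`, with one deliberate
exception noted below.

**Entropy.** Column shares `q_ij = x_ij / Σ_i x_ij`, Shannon entropy
`E_j = −(1/ln n) Σ q ln q` with the convention `0·ln 0 = 0`, weight
∝ `1 − E_j`. A constant column carries no information (`E = 1`,
weight 0); a matrix of only constant columns is an error, not a silent
uniform vector.

**CRITIC.** `I_j = s_j · Σ_k (1 − γ_jk)` with `s_j` the column standard
deviation and `γ` the Pearson correlation between raw columns, then
normalized. The `j = k` term contributes zero, so the sum may run over
all `k`. The standard-deviation convention (sample vs population) scales
every `I_j` by the same factor and cancels in the normalization; a
property test asserts this invariance. A constant column makes the
correlation undefined and is an error. The degenerate case where all
columns are perfectly correlated (zero conflict everywhere) returns
equal weights by symmetry rather than 0/0.

**Removal effect.** The composite score of alternative `i` is the
equal-coefficient mean `P_i = (1/m) Σ_j r_ij` of its *normalized* row
(the coefficient inside `P_i` cannot itself be the weight vector being
solved for, so equal coefficients are the resolved reading). Dropping
criterion `j`'s term while keeping the `1/m` coefficient changes `P_i`
by exactly `r_ij / m`; the removal effect of `j` is therefore the
column sum of `r` up to a constant, and the weights are the normalized
column sums of the normalized matrix. A brute-force literal-removal
oracle in the test suite confirms the closed form. This scheme is the
one place weighting consumes the normalized matrix — running it on raw
scores produces a different (scale-dependent) vector, whereas the
normalized form is scale-invariant per column and reproduces the
bundled case study's published weight row. The canonical logarithmic
removal-effect method (`P_i = ln(1 + mean |ln r|)`) is available behind
`variant="logarithmic"` for comparison; it is a different statistic and
is labeled as such in its `method_id`.

**Impact loss.** `T_j = Σ_i 1/x_ij` on raw scores, normalized. This
reciprocal-sum form rewards criteria on which alternatives score poorly.
It differs from the canonical criterion-impact-loss method (which builds
a square loss matrix from per-criterion champions); the canonical method
is out of scope here and the reciprocal-sum form is the one implemented
and documented.

**Fusion.** The fused vector is the Bonferroni mean with `p = q = 1`
over the `K` method vectors, per criterion:
`BM_j = sqrt( Σ_{k≠L} w_j^(k) w_j^(L) / (K(K−1)) )`, computed through
the closed form `(Σ_k w)² − Σ_k w²` and renormalized to unit sum. It is
symmetric in the input order and fixes identical inputs. The case
study's published fused vector is *not* exactly the `p = q = 1`
Bonferroni mean of its four published method vectors — no standard
Bonferroni variant we tested reproduces it to four decimals; the mean
lands within 0.02 elementwise with the identical criterion importance
order (C1 > C6 > C5 > C2 > C4 > C3). The published vector therefore
ships as the constant `CASE_STUDY_FUSED_WEIGHTS`, and every exact
downstream reproduction consumes that constant, while `--weights auto`
exposes the package's own fusion. Under the computed fusion the top
three of every method ranking and the consensus podium are unchanged;
the closely scored A1/A5 tail can swap.

## MARCOS

Weighted normalized scores `u_ij = r_ij w_j` sum to `Q_i`; with
all-benefit criteria and unit-sum weights the ideal row's score `Q⁺` is
exactly 1, so `λ⁺_i = Q_i/Q⁺ = Q_i` (visible in the case-study tableau).
The utility is the standard MARCOS function

    U_i = (λ⁺ + λ⁻) / (1 + (1 − f⁺)/f⁺ + (1 − f⁻)/f⁻),
    f⁺ = λ⁻/(λ⁺ + λ⁻),  f⁻ = λ⁺/(λ⁺ + λ⁻).

A simple-ratio form `U = λ⁺/λ⁻` is sometimes written instead, but it is
algebraically constant (`Q⁻/Q⁺`) across alternatives and cannot produce
a ranking; the standard function reproduces every published case-study
utility including the ideal (0.8443) and anti-ideal (0.4487) rows, and
is the corrected reading implemented here. `U` is strictly increasing in
`Q` at fixed references, so MARCOS cannot reverse the weighted-sum order
within one run — its contribution is the utility scale, anchored to the
attainable range, not a different order.

## Benchmark rankers

Method variants are fixed (the comparison is only meaningful when each
method runs in one well-defined configuration):

* **TOPSIS** — vector (root-sum-square) normalization, Euclidean
  distances, closeness `D⁻/(D⁺+D⁻)`.
* **VIKOR** — linear max−min normalization, `v = 0.5`, single complete
  ranking by ascending `Q` with no acceptable-advantage screening. A
  criterion with zero range contributes zero distance. Stored scores are
  `−Q` so every `RankingResult` is higher-is-better; reports print the
  raw `Q`.
* **EDAS** — arithmetic-mean average solution; if every alternative has
  zero positive (or negative) deviation the corresponding normalized
  component is defined as 1 for all.
* **WASPAS** — `λ = 0.5` mix of weighted sum and weighted product on the
  max-normalized matrix; `λ = 1` reduces exactly to the MARCOS `Q`
  column.
* **PROMETHEE-II** — usual (0/1) preference criterion on raw scores,
  no indifference/preference thresholds; net flows sum to zero.

Ties in any score vector share the average rank.

On the bundled case study these choices reproduce the published rank
structure: A3 first under MARCOS/TOPSIS/EDAS/WASPAS/PROMETHEE-II, A4
first under VIKOR, A2 second everywhere, and PROMETHEE-II's order equal
to MARCOS's. The published material reports the methods' pairwise
correlations rather than every full order; the A1/A5 tail orders used in
the test fixtures are reconstructed from those correlation values and
verified self-consistent against the recomputed score oracles.

## Rank concordance

Kendall's τ is tau-a — `(N_c − N_d)/(n(n−1)/2)` with ties counted as
neither concordant nor discordant — matching the plain denominator of
the definition used by the case study (for `n = 5`, one adjacent
transposition gives τ = 0.8 exactly). Spearman's ρ is the classical
`1 − 6Σd²/(n(n²−1))`, falling back to the product-moment correlation of
the rank vectors under ties. Row means of the correlation matrices
**include the diagonal self-correlation of 1** by default. This is
non-standard but deliberate: it is the convention under which the case
study's published summary values arise (the VIKOR row mean τ of 0.433 is
`(0.2+0.4+1+0.4+0.4+0.2)/6`). `include_diagonal=False` (CLI:
conventional means) divides the off-diagonal sum by `M − 1` instead.

## Sensitivity analysis

One-at-a-time perturbation: `ω′_h = ω_h ± ε`, with the mass
redistributed equally over the other `m − 1` criteria, for every
criterion, ε level, and sign — `2·m·|levels|` scenarios, each conserving
the unit sum. With the bundled weights and ε ∈ {0.05, 0.10, 0.15} this
yields 36 scenarios of which exactly three (−0.15 on C2, C3, C4) drive
the focal weight negative. The default policy `include` uses those
vectors as-is — the published tabulations total 36 scenarios per row
even while declaring 33 feasible, so retaining all 36 is the reading
that matches the published accounting; `skip` and `clamp` are available.

**Known divergence.** The *interior* counts of the published
rank-frequency table do not reproduce under this (or any standard)
perturbation convention: the recomputed table matches all row sums and
the A2 row exactly (2, 34, 0, 0, 0), but concentrates more mass on the
baseline ranks (e.g. A3 rank-1 in 30 scenarios vs 22 published), and
the published table contains events — A3 at rank 5, A5 at rank 1 —
that are unreachable at |ε| ≤ 0.15 under the stated update. We tested
equal-redistribution, proportional redistribution, renormalization, and
clamping, with both the published and the recomputed fused weights; none
lands within 2 counts per cell. The corresponding acceptance test is
left failing rather than loosened, and the published counts ship only as
a reference constant (`CASE_STUDY_RANK_FREQUENCIES`) from which the
published Stability Index ratios (0.61, 0.69, 0.28, 1.0, 0.06) are
verified as count/36 arithmetic.

The Stability Index takes either scenario universe: the OAT frequency
table (perturbation robustness) or a list of method rankings
(cross-method robustness). The published consensus table uses the
latter — A3's Top-1 value 0.833 is 5 of 6 methods — and so does the
default consensus aggregation.

## Consensus

Borda awards `n − rank` points per ranking source; Copeland scores
pairwise majority wins (+1/0/−1, ties 0, kept verbatim). The default
aggregation universe is the six method rankings only: the published
consensus scores are exactly reproduced by them (a maximum Borda score
of 24 = 6 × 4 is only consistent with six sources), while
`--include-oat` folds the perturbation scenarios in as extra sources.
The final order sorts by Borda descending, breaking ties by Copeland,
then Stability Index, then alternative id — on the case study no
tie-break fires and the order is A3 > A2 > A4 > A1 > A5.

## Synthetic data

`generate_synthetic` draws uniform integer matrices on a configurable
scale (default 1–9, matching the case study's nine-point expert rating
scale) from a seeded generator. It emulates the *format* of
expert-averaged ratings — positive, bounded, discrete — and is used for
property tests: weight normalization, convention invariances,
closed-form vs brute-force oracle equivalences, Borda conservation
(`ΣB = M·n(n−1)/2`) and Copeland zero-sum. It does not emulate the
correlation structure, consensus effects, or score averaging of a real
expert panel, so passing property tests demonstrates algebraic
correctness of the pipeline, not behavioral claims about real
elicitation data. Independent draws can also produce constant columns
(with low probability at realistic sizes), which the weighting stages
treat as the documented error cases.

## Problem sizes and determinism

The case study is 5 × 6 and every stage on it runs in milliseconds;
property tests use matrices up to 50 × 10 and the full suite completes
in seconds. The pipeline is fully deterministic given its configuration
— identical configs produce byte-identical JSON reports; the only
random source in the package is the synthetic generator's explicit
seed.

## Limitations

* Expert elicitation and multi-expert score aggregation are upstream of
  this package: it consumes an already-averaged matrix.
* Only the usual (0/1) PROMETHEE preference function is implemented; no
  thresholds, no VIKOR compromise-set (acceptable-advantage) analysis.
* Weights are crisp; fuzzy/interval weights and subjective schemes
  (AHP, BWM) are out of scope.
* Sensitivity is strictly one-at-a-time; no variance-based or
  simultaneous multi-criterion perturbation.
* The exact generating formula of the case study's published fused
  vector and the scenario handling behind its published rank-frequency
  interior counts are unresolved upstream ambiguities, handled as
  documented above.
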