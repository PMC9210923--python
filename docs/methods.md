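# Methods

## Estimand and estimator

For `m` hypothesis tests with p-values `P₁…Pₘ`, a discovery threshold `t`
defines `S = #{i : Pᵢ < t}` rejections, of which an unknown `F` are false.
The estimand is the positive FDR, `pFDR(t) = E[F/S | S > 0]`, the expected
false discovery proportion given that something was discovered.

The permutation estimator uses `P` replicate analyses of the same data with
the association of interest destroyed by permutation but the dependence
*within* the predictor set and within the outcome set left intact. With
`V̄(t)` the mean per-permutation rejection count,

- null proportion: `π̂₀ = ((m − S)/m) / ((m − V̄)/m)`, truncated to [0, 1];
- point estimate: `FDR̂(t) = π̂₀ · V̄ / S`, truncated at 1 (pFDR ≤ 1 by
  definition; the truncation also pins the Wald statistic at 0 so that a
  threshold with `FDR̂ = 1` can never look like evidence *against* the null);
- log-scale variance (delta method):
  `σ² = (m − S)/(mS) + c₁ (m − V̄)/(P m V̄)`.

The first term is the binomial-style uncertainty of the observed count; the
second is the Monte-Carlo uncertainty of the permutation ensemble, shrinking
as `1/P` so the interval width honestly reflects how many permutations were
run. `c₁` is an over-dispersion factor for the permutation counts relative to
`Binomial(m, V̄/m)`: dependence among tests typically inflates the count
variance, so by default `c₁ = max(1, var(counts)/(V̄(1 − V̄/m)))`, estimated
per threshold from the `P` counts and floored at 1 (never *less* dispersed
than independence); a fixed user value is supported for small `P`. The
variance contribution of `π̂₀` itself is omitted: for the regimes the method
targets (`S, V̄ ≪ m`) it is smaller than either retained term by a factor of
order `S/m`.

Confidence intervals are log-normal Wald intervals,
`exp(log FDR̂ ± z₍₁₋cl₎/₂ σ)`. The upper bound is deliberately not clipped at
1, because the "upper bound < 1" selection rule needs it.

Everything is a function of `(m, S, per-permutation counts)`: rejection
counts are sufficient, and `fdr_table_from_counts` on a pre-reduced counts
table is bit-identical to `fdr_table` on raw p-value vectors.

## Threshold selection and FCR control

Each threshold in the investigator's grid `T` gets a one-sided Wald p-value
`P_t = Φ(log FDR̂ / σ)` for `H₀: log FDR = 0` vs `Hₐ: log FDR < 0`. A
Benjamini–Hochberg step-up pass over these p-values computes
`R = max{i : P₍ᵢ₎ < iα/|T|}` (strict inequality, exactly as the procedure is
stated); the selected thresholds are all rows with `P_t ≤ P₍R₎` (ties at the
critical p-value included — standard step-up rejection-set semantics), and
their intervals are recomputed at level `α* = Rα/|T|`. When `R < |T|` the
adjusted intervals are strictly wider than the nominal ones; when `R = |T|`
they coincide. This is the interval analogue of FDR control: under positive
regression dependence the expected fraction of selected intervals that miss
their parameter (the FCR, defined 0 when nothing is selected) is at most `α`.

Two naive comparators are implemented for benchmarking: select thresholds
whose unadjusted CI upper bound is `< 1` (UCB) or whose point estimate is
`< 0.2` (M.2), both at `cl = 0.95`.

Defaults everywhere: `cl = 0.95`, `α = 0.05`, rejection rule strict `p < t`.

## Numerical and degenerate-input choices

- `S = 0`: no estimate exists; the row is flagged undefined, carries no Wald
  p-value, and can never be selected. Undefined rows still count in the
  step-up denominator `|T|` — the candidate family is the grid the
  investigator proposed, and treating a missing p-value as never-selectable
  is equivalent to giving it `P_t = 1`. (This is also the conservative choice;
  using only defined rows as the family was measured to over-select.)
- `V̄ = 0` with `S > 0`: continuity substitution `V̄_eff = 0.5/P` (half of
  the smallest observable nonzero mean count), flagged `continuity`; the row
  remains eligible for selection. This keeps strict thresholds usable at the
  cost of a conservative, nonzero FDR floor of `0.5/(P·S)`.
- `S = m` or `V̄ ≥ m`: the corresponding variance term clamps at 0; `π̂₀`
  truncates rather than leaving [0, 1].
- `FDR̂ = 0` (only possible when `π̂₀ = 0`, i.e. `S = m`): no log-scale se
  exists; the row is reported with a zero estimate and no interval, and is
  excluded from selection.
- p-values must lie in `(0, 1]`; permutation p-values of exactly 1 are valid
  (never rejected at any grid threshold).

## Validation study

The simulation regenerates the published coverage benchmark. Per replicate:
`n = 200` observations of 100 Gaussian predictors in `L = 20` independent
blocks of 5 with compound-symmetric within-block correlation `ρ = 0.3`
(covariance `σ²[(1 − ρ)I + ρJ]`, `σ = 1`; the unit scale is the natural
standardized choice and is exposed in `ScenarioSpec`), one outcome per block
`Y_l = X_l β_l + ε`, `ε ~ N(0, 1)`. All 100 × 20 = 2000 predictor–outcome
pairs are tested with the simple-linear-regression slope t-test (equivalently
the Pearson-correlation t-test on `n − 2` df — the natural marginal pairwise
test). Permutation replicates apply one shared row permutation to the whole
outcome matrix, preserving both within-predictor and within-outcome
dependence. Scenarios: A (5 non-null blocks, all five within-block
coefficients 0.05), B (10 at 0.05), C (5 at 0.075), D (10 at 0.075), E (all
zero — the global null). In a non-null block every one of its 5 predictors is
marginally associated with the block's outcome (directly or through `ρ`), so
the null pairs are exactly the cross-block and null-block pairs; `F` is
therefore known by design and the simulation can score every interval.

The defaults in `ScenarioSpec` are the study conditions: 2000 replicates, 20
permutations per replicate, grid `−log₁₀(p) = 2.0…6.0` step 0.1 (41
thresholds), `α = 0.05`, `cl = 0.95`.

**True-pFDR oracle.** Coverage needs the true `E[F/S | S > 0]` per threshold.
It is estimated once per scenario by an independent Monte-Carlo run (default
10000 draws) of single unpermuted analyses, averaging `F/S` over draws with
`S > 0`; thresholds with `S = 0` in every draw are unavailable (NaN). Under
the global null the truth is exactly 1 and no oracle run is needed.

**Coverage accounting.** Per replicate and selection method, `Q` is the
fraction of selected intervals not covering the true FDR (0 when nothing is
selected); coverage is `1 − mean(Q)` over replicates. BY is scored on its
adjusted intervals, UCB and M.2 on the unadjusted ones — the comparators are
deliberately naive. Thresholds with `S = 0` contribute no interval and leave
that replicate's `Q` denominator; a selected threshold whose oracle value is
unavailable is likewise excluded (rare: it requires `S > 0` in the replicate
but `S = 0` in all 10000 oracle draws). Coverage is judged on the raw FDR
scale (identical to the log scale by monotonicity, and avoids log 1 = 0
boundary handling under the global null). Conditional coverage pools
per-interval records across the non-null scenarios and bins them by true FDR
(default: ten bins of width 0.05 on [0, 0.5]).

**Seeding.** One master seed spawns an independent `SeedSequence` substream
per replicate (and the oracle gets its own stream), so every summary is
bit-reproducible and independent of execution order.

## What the simulations do and do not show

The generator emulates a dense block-dependence structure with exchangeable
within-block correlation and weak-to-moderate signals — the regime where
permutation FDR estimation is most useful. It does not emulate heavy-tailed
data, heteroscedastic noise, confounding between the permuted factor and
other covariates, or test statistics whose null distribution differs across
tests (the method assumes approximate exchangeability). Passing the coverage
checks here therefore supports the selection/adjustment machinery under
positive dependence, not robustness to assumption violations.

Measured behaviour (reproducible via `scripts/acceptance.py` and the test
suite): the step-up/adjusted method holds its FCR at or below `α` and is the
most conservative selector in every scenario, while the naive UCB rule loses
roughly a fifth of its nominal coverage under the global null. Residual
differences of up to ~0.02 in a few scenario-by-method coverage values
relative to the published table are of the order of the combined Monte-Carlo
errors; the exact reference variance formulas were not available for
transcription, so the implementation uses the decomposition stated above.

## Problem sizes used in the shipped checks

The test suite runs the non-null scenarios at 500 replicates (with a
correspondingly widened Monte-Carlo band) and the global null at the full
2000; `scripts/acceptance.py` runs all reported scenarios at the full 2000
replicates with 10000-draw oracles. A single replicate (21 analyses × 2000
tests + table + selection) takes a few milliseconds, so the full study is
minutes of CPU time.

## Known limitations

- The Wald interval is asymptotic in both `S` and `P·V̄`; with very few
  discoveries or permutations the intervals are wide and the continuity
  floor dominates — more permutations, not more thresholds, is the remedy.
- `c₁` is estimated per threshold from only `P` counts and is floored at 1;
  with `P = 1` the variance term cannot be estimated at all and a fixed `c₁`
  must be supplied.
- The step-up pass treats the threshold p-values as PRDS; strong negative
  dependence between thresholds (not possible for nested rejection regions,
  but conceivable for user-supplied exotic grids) is outside the guarantee.
- The true-FDR oracle is itself Monte Carlo; its error (~`0.5/√n_mc` per
  threshold in the worst case) is negligible at the default size but matters
  if `n_mc` is reduced aggressively.
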