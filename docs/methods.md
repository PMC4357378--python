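# Methods

## Design and statistic

A stratum-matched pooling study recruits `n` cases, each with `m ≥ 1`
controls matched on stratum-delineating variables, and randomly allocates
each matched set to one of `J` pooling sets. Within set `j` the cases form
one case pool and the k-th control of each matched set forms control pool
`k`, so the study types `J·(1+m)` pools per marker. Pools are measured at
the candidate marker (`i = 0`) and at `L` unlinked null markers
(`i = 1..L`); `p1[i, j]` is the case-pool measurement, `p0[i, j]` the mean
of the `m` control-pool measurements, and `D = p1 − p0`.

The per-marker statistic `χ²_i = (Σ_j D_ij)² / Σ_j D_ij²` is large when the
case-control differences have a consistent sign across pooling sets. It is
bounded by `J` (Cauchy–Schwarz), attaining the bound only for constant
nonzero rows; an identically-zero row is assigned `χ² = 0` — the 0/0 limit
is path-dependent, and 0 is the unique choice that reads "no evidence" and
keeps the ratio statistic defined. The disequilibrium statistic
`T = χ²_0 / mean{χ²_1..χ²_L}` divides out inflation shared with the null
markers (genomic control). `T` is invariant to rescaling or negating whole
marker rows of `D`.

## Permutation null

Exchanging the case/control labels of pooling set `j` leaves all
measurements intact and negates column `j` of `D`. Under the null
hypothesis of no association the labels are exchangeable within each set,
so the `2^J` sign patterns are equally likely. One sign per pooling set is
applied to **every** marker row simultaneously — label exchange affects
all markers measured on that set's pools — and both the numerator and the
denominator of `T` are recomputed under each pattern. Because
`Σ_j D_ij²` is sign-invariant, only the signed row sums change; the
implementation precomputes the denominators and evaluates a whole batch of
patterns with one matrix product, which is what makes 5000-replicate
calibration runs take seconds.

Two p-value rules are provided:

* `greater-or-equal-plus-one` (default): `p = (1 + #{T_perm ≥ T_obs}) / (1 + B)`.
  Counting the observed data as one more null draw guarantees `p > 0` and a
  valid (never anti-conservative) test at any replicate count `B`.
* `greater`: the literal proportion of permutation statistics strictly
  larger than the observed one. It can return 0 and is slightly
  anti-conservative at small `B`; it is kept for fidelity to the original
  description.

`B` defaults to 10 000. For `J ≤ 20`, `exhaustive_pvalue` enumerates all
`2^J` patterns and serves as the exact oracle in the test suite; the
identity pattern always ties, so the exact p-value is at least `2^-J`.
Patterns `s` and `−s` give identical `T`, so the effective null support has
at most `2^(J−1)` points — the resolution limit of the test at small `J`.

## Large-sample comparator

Under the polyset large-sample model the candidate chi-square behaves as a
scaled `χ²₁` and the genomic-control denominator — the mean of `L`
independent null chi-squares with the same scale — as `χ²_L / L`; the scale
cancels and `T` is referred to `F(1, L)`. The familiar genomic-control
referral of `T` to `χ²₁` is the `L → ∞` limit of this and is what
`large_sample_pvalue` uses when the null-panel size is not supplied. The
distinction matters at `L = 10`: ignoring the denominator's variability
(the `χ²₁` referral) is measurably anti-conservative there, while the
`F(1, L)` referral is conservative for oligoset `J` — the bounded
pooling-set chi-square (`χ² ≤ J`, a weighted Rademacher sum squared) has a
lighter tail than its chi-square limit. The experiment drivers therefore
use `F(1, L)` for the comparator. Either way the comparator is a
documented approximation; the permutation test is the primary inference for
`J < 30`.

## Simulation model

`simulate_dataset` composes:

1. **Population.** Five hidden strata of equal weight. Null-marker allele
   frequencies are drawn per (marker, stratum) from `Uniform(0.1, 0.9)` —
   a fresh random genomic-control panel per simulated study. The candidate
   frequencies (0.2, 0.3, 0.4, 0.5, 0.6) and baseline disease risks
   (0.02, 0.04, 0.06, 0.08, 0.10) rise together across strata, so hidden
   structure confounds the naive case-control comparison (the simulator's
   own test suite demonstrates the resulting inflation when genomic
   control is switched off). All of these are overridable via
   `StratumModel`; they are defaults chosen to make confounding material,
   not estimates of any particular population.
2. **Disease model.** Per-allele multiplicative odds at the candidate:
   `odds(D | g, s) = odds_s · ψ^g` with `ψ = effect_size` (`ψ = 1` under
   the null). Case (stratum, genotype) pairs are drawn from the
   case-ascertained joint distribution; control candidate genotypes from
   the non-diseased conditional.
3. **Matching.** Each of a case's `m` controls is independently a perfect
   stratum match with probability `1 − δ` and a random draw from the
   population stratum distribution with probability `δ` (mismatch index
   `δ ∈ [0, 1]`).
4. **Pooling.** Matched sets are allocated independently and uniformly to
   the `J` pooling sets; an allocation leaving a set empty is redrawn
   (practically impossible at `n ≫ J`). True pool frequency = allele
   copies / (2 · pool size).
5. **Measurement.** Unequal allelic amplification distorts a true
   frequency `p` to `p′ = κp / (κp + 1 − p)`, with `κ ~ Uniform(1, 2)`
   drawn once **per marker** — one assay measures all pools of a marker.
   The measured value is logit-normal about `p′`:
   `logit(p_obs) ~ Normal(logit(p′), τ²)` with `τ = σ / (p′(1 − p′))`,
   the delta-method calibration that makes the frequency-scale SD ≈ `σ`
   (so `σ = 0.01` vs `0.05` is directly comparable to allele-frequency
   differences). `σ` could instead be read as a logit-scale SD; the two
   readings only diverge far from `p = 0.5`. A monomorphic pool (`p` of 0
   or 1) passes through unmeasured with a warning.

Defaults are the canonical evaluation conditions: `n = 900` cases,
`m ∈ {1, 2}`, `J ∈ {10, 15, 25}`, `L ∈ {10, 50}`, `δ ∈ {0.1, 0.3, 0.5}`,
`σ ∈ {0.01, 0.05}`, `κ ~ U(1, 2)`. Everything is reproducible from a
single seed; experiment grids derive per-replicate seeds by
`SeedSequence(master, spawn_key=(scenario_index,)).spawn(n_replicates)`, so
cells are independent and the whole grid is deterministic given the master
seed.

What the generator does **not** emulate: linkage disequilibrium among
markers (null markers are assumed unlinked), unequal DNA contributions of
individuals within a pool, pool-construction errors, and sequencing-based
pool genotyping. Passing tests therefore certify the statistic and its
calibration under the stated error model, not robustness to violations of
it.

## Experiment drivers and problem sizes

`run_type1_grid` / `run_power_grid` estimate rejection rates (`p ≤ α`,
default tie rule) with binomial Monte-Carlo standard errors
`sqrt(r(1−r)/n)`. The permutation and large-sample summaries of a cell are
computed on the same simulated replicates, so comparisons between them are
paired. Default desk-scale replication is 2000 replicates × 1000
permutations per cell; the packaged calibration script uses 5000 × 500 and
the power-ordering tests 400 × 300, sizes at which every check here runs
in seconds to a couple of minutes on one CPU while leaving Monte-Carlo
error well below the effects being asserted.

Power is reported only ordinally (more pooling sets, more controls per
case, more null markers, less measurement noise, better matching ⇒ more
power): no absolute power values are published for this design's
evaluation scenarios, so none are asserted. The ordering tests fix the
per-allele odds ratio at 1.30, which puts the baseline cell
(`J = 10, m = 1, L = 10, δ = 0.3, σ = 0.05`) near 50% power at `α = 0.05` —
mid-range, where orderings are most visible. `typing_cost_ratio` returns
the exact rational assay-cost ratio `J(1+m) / (n_cases + n_controls)`.

## Numerical notes

* All-zero chi-square rows: defined as 0 (above); a dataset whose **every**
  null row is zero raises `DegenerateNullError` rather than returning an
  uncalibrated statistic.
* Tie comparisons in the permutation loop are exact floating-point
  comparisons; the observed pattern is reproduced bit-identically by the
  identity sign vector, so ties are genuine.
* TSV I/O writes 17 significant digits and parses with round-trip float
  precision, making write→read the identity on IEEE doubles.
* Pool sets are 1-based in files; markers are ordered candidate-first.

## Known limitations

* The large-sample comparator approximates the original polyset test from
  first principles (`F(1, L)` referral); the original's exact finite-`J`
  reference is not reproduced here, and only the comparator's qualitative
  conservatism is claimed.
* With `B` permutations the smallest attainable p-value is `1/(B+1)`
  (default rule); studies chasing genome-wide significance need `B` scaled
  accordingly, or the exhaustive enumeration when `J ≤ 20`.
* Residual confounding at the candidate (imperfect matching, `δ > 0`) is
  corrected only insofar as it is shared with the null markers; extremely
  aligned frequency/risk gradients with large `J` can leave a small size
  inflation, visible only beyond the replication used here.
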