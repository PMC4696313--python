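# Methods

## Model and procedure

The toolkit treats each feature (matrix row) independently.  For a row with
strictly positive values x₁,…,xₙ in one condition, the normalized Shannon
entropy is SE = (−Σ (xᵢ/x) log₂(xᵢ/x)) / log₂ n with x = Σxᵢ, so SE ∈ [0, 1]
with 1 for a constant row; the coefficient of variation is CV = s/|x̄| with
the n−1 sample standard deviation.  The differential metrics are the
absolute between-condition differences DSE, DCV and DE.  Note the entropy
convention: *lower* SE means a more concentrated (more variable) row, so a
large DSE can reflect variability gained in either condition — the per-
condition SE columns disambiguate the direction.

Statistical testing is metric-specific:

- **DSE: pooled-permutation test.**  DSE has no usable closed-form null,
  and entropy is not well enough correlated with variance for a variance
  test to act as a surrogate, so the null is built empirically: the n₁+n₂
  values are pooled, randomly permuted, and re-split into groups of sizes
  n₁ and n₂; the p-value is the proportion of `nperm` permuted DSEs at
  least as extreme (≥) as the observed one.  With the plain proportion
  estimator p = 0 is possible; an optional (count+1)/(nperm+1) estimator
  (`bias_corrected_permutation`) is available, default off.
- **DCV: Fligner–Killeen test on log-transformed data.**  A rank-based,
  median-centered test of variance homogeneity, robust to non-normality,
  asymptotically χ² with 1 df for two groups.  On the log scale a variance
  difference is a relative-dispersion (CV-like) difference, which is what
  DCV measures.
- **DE: two-sided Welch t-test** (unequal variances).  DE is included as a
  simple magnitude-based point of comparison, not as a state-of-the-art
  differential-expression method.

Adjusted p-values (Bonferroni, Holm, Hochberg, BH, BY) are computed over
*all* rows with a computable raw p — the family size is the number of
tested hypotheses, not the number of displayed rows — with R `p.adjust`
semantics (order-preserving, clipped at 1).

## Key parameters

| Parameter | Default | Meaning / rationale |
|---|---|---|
| `nperm` | 1000 | permutations per row for the DSE test; the p-value grid is 1/nperm, so smaller values bound the attainable significance |
| `padjust` | `bh` | FDR control is the usual choice for feature screens; `holm` etc. available |
| `shift` | `(0, 0)` | per-matrix additive bias; `auto` resolves to \|min\| + (smallest positive entry, fallback 1) when the matrix minimum is ≤ 0, else 0.  Results are shift-sensitive: entropy and CV are translation-variant, so any shift is logged and should be reported |
| `ntop` | all rows | truncation applied after sorting; adjustment happens before truncation |
| `seed` | none | seeds every permutation stream; per-row substreams are derived from (seed, row index) so results do not depend on evaluation order |

Output types: `v` = the two per-condition statistics; `bv` = + difference;
`p`, `pa`, `bp`, `bpa` = + raw and adjusted p, sorted by raw p, adjusted p,
difference and difference respectively.  Value sorts are descending, p
sorts ascending; ties break lexicographically by row label; rows with
fewer than two finite values in either condition are reported entirely as
NA, sort last, and are excluded from the adjustment family.

## Synthetic data

`generate_pair` emulates a preprocessed case/control microarray cohort:
1000 features × 30 samples per arm by default, intensities log-normal with
meanlog 5 and sdlog 0.5 (natural logs; median intensity ≈ 148, CV ≈ 0.53 —
the scale of typical normalized microarray intensities), 10% of rows with
the control log-sd multiplied by 3 (differential variability), a disjoint
10% with the control log-mean shifted by 0.7 (≈ 2-fold differential
expression), and optional uniform NA knockout.  The generator produces
per-row ground truth, which the power checks use.

What it does **not** emulate: probe- and batch effects, row-specific
baseline heterogeneity, count noise (RNA-seq), correlated features, or
structured missingness.  Passing tests therefore demonstrate calibration
and power under a clean log-normal null, not performance on raw platform
data — which the tool in any case expects to be preprocessed upstream.

## Numerical choices

- SE of an exactly constant vector returns exactly 1.0 (short-circuit), and
  all entropies are clipped to [0, 1]; otherwise the rounding of xᵢ/x can
  leave 1 ± 1e−16.
- Permutation tie handling: a resampled split that reproduces the observed
  grouping can recompute DSE a few ulp away from the observed value
  (summation order), so "at least as extreme" is counted as
  `perm ≥ observed − 1e−9`.  Ties matter: at n₁ = n₂ = 3 the observed
  grouping recurs with probability ~0.1 per draw, and dropping those ties
  would visibly bias p downward.
- Swap symmetry: the permutation null depends only on the pooled multiset
  and the two group sizes, so the pool is sorted before permuting and the
  split always assigns the first min(n₁, n₂) elements to the smaller
  group — swapping the two matrices then yields bit-identical p-values.
  The Fligner–Killeen wrapper likewise canonicalizes group order before
  pooling, since the grand-mean rounding is otherwise order-dependent at
  the last ulp.
- The Fligner–Killeen statistic uses natural logs; the statistic is
  rank-based, so the log base is irrelevant in exact arithmetic.  (In
  floating point an even-sized group carries a structural tie — its two
  middle values are exactly equidistant from the median — whose resolution
  can differ between bases; this is inherent to the test, not to this
  implementation.)
- Degenerate rows: both groups constant and equal → t-test p = 1 with a
  warning; constant and unequal → p = 0; all median-centered log
  deviations zero → FK p = 1.
- Auto-shift bumps its margin with `nextafter` until the post-shift
  minimum is strictly positive, guarding against the margin being absorbed
  by rounding when it is many orders of magnitude below |min|.
- Multiple-testing adjustments are computed directly from the step-down /
  step-up closed forms (verified against R's `p.adjust` and statsmodels in
  the test suite).

## Design choices

- The analysis is exposed as a scikit-learn estimator
  (`DifferentialVariability.fit(X, y)` with `transform` keeping the
  `n_top` largest differences), because per-feature two-group scoring is
  shaped exactly like univariate feature selection; `run_analysis` and the
  CLI wrap it for matrix-pair workflows.
- The t-test variant is Welch, two-sided — the safer general default when
  group variances are not known to be equal (and variance inequality is
  precisely what the neighbouring metrics look for).
- Missing values are dropped per row per condition; the entropy
  normalization uses the post-drop count in log₂ n.
- The permutation streams are per-row substreams keyed on (seed, row
  index), making the full table reproducible and order-independent.
- The Hommel adjustment is omitted (quadratic cost, rarely used); the
  method list is a deliberate subset of R's `p.adjust` menu.

## Known limitations

- The Fligner–Killeen χ² approximation is slightly conservative at
  moderate sample sizes: simulated type-I error at α = 0.05 is ≈ 0.039–0.043
  with 30 samples per arm and approaches the nominal level only around
  200 per arm.  This is a property of the test itself (R's `fligner.test`
  matches this implementation to 15 digits), inherited by the DCV
  p-values.
- Permutation p-values live on the grid {0, 1/nperm, …, 1}; with the
  default 1000 permutations, adjusted significance below 1/1000 per row is
  unattainable without raising `nperm`.
- Exactly two conditions, unpaired; no normalization or preprocessing is
  performed; CV is unreliable when means approach zero, which is one
  reason the tool insists on strictly positive input.

## Problem sizes used in the checks

The statistical acceptance checks run at: 2000 null rows × 1000
permutations (DSE calibration, with a 99% Dvoretzky–Kiefer–Wolfowitz
uniformity band), 10 000 null replicates at 30 samples per arm (FK and
Welch levels), 20 random 3+3 instances against exhaustive 6! enumeration
at 20 000 sampled permutations, 10⁵ fuzzed vectors for entropy bounds, 10⁴
fuzzed vectors for adjustment properties, and the 1000-row / 10%-affected /
variance-ratio-3 power design.
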