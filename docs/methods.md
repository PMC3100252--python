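# Methods

## Model

A compound profiled on a panel of targets is modelled as distributing over
a hypothetical equilibrium mixture of all those targets, with no competing
cofactors and no site saturation. The occupancy of target *i* is the
Boltzmann weight written in terms of association constants,
φᵢ = K\_a,i / ΣK with K\_a,i = 1/K\_d,i, and the selectivity entropy is

S\_sel = − Σᵢ φᵢ ln φᵢ  (natural logarithm; the value is in nats).

This is an information-theoretic summary of the affinity profile, not a
physical entropy. Assumptions worth keeping in mind:

- **Affinities are comparable across targets.** Kd, Ki and IC50-at-KM,ATP
  can be mixed because any common scale factor (e.g. the Cheng–Prusoff
  factor 2 relating IC50-at-KM,ATP to Kd) cancels in φ.
- **The value is panel-relative.** Adding a target the compound binds
  changes S\_sel; adding one it does not bind leaves it exactly unchanged
  (0·ln 0 := 0). Entropies should be compared on similar panels.
- **No cellular corrections.** Intracellular ATP shifts effective
  selectivity target-by-target; biochemical panel entropy is a first pass.

Implementation conventions: zero-Ka entries are dropped from the fraction
vector rather than producing NaN; the result is clamped at 0 so a single
binder returns exactly 0.0; 0 ≤ S\_sel ≤ ln(n\_active) always holds.

## Companion metrics

- **S(c)** (default c = 3 μM): count of measured Kd strictly below c,
  divided by the number of targets *tested* — the full panel size including
  censored and missing cells. Strict `<` is used ("hit at" a concentration);
  the cutoff is configurable. Censored entries never count as hit: with
  limit ≥ c the true Kd is provably above c, below the limit nothing is
  known, and the conservative choice is uniform.
- **S(fold)** (default 10×): reference is the most potent measured Kd;
  entries with Kd ≤ fold·reference count, boundary inclusive, so the
  reference itself always counts and S(fold) ≥ 1/n_tested. The inclusive
  convention is a choice — the verbal definition does not fix the boundary.
- **Partition index**: φ of the most potently hit target (first index on
  ties), or of an explicit reference target. Identical to max φᵢ, hence the
  invariant S\_sel ≥ −ln Pmax.
- **Gini**: %-inhibition values are sorted ascending and accumulated into a
  Lorenz curve with nodes at k/n; the score is 1 − 2B with B the
  *trapezoidal* area under the curve. The trapezoid rule is the
  continuous-area-consistent choice for a discrete curve; it matters most
  for small panels (single-spike profile on n targets scores (n−1)/n, not
  1). Kd panels are converted to %-inhibition with the Hill expression
  %-inh = 100/(1 + 10^−(pKd − pconc)), so the Gini value depends on the test
  concentration (default 1 μM) and that concentration is always logged with
  the output.
- **Ka-Gini**: the same Lorenz construction applied directly to the Ka
  vector, including zero-Ka (non-binding) panel targets, which removes the
  test-concentration dependence.
- **Weighted entropy**: φᵢ = wᵢK\_a,i / Σⱼ wⱼK\_a,j with nonnegative
  importance weights; unit weights reproduce the plain entropy exactly and
  a zero weight removes a target.

## Units, censoring, missing data

Everything is stored in molar; file readers take the input unit once
(default nM) and convert by an exact power of ten. A cell `>X` means "no
binding detected up to X". Policies for the Ka vector:

- censored: `drop` (default), `zero` (keep a 0 slot), or `at_limit`
  (Ka = 1/limit, an optimistic bound);
- missing: `drop` (default), `zero`, or `panel_mean_pkd`, which imputes the
  mean pKd of the measured values for that target across the panel, falling
  back to the compound's own measured mean when the column is empty. The
  mean is taken in log space because affinities are log-distributed.

`drop` and `zero` give identical entropies (zero-Ka terms contribute
nothing), but denominator-based scores always divide by the full panel
size, and the whole-panel driver evaluates rank-ordered metrics (Gini,
Ka-Gini) on the panel-length vector so that non-binding targets stretch the
Lorenz curve as they should.

## Ranking and classification

`compute_all_metrics` reports one promiscuity rank per metric, oriented so
rank 1 is always the most selective compound: ascending by value for
entropy and the S-scores, descending for Pmax and the Gini-type scores
(where larger = more selective). Ties resolve by input order, keeping every
rank column a permutation of 1..n.

A compound is classified *selective* when S\_sel < 2 nats and *promiscuous*
at or above 2. The threshold sits just above the centre of the entropy
distribution of a large public kinome benchmark (38 inhibitors × 290
kinases; mean 1.8, median 1.9, sample SD 1.0 — the package ships the
benchmark vector and recomputes these statistics in its tests). The sample
(n−1) standard deviation is used throughout.

## Cross-dataset robustness

For one metric measured on the same compounds by two profiling
technologies, `cross_dataset_consistency` pairs values by compound id
(first argument = x dataset) and reports: R² of the OLS regression of y on
x, the Pearson correlation, and the total squared *vertical* residual to
the diagonal y = x after dividing each set by its maximum (vertical rather
than orthogonal residuals, for consistency with OLS). For metrics whose
values crowd into a narrow sub-interval — the Ka-Gini typically occupies
roughly 0.93–1.00 on large panels — each set's minimum is subtracted before
normalization (`rescale_min`). Group contrasts use the two-tailed Welch
t-test: with unequal group sizes it is safer than the pooled variant; two
constant equal-mean groups return p = 1 by convention.

## Synthetic data generator

`SyntheticSpec` draws a profile with `n_potent` targets log-uniform in pKd
8–9 (1–10 nM, a realistic potent cluster) and the remainder in pKd 4–6
(weak background), with an optional fraction of background entries replaced
by above-limit censored cells at the background floor (Kd 100 μM). Sampling
in pKd space matches the log-normal-like spread of real panels. Each
compound in a generated panel uses seed + index, so any sub-panel is
independently reproducible. The generator emulates the *shapes* of real
profiles (dominant-target, equal-potency, mixed) but not the correlation
structure of a real kinome — targets are drawn independently — so passing
property tests demonstrate the metrics' mathematical behaviour, not
biological realism. Test problem sizes (panels of ~8–25 targets, property
sweeps over ~1000 generated profiles) keep the whole suite in seconds while
covering the regimes where the metrics differ.

## Known limitations

- Percent-inhibition input supports the Gini score directly; the other
  metrics require affinity-type data.
- No ATP-competition correction for cellular selectivity, no clinical-phase
  or structural (type I/II/III) auto-classification — group labels are user
  input.
- The published per-compound metric table for the 290-kinase benchmark is
  shipped as reference *values*; recomputing it requires the external raw
  Kd matrix, which is not redistributed here.
- Explicitly choosing a zero-Ka reference in `partition_index` returns 0,
  outside the (0, 1] range of the default reference; callers opting into an
  explicit reference are expected to pick a binding target.
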