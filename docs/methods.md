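# Methods

## The model

`trendtree` detects temporal trends in the *rate* of phenotypic evolution and
directional *drift* of the phenotypic mean on rooted phylogenies that may
contain extinct tips (non-ultrametric trees). It makes no a-priori choice
among evolutionary models; everything is estimated from the distribution of
the observed trait over the tree and judged against Brownian-motion (BM)
simulation on the same tree.

### Phylogenetic ridge regression

Let the tree have N tips and M internal nodes, and let every non-root
element index the branch above it (B = N + M − 1 branches). Ages are
root-distances: the root is at 0, the most recent tip at the tree height H,
extinct tips in between. Each tip value is modeled as the root state plus
the accumulated change along its root path,

    y_i = rootV + Σ_{b ∈ path(i)} l_b · β_b ,

with one rate β_b (trait units per time) per branch. In matrix form
y = rootV + L β, where L is the tips × branches path matrix whose entry is
the branch length if the branch lies on the row's root path. With B > N the
system is underdetermined, so β is the ridge solution

    β = argmin ‖(y − rootV) − Lβ‖² + λ‖β‖² ,

computed in closed form from the SVD of L. Ancestral states are read off
the node rows of the same path matrix: aces = rootV + L_node β. These
"rates" are regression coefficients — phenotypic change per unit time
between consecutive nodes — and under BM their magnitude grows toward the
present, tracking the accumulation of phenotypic variance.

**rootV.** The root state is estimated before the solve as a weighted mean
of the 10 % most ancient tips (the earliest-terminating lineages,
k = max(1, round(N/10))), with weights ∝ 1/age² so that older tips dominate.
The direct-weighting alternative (∝ age²) is exposed via
`rootv_weighting="age_sq"`. rootV is then held fixed; the ridge sees
residuals y − rootV.

**Penalty.** λ is selected by minimizing the exact leave-one-out prediction
error of the tip values over a log-spaced grid (10⁻⁶ … 10³, 19 points). The
residual is standardized to unit variance before the solve, which makes the
grid scale-free; the returned rates are on the original trait scale (ridge
is linear in y, so standardization commutes with the solve at fixed λ). A
fixed λ may be supplied instead. The same policy is applied to observed and
null traits, which is what makes their regression slopes comparable.

### The trend and drift statistics

From a fitted ridge result two ordinary regressions are run:

- **trend**: log(rescale01(|β|) + ε) against branch age, over all branches;
  rescale01 maps a vector affinely onto [0, 1], and ε = 10⁻⁴ guards the
  rescaled minimum (exactly 0). The branch age is the age of the branch's
  child element (a midpoint option exists). The log tames the strong right
  skew of rate magnitudes.
- **drift**: rescale01 of the phenotype vector — ancestral estimates
  collated with observed tip values, one entry per element — against
  element age.

Neither slope is interpreted against zero: under BM the trend slope is
itself positive (rate magnitudes grow toward the present). Instead, n_null
(default 100) BM traits with σ² = 1 are simulated on the same tree, each is
pushed through the identical pipeline (same rootV rule, same λ policy, same
rescaling and log), and the observed slope is ranked within the null family:

    P = (#{null slopes < observed} + 1) / (n_null + 1).

P > 0.95 flags an increase, P < 0.05 a decrease. Because every statistic is
invariant to affine transformation of the trait, the null's σ² = 1 is
immaterial. An alternative null (`null_mode="bm_true"`) takes the true
simulated branch increments as rates; it is retained for methodological
comparison but is strongly mis-calibrated (estimated and true rates have
very different age profiles), so the refit null is the default.

**Half-tree SD check.** A positive rate trend leaves the standard deviation
of rates in the older half of the tree (branch midpoint before H/2) smaller
than in the recent half. The ratio SD(old)/SD(recent) is ranked within the
same null families and arbitrates the *direction* of rate variation: by
default a trend verdict requires the rank-significant slope and an SD ratio
on the matching side of the null median (`sd_concordance="direction"`;
"significance" demands a rank-significant ratio, "none" disables the gate).

### Clade contrasts

Drift is compared clade by clade: the drift regression is refit on the
clade's own elements (focal node + descendants, values rescaled within the
clade), and the observed clade slope is ranked within the same
clade-restricted slope computed on each whole-tree BM null.

Raw trend slopes are not comparable between clades — a clade's slope
depends on where it sits on the age axis — so clades are compared through
estimated marginal means: one linear model

    log rescale01(|β|) ~ age × group

is fitted over all branches (background as reference level, interaction
always retained), each group's adjusted prediction is evaluated at the
grand-mean branch age, and the contrast (clade − background, or
clade A − clade B) is ranked within the same contrast computed on the BM
nulls. The parametric t-test of the contrast from the observed fit is
reported alongside.

## The validation harness

**Trees.** Birth–death simulation at birth 0.5 / death 0.2 (time units are
the reciprocal of these rates), conditioned on 100 extant lineages with all
extinct lineages retained as fossil tips; trees below 80 total tips are
rejected. This yields ~160 tips on average (≈60 extinct) and heights around
12–15. The simulator stops exactly at the 100th birth, which would leave
that event's daughters with zero-length branches; every extant tip is
therefore extended by a single Exp(n(b+d)) waiting-time draw — the process
state cannot change during the wait, so the law of the tree is preserved.

**Traits.** BM with root value ~ U(−10, 10) and rate σ² drawn from a
300-point uniform grid on [0.01, 10], simulated by independent Gaussian
branch increments (variance σ²·length); true node values are retained where
the harness needs them.

**Transforms.** A rate trend is imposed by y ← y · t^es / t on the tip ages
t (es = 1 is the identity; es > 1 inflates variance toward the present);
a mean drift by y ← y + t · ds. **Battery drift intensities are specified in
units of the untransformed trait's tip standard deviation**: a battery at ds
applies y + t·ds·sd(y). A fixed absolute slope would be an enormous
perturbation on a low-rate trait and an invisible one on a high-rate trait
(the generator spans three orders of magnitude in σ²), making "power at ds"
ill-defined; the SD-relative convention makes the imposed drift, the dev
statistic, and the tests' power all independent of the starting rate.
Clade-restricted transforms double the parameter, and drift is additionally
scaled by H_ratio (tree height / clade height) so that clades of different
depths receive comparable displacement.

**Deviation metrics.**

- dev = (mean(y_drifted) − root) / (sd(y_drifted) · H): displacement of the
  trait mean from the root state, in trait SDs per unit time; ≈ 0 under BM,
  odd in ds, and ≈ ds · (mean tip age / H) ≈ 0.8·ds under the SD-relative
  convention (≈ 0.19 at ds = 0.25).
- spread: range of values among elements beyond H/2 divided by the range
  among elements before H/2, normalized by the mean of the same ratio over
  100 BM simulations on the tree; ≈ 1 under BM, increasing in es. The
  per-replicate ratio is heavy-tailed (it is a ratio of ranges), so only its
  center is tightly calibrated.

**Batteries.** `run_table1` measures Type I error (BM) and power (es at
0.3 / 1.6, ds at ±0.25) with all scenarios paired on the same trees;
`estimate_sig_thresholds` sweeps es ~ U(−1, 3) and ds ~ U(−2, 2), fits a
logistic curve to rank-P versus the parameter, and solves it for P = 0.05
and P = 0.95 (a straight line cannot represent a bounded saturating response
across the sweep — its P = 0.95 crossing is an artifact of the sweep range —
so the line is emitted only as a diagnostic); `run_clade_battery` /
`run_table2` transform random clades (≥ 20 tips inside and ≥ 20 tips of
background, uniform over qualifying non-root nodes) with random,
fixed, same, or opposite signs and tabulate matched-direction detection;
`run_size_and_sigma_checks` regresses rank-P on tree size and σ². Every
battery derives all randomness from one master seed via spawned child
streams and logs per-replicate seeds, sizes, parameters, and P values.

**Problem sizes.** The acceptance script runs 200 replicates for the
whole-tree batteries and the threshold sweep and 100 per clade battery, with
100 nulls throughout (~30 s total on one CPU); the test suite uses the same
machinery at smaller replicate counts. Per-tree SVD factorization lets all
100 null fits share one decomposition, so a full search costs ~30 ms.

## Numerical choices

- Ridge solve via economy SVD; LOO errors via the hat-diagonal identity.
- rescale01 of a constant vector is an error (the range is the scale unit);
  a constant trait yields all-zero rates without error.
- rank-P uses (k+1)/(n+1); it cannot be 0 but reaches exactly 1 when the
  observation exceeds every null.
- ε = 10⁻⁴ is shared by observed and null pipelines, so rank comparisons are
  insensitive to its exact value.
- Branch age = child-element age by default; midpoint exposed.
- Ties in the rootV age sort are broken by stable sort order.

## Known limitations

- **Power at strongly positive rate trends is modest.** The positive-trend
  signal competes with the already-positive BM null slope family; at es = 1.6
  detection is ~0.2–0.4 depending on the penalty policy, versus ~0.8–1.0 for
  the mirrored negative case. The upper significance threshold recovered by
  the sweep is correspondingly es ≈ 2.5–2.8.
- **Two-tailed Type I error of the drift tests sits at the nominal ~10 %**
  (5 % per tail) implied by the exchangeable rank construction; tests that
  report lower false-positive rates necessarily treat null and observed
  statistics asymmetrically.
- The BM generator does not emulate measurement error, fossil age
  uncertainty, incomplete or biased fossil sampling, or multifurcations
  (accepted by the data model, but the harness generates binary trees), so
  green batteries certify behavior under the stated generator only.
- Traits are univariate; covariates and rate-shift searches are out of
  scope.
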