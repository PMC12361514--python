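# Methods

## Data model

The experimental unit is a complete 3×3×3 crossed design over extraction
temperature (°C), time (h) and ethanol/water ratio (%), with a uniform
replicate count per condition. The packaged `table1` fixture stores the
measured dataset as per-condition (mean, SD, n = 3) summaries; the "±"
dispersions are treated as standard deviations of triplicates. Two
consistency checks support that reading: the one-way ANOVA recomputed from
the summaries under ±=SD, n=3 gives F(26, 54) = 3205.78 with exactly the
published degrees of freedom (54 = 27·(3−1)), and mean ± 1.96·SD/√3
reproduces every published confidence bracket to ≤0.002.

Where replicate-level values are needed (the regression fit, lack of fit),
they are **reconstructed** as the triple {m−s, m, m+s}, which has exactly
mean m and sample SD s. This is a reconstruction, not original data, but it
is exact for every statistic that depends on the data only through
per-condition first and second moments — which covers everything computed
here. The loader flags any replicate count other than 3 when summaries are
supplied, since the symmetric exact triple needs n = 3.

Factors are coded −1/0/+1 in level order; intermediate settings map
linearly. Coefficients are reported **keyed by factor name, never by symbol
index**: on this dataset the large "second factor" effects
(−0.433 linear, −0.976 quadratic) belong to extraction *time* and the
near-zero ones to the solvent axis, and name-keying makes that labelling
unambiguous. (Balanced-design contrast identities — each linear coefficient
equals half the high-minus-low factor-mean difference — are asserted in the
test suite, so a mislabelling cannot pass silently.)

## Response-surface stage

The full 10-term quadratic is fitted by least squares (QR on the explicit
design matrix) to all 81 replicate rows. Reported fit statistics:

* `r2`, `r2_adjusted` — on the replicate-level rows (0.991 / 0.990 on the
  packaged data);
* `r2_predicted` — leave-one-out PRESS R² computed on the 27 condition
  means, the "predicted R²" convention of response-surface software
  (0.981 on the packaged data). This is the statistic that matches the
  fit quality quoted for this dataset at ~0.980; the package reports all
  three rather than privileging one.

Lack of fit partitions residual SS into pure error (Σ(nᵢ−1)sᵢ², 54 df) and
lack of fit (17 df for 27 conditions, 10 parameters). On the packaged data
lack of fit is strongly significant (F ≈ 42): the replicate scatter
(SD ≈ 0.03) is far smaller than the quadratic's smoothing error, i.e. the
surface is a good summary but not a complete description. Pure error below
1e−20 of the response's sum of squares (replicates numerically identical)
raises an error rather than returning an F built from rounding dust.

Maximisation over the coded cube uses a deterministic dense grid
(step 0.01, sliced to bound memory) followed by a bounded L-BFGS-B polish;
the interior stationary point from the 3×3 gradient system is added as a
candidate when it lies in the cube. On the packaged data the maximum sits
at 53.46 °C, 8.91 h, 0 % ethanol. Only the temperature coordinate is
treated as a pinned, reproducible quantity: the surface's ethanol curvature
(+0.001) is indistinguishable from zero, so the time/solvent coordinates of
any quoted optimum are not recoverable from the printed model and are
reported without being used as targets.

## Neural surrogate stage

Architecture: 3 inputs → H tansig units → 1 linear output, H ∈ 1..20.
Inputs and output are min–max scaled to [−1, 1] (standard for tansig
networks and necessary for stable damped Gauss–Newton steps). Training
minimises the sum of squared errors by Levenberg–Marquardt: the residual
Jacobian is assembled by backpropagation each epoch; λ starts at 1e−3,
×10 on rejected steps, ×0.1 on accepted ones. Stopping: 500 epochs,
training MSE below 1e−5 (scaled space), or 50 epochs without validation
improvement; the weights returned are those of the best validation epoch.
Initial weights are uniform(−0.5, 0.5) from a seeded stream.

The 27 conditions are split 21/3/3 (the nearest whole-condition split to
80/10/10) with replicates kept together to avoid leakage. Each hidden size
is trained with 100 seeded restarts by default (a desk-scale reduction of
a 1000-training sweep; both scales are available through `TrainConfig`),
the restart with the lowest validation MSE wins, and near-ties between
hidden sizes go to the smaller network. A quoted learning rate/momentum of
0.5 has no role in Levenberg–Marquardt and is not a parameter here.
Error metrics (MSE, MAPE, Pearson r) are reported on train, validation,
test and all data; headline comparisons use the all-data values,
stated explicitly wherever they are used.

On the packaged data the search selects H = 5 and reaches all-data
MSE ≈ 0.001–0.003, MAPE < 0.5 %, r ≥ 0.999 — the replicate noise floor
(mean within-condition variance ≈ 7e−4) bounds what any point-predictor
can achieve.

## Genetic algorithm stage

Real-coded 3-gene chromosome in actual units over the design box
(45–65 °C × 5–15 h × 0–100 %); the surrogate is never evaluated outside
the box it was trained on. Defaults: population 10, crossover 0.85,
mutation 0.02, ≤50 generations with patience 10, one elite. Selection is
fitness-proportional roulette; non-negative fitness is used as-is, and only
when negative values occur is the vector shifted by −min(f) (plus a small
floor so the wheel stays defined) — plain proportionality is the natural
reading for a positive assay response, and the shift exists only to keep
the wheel valid. Single-point crossover cuts at a gene boundary (after
gene 1 or 2, equiprobable); mutation resamples each gene uniformly within
its bounds with probability 0.02. Non-finite objective values quarantine
the individual at −∞ fitness. Sixty independent runs (seeds derived from
one master seed) are aggregated; the best-of-runs individual is the
reported optimum.

Resolution, calibrated against deterministic oracles: the best-of-60
aggregate lands within ~0.5 °C of the true surface maximum and within ~4 %
of the box range per gene on concave test surfaces, but *individual* runs
scatter by 1–2 °C — with uniform-resample mutation the algorithm has no
local refinement operator, so per-run precision is limited by the density
of random draws. Aggregate-level answers are the supported output.

## Hybrid pipeline and its honest precision

`ann_ga_optimize` = architecture search → best network → 60 GA runs.
Because the surrogate near-interpolates 27 points with ~26 parameters, its
*continuous* interior maximum is loosely pinned even when its fit metrics
are excellent: across master seeds the optimum temperature on the packaged
data ranges over ≈53–56 °C (time 8–11 h), and on synthetic quadratic
truths at σ = 0.02 the recovered argmax deviates from the analytic argmax
by up to ~0.4 coded units per curved coordinate. This is a property of
small-sample neural surrogates, not of the optimizer; the polynomial route
recovers noiseless truths to 1e−10. Users who need a tightly identified
optimum should read the quadratic's answer; the surrogate route's value is
flexibility, at the cost of peak-location variance. The package reports
the full per-run spread so that variance is visible.

## Assay statistics

All tests work from (mean, SD, n) sufficient statistics and agree exactly
with raw-data computation (asserted). Duncan's multiple range test uses
least significant ranges LSR(p) = q(αₚ, p, df_w)·√(MSW/n) with the
protection level αₚ = 1−(1−α)^(p−1), q from the studentized range
distribution, step-down protection (no pair inside a non-significant range
is declared significant), and harmonic-mean n with a warning when groups
are unbalanced. Letters are assigned from the smallest mean upward, so "a"
marks the lowest homogeneous subset. On the packaged factorial table the
computed display reproduces all 27 published superscripts, including the
overlapping `fg`/`cd` groups.

Confidence intervals default to the normal quantile (mean ± 1.960·SD/√n),
matching the published brackets; a t-based alternative is a flag away.
η² is reported as computed from the sums of squares (0.9994 on the
factorial table — any external figure inconsistent with the F statistic is
not reproduced). The t-test is the pooled-variance Student test; with
equal n = 3 per group the Welch correction would be cosmetic.

## Synthetic data generator

`generate_ffd` evaluates a known quadratic truth at the 27 design points
and adds homoscedastic Gaussian replicate noise — the replicate SDs of the
measured table are nearly constant (0.01–0.07 on a response of 5–9), so a
single σ (default 0.03) is the right emulation; `table1_like` uses the
fitted packaged surface as its truth. An optional third-order term
(x₁²x₂) provides a detectable misspecification for lack-of-fit power
studies; a pure x³ term would be aliased with the linear term on a
three-level design and is therefore deliberately not offered. The
generator does not emulate heteroscedastic assay drift, batch effects, or
any chemistry (phenolic profiles, dose–response curves) — passing tests on
synthetic data therefore certify the statistical machinery, not the
biology.

All randomness everywhere flows through explicit seeded
`numpy.random.Generator` streams; per-restart and per-run seeds derive
from one master seed, and identical seeds give bit-identical results.

## Problem sizes used by the packaged reproduction

The shipped reproduction settings are hidden-size sweep 1–10 with 100
restarts each, and 60 GA runs (about 10 s total); `--full` restores the
1–20 sweep with 1000 restarts. Simulation-based checks in the test suite
use 100–500 replications, sized for stable verdicts from their 4σ /
Kolmogorov–Smirnov acceptance bands.

## Known limitations

* Time and solvent coordinates of the surface optimum are weakly
  identified on the packaged data (flat directions); only temperature is a
  meaningful point estimate.
* The surrogate route's optimum location carries seed-to-seed variance of
  a few °C (see above); it is reported with its spread, never as a point
  truth.
* MAPE is undefined for responses at zero, and the Duncan implementation
  targets balanced or mildly unbalanced one-way layouts.
* Summary-based statistics cannot detect non-normality or outliers within
  replicates; they trust the published moments.
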