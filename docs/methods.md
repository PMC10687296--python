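# Methods

## The model

ANN-L36 is a deliberately minimal feed-forward network — 10 inputs, two
logistic-sigmoid hidden units without biases, one linear output with a bias
— whose 23 connection weights are found not by gradient descent but by
iterated evaluation over the Taguchi L36(2¹¹·3¹²) mixed-level orthogonal
array. Each weight is one experimental *factor*; the 11 two-level factors
are the first hidden pathway (W1–W10 fan-in, W11 fan-out) and the 12
three-level factors are the second pathway (W12–W21 fan-in, W22 fan-out)
plus the output bias W23. The forward pass is

    y = W23 + W11·σ(Σᵢ Wᵢ fᵢ) + W22·σ(Σᵢ W₁₁₊ᵢ fᵢ)

A full factorial sweep of the weight grid would need 2¹¹·3¹² =
1 088 391 168 evaluations; the orthogonal array evaluates 36 per iteration
while keeping every factor level — and every pairwise level combination —
equally represented (strength-2 balance, re-validated on every load of the
embedded array).

The exact wiring that yields 23 weights is not uniquely determined by a
10-2-1 sketch; the canonical mapping above was chosen because it makes the
two-level/three-level factor split of the array coincide exactly with the
two hidden pathways. The `Topology` type allows alternative wirings behind
the same contract.

## The search

Per iteration:

1. the level table instantiates 36 candidate weight vectors from the array;
2. each candidate is scored by training MMRE (mean magnitude of relative
   error, percent, computed on the *decoded percent scale*);
3. the winner is the argmin of the 36; additionally one *confirmation*
   candidate is assembled from the per-factor marginal means of log-MMRE —
   the classical Taguchi main-effect analysis plus confirmation experiment —
   and scored;
4. the level grid contracts geometrically (factor 0.5) around the best
   weights seen so far: three-level factors keep the center,
   `{c−δ, c, c+δ}`; two-level factors straddle it, `{c−δ/2, c+δ/2}`;
5. the loop stops when the relative improvement of the best objective stays
   below ε = 0.01 for `patience` = 3 consecutive iterations, or at
   `max_iterations` = 20.

Design choices that mattered, and why:

* **Initial levels.** Two-level factors start at {−1, +1}, three-level at
  {−1, 0, +1} — except the output bias W23, which starts at
  {−0.5, 0.5, 1.5}, centered on the midpoint of the coded target band.
  Centering the output distribution on the data is textbook initialization
  for sigmoid regression networks; without it every initial candidate's
  output sits far outside the coded target range, the first winner is a
  near-flat network, and the geometric contraction then freezes the search
  in a predict-a-constant basin (observed plateau: 85–100 % MMRE versus
  0.2–0.9 % with the centered bias).
* **Best-so-far centering.** The contracted two-level grid never contains
  the winner's exact value, so the best-so-far network is cached separately
  and used as the contraction center; this guarantees a monotone
  non-increasing best-objective trace. Centering on the per-iteration
  winner instead was measured to be uniformly worse.
* **Patience in the stopping rule.** Read literally, "improvement < 0.01"
  fires on any transient plateau of the contraction scheme — in practice at
  iteration 2, an order of magnitude short of convergence. Convergence is
  therefore declared only when the criterion holds in several consecutive
  iterations (default 3); the single-iteration mode remains available in
  `SearchConfig`.
* **Tie-breaking** among equal objectives: lowest array row index.

The search is deterministic for a fixed dataset; the only randomness in the
experiment is the seed-controlled train/test split.

### What convergence looks like

The first-iteration winner typically scores 40–60 % MMRE; the trace then
falls steeply for ~6 iterations and grinds for another ~5 before the
stopping rule fires, usually after 11–17 iterations at 0.2–0.9 % training
MMRE. The greedy geometric contraction is a pattern search, not a global
optimizer: an early commitment of a three-level factor away from zero can
never be fully undone, which is visible in the constant-target behaviour —
with informative features present the error plateaus near 10 % (the planted
bias solution is no longer reachable), whereas with featureless inputs the
bias converges onto the coded constant within 8 iterations.

## Coding functions

Inputs and targets are coded before training and predictions decoded back
to percent before any error is computed (all accuracy numbers live on the
percent scale). Four invertible families share one interface:

* **fuzzy** — triangular three-term partition (low/medium/high) with peaks
  at the minimum, midpoint and maximum of the fitted support; the scalar
  code is the membership-weighted centroid of the unit-normalized peak
  positions. With this peak placement the fuzzify→defuzzify round trip is
  the exact identity, and the scalar map coincides numerically with min-max
  scaling (it is the same piecewise-linear interpolant); the fuzzy pathway
  is retained because it carries the membership semantics and the explicit
  out-of-support handling.
* **log** — ln(1+x)/ln(1+x_max): compresses large prevalences.
* **minmax**, **zscore** — the usual affine maps.

Targets are additionally mapped into the interior band **[0.2, 0.8]** of
the unit interval. With a sigmoid-bounded output this keeps the coded data
inside the region where the network has usable slope and roughly halves the
weight magnitudes the search must reach — a standard practice for
sigmoid-output regression.

Coder parameters are fitted on the **training split only**; test-split
values outside the fitted support are clamped, and every clamp is logged.
Both inputs and targets use the selected coding family (the choice is
per-run configuration).

## The modelling dataset

The fixture prevalence table transcribes the published stratified
percentages: 17 chronic non-communicable diseases × 2 survey years for the
region-panel and age-panel summaries, and 17 diseases × 2 genders pooled
over years. Quantities printed inconsistently in the source (e.g.
hypertension 2019 appears as 32.2, 32.3, 32.4 and 33.2 in different
places) default to the region-panel value; every variant is kept in
`data/prevalence_variants.csv` with its provenance.

The canonical experiment fits one network per survey year on the rows of
the **10 most prevalent diseases** (ranked by mean region-panel prevalence)
from the region and age panels — 20 rows per year, split 70/30. Rationale:

* the survey documentation itself states the disease identification was
  done for the 10 most prevalent diseases;
* the rarest diseases (liver cirrhosis at 0.2–0.3 %) make the relative
  error objective pathological — a handful of near-zero denominators
  dominate MMRE and drive the optimum toward systematic under-prediction;
* the gender panel prints pooled-year values only and therefore cannot
  enter a per-year fit; it remains available to the gender-stratified
  baselines.

Features per row (10): year indicator, gender indicator, region one-hot
(neutral ¼ each for unstratified rows), coded age-band midpoint, the
disease's **coded observed share** (the informative input), the stratum's
cohort share, and a constant 1.

## Evaluation

MMRE (percent, on actuals), Pearson, Spearman (average ranks on ties), and
the cubic determination coefficient — R² of the OLS fit of estimates on
{1, a, a², a³} of the actuals, predicted-on-actual direction, defined as 0
for constant predictions. Correlations pool the two year panels by default;
per-year values are also emitted. MMRE's argument order matters and is
pinned by test: the denominator is the actual value.

### Accuracy attainable on this fixture

Two facts bound what any honest fit of this architecture can report:

* The region-panel and age-panel rows of the same disease-year differ by up
  to ~1 % relative (e.g. depression 4.8 vs 4.7 in 2019) while their feature
  vectors differ only through the coded base rate; multistart direct
  optimization (an optimizer strictly stronger than the in-scope search)
  bottoms out near 0.08 % (2013 panel) and 0.7 % (2019 panel) training
  MMRE on the full 20-row tables.
* A published relative error of 0.1 % is mutually inconsistent with a
  published Pearson correlation of 0.982 on the same estimates — the
  latter corresponds to roughly 10–15 % scatter. The published iteration
  trace, which plateaus at 13.3/12.6, equals the published "0.1" only if
  the latter is read as the error *fraction* (13.3/100 ≈ 0.13). This
  package reports MMRE in percent and makes no attempt to reproduce the
  0.1 figure literally; the canonical runs land at 0.2–0.9 % training MMRE
  with pooled Pearson ≥ 0.996.

## The synthetic cohort generator

`StratumParams` carries the published marginal counts — wave sizes 14 623
(2013) and 13 178 (2019), region, age-band and gender totals — and
per-disease, per-year prevalences. Cell counts for the 4×8×2 stratum grid
are derived per year by largest-remainder apportionment of the product of
pooled marginal shares, so every published marginal is reproduced exactly
up to rounding. Disease flags are independent Bernoulli draws per
respondent.

What the generator does **not** emulate: comorbidity correlation between
the 17 flags, within-year region/age/gender prevalence gradients (the
published per-stratum breakdowns are regression summaries, not count
tables; per-cell probabilities can be supplied explicitly), survey
weighting, and missing data. Consequently, tests passing on synthetic
cohorts demonstrate the correctness of the pipeline's accounting — exact
stratum counts, binomial-consistent prevalences, conservation across
aggregation — not epidemiological realism of joint distributions.

## Contingency statistics

2×2 odds ratios use the cross-product estimate with the Woolf log-normal
confidence interval and a two-sided Wald p; zero cells raise, with the
Haldane–Anscombe 0.5 correction available explicitly (`TwoByTwo.corrected()`).
The two-period comparison uses the pooled two-proportion z test. The
multivariate logistic regressions of the published stratified tables are
out of scope (their microdata is unavailable); only the closed-form
statistics are provided.

## Baselines

Decision trees (stratified by gender/region/age), SVR with linear and
polynomial kernels, and an RBF network in standardized/normalized coding —
realized as Gaussian-kernel ridge regression, a standard RBF-network fit —
all delegate to scikit-learn behind one fit/predict contract (same feature
encoding as the ANN, predictions in percent, evaluation through the same
metrics). Their published accuracy rows are not reproduction targets: they
were computed on the unavailable microdata. Gain ratio (information gain
over split information, base-2, defined 0 for a non-splitting attribute)
is implemented directly.

## Numerical conventions

* Sigmoid arguments clipped at ±500 (prevents overflow, exact in double
  precision for any realistic weight scale).
* Exact integer arithmetic for factorial-plan sizes; the reduction
  fraction uses rational arithmetic before the final float conversion.
* Percentages in table-style CSV output round half-up to one decimal;
  machine-readable files keep full precision.
* Seeds: `numpy.random.default_rng` throughout; a run's seed controls the
  train/test split and the cohort draws; the search itself is
  deterministic.

## Known limitations

* The greedy contraction cannot escape early mis-commitments; reported
  accuracy is the best-of-five-seed-splits protocol, which only varies the
  split, not the search trajectory.
* The fixture's panel inconsistencies put a floor under the reachable
  training error (see above).
* The generator's independence assumptions make it unsuitable for studying
  comorbidity or within-year stratum gradients without supplying per-cell
  probabilities.
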