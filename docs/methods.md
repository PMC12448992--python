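# Methods

## Generative observer models

All four architectures share one generative front end. On a trial with true
auditory position `s_A` and visual position `s_V` (each in {−9°, 0°, +9°}),
the observer receives internal signals

    x_A ~ N(s_A, σ_A),   x_V ~ N(s_V, σ_V),

and holds a central spatial prior `N(μ_P, σ_P)` over source locations with
`μ_P` fixed at 0 (a central bias; the prior mean is never fitted). The
structure-conditional location estimates are the standard precision-weighted
averages: under a common cause,

    Ŝ_C1 = (x_A/σ_A² + x_V/σ_V² + μ_P/σ_P²) / (1/σ_A² + 1/σ_V² + 1/σ_P²),

and under independent causes each signal is shrunk toward the prior alone.
The architectures differ only in how they arbitrate between these
estimates:

* **BCI** computes the posterior probability of a common cause from the
  prior `p_common` and the marginal likelihoods `p(x_A, x_V | C)`. These
  marginals are not usually written out; because sources are Gaussian and
  noise is Gaussian, both are available in closed form:

      p(x_A, x_V | C=1) = N₂([x_A, x_V]; μ_P, Σ₁),  Σ₁ = diag(σ_A², σ_V²) + σ_P² 11ᵀ
      p(x_A, x_V | C=2) = N(x_A; μ_P, σ_A²+σ_P²) · N(x_V; μ_P, σ_V²+σ_P²)

  We implement these closed forms (validated against dense numerical
  integration over source locations to 10⁻⁶; see the quadrature oracle in
  the tests) rather than integrating numerically — exactness and speed.
  The final estimate is the model average, e.g.
  `Ŝ_A = p(C=1|x) Ŝ_C1 + (1 − p(C=1|x)) Ŝ_A,C2`. Model selection and
  probability-matching decision functions are deliberately out of scope.
* **FF** is BCI with `p_common = 1`: mandatory fusion, no disparity or
  response-modality effects.
* **FC** integrates iff the *internal* disparity `|x_A − x_V|` is at most
  `k_C` — the criterion is applied to the noisy signals, not the true
  stimulus disparity, so the decision is itself stochastic across trials.
* **SF** integrates with probability `η` on each trial, independent of
  disparity. The architecture is read as a per-trial Bernoulli(η) fusion
  choice (a uniform draw compared against η): a literal fixed indicator
  `η > 0.5` would make the strategy deterministic and η unidentifiable
  beyond a binary switch, contradicting its description as the
  *probability* of reporting a common cause.

Continuous estimates are discretized to the three response options by
nearest-position bins with boundaries at ±4.5°, half-open `[−4.5, 4.5)` for
"centre" so behaviour at the (measure-zero) boundary is deterministic. The
discretization rule is a design choice; nearest-position is the
minimal-assumption reading of a three-alternative report.

## Synthetic cohorts

The trial generator reproduces the factorial design: 4 runs × 18 blocks ×
9 trials; each block contains every (s_A, s_V) combination exactly once in
seeded random order; action intention alternates per block; response
modality changes every two blocks with the starting modality alternating
across runs so the 36 cells balance at 18 trials each. The
intention-to-modality pairing and starting labels are exposed as options
since a fixed convention is arbitrary.

Between-participant variability is log-normal for σ_A, σ_V, σ_P and k_C
and logit-normal for p_common and η (respecting supports). Response times
on valid trials are log-normal (median 0.55 s, log-SD 0.25) and clean
saccade amplitudes uniform on [0, 3]°: RTs and gaze are not modelled
substantively — they only need to pass or fail the exclusion filters
plausibly, and raw gaze traces are out of scope (the pipeline consumes a
per-trial scalar saccade amplitude). Contaminated trials are marked
missed (no response), premature (RT < 100 ms) or saccade-contaminated
(amplitude uniform on [7.5, 15]°), with ground-truth labels retained so the
filters can be tested exactly.

Two cohort presets emulate the study conditions. Both give the
communicative condition a higher common-cause prior; the first preset also
gives the non-communicative condition a larger auditory noise (its shorter,
static stimuli localize poorly), while the second equates auditory noise
across intentions, isolating the prior difference. Visual noise is small
(1.5°) and equal in both presets — high visual reliability. Because the
fitted parameter tables of the original study are not available, the preset
magnitudes were chosen once to reproduce the reported directions and effect
sizes of the intention effects and are not tuned further.

What the generator does *not* emulate: real response biases that differ
across hemifields, lapses and attentional drift, sequential dependencies,
RT–difficulty coupling, and eye-movement dynamics. Passing tests on this
synthetic data therefore validate the estimation and inference machinery,
not the psychological adequacy of the models for any particular dataset.

## Fitting

Predicted response distributions have no closed form after discretization,
so they are simulated: 10,000 internal-signal draws per condition by
default, pushed through the architecture's decision rule and discretized;
relative frequencies give multinomial category probabilities. Predicted
probabilities are floored at `1/(10·n_sim)` and renormalized so finite
simulations can never produce a −∞ log-likelihood; the floor is
configurable since the choice is not dictated by the model. The
log-likelihood sums `n_ij log p_ij` over conditions and categories; the
multinomial coefficient is constant in the parameters and omitted
(consistently, so it cancels from all likelihood differences).

Common random numbers make the objective deterministic: one fixed
standard-normal substream per spatial combination is rescaled by the
candidate σs on every evaluation, and one fixed uniform substream drives
the SF fusion choice. Optimization runs in transformed space (logit for
p_common and η, log for the σs and k_C): a coarse grid (p/η at
0.1–0.9 step 0.2; σ_A, σ_V log-spaced over [0.5°, 32°]; σ_P log-spaced
over [2°, 32°]; k_C at {1, 5, 10, 20}°) scores all combinations, the top
three points each seed a Nelder–Mead simplex, and ties are broken toward
the smaller transformed-parameter norm. A final short simplex polish from
the best point at 5× the simulation count (capped at 20,000, fresh
substream) reduces the Monte-Carlo noise of the reported optimum at a
fraction of the cost of running everything at the larger count.

Pooled models share one parameter set across intentions (predictions do
not depend on intention, so counts are pooled); separated models fit each
intention independently and double k. Goodness of fit is the
likelihood-ratio R² against the uniform three-choice null
`l(0) = n ln(1/3)`, scaled by its attainable maximum
`max(R²) = 1 − exp((2/n) l(0))`; n is the participant's count of valid
(post-exclusion) trials. Model evidence is approximated by
`BIC = −ln L̂ + k ln n`; this is the form used throughout (a conventional
`−2 ln L̂ + k ln n` switch exists), and the log evidence passed to group
selection is −BIC. Rankings within a participant are unaffected by the
convention since n is fixed.

### Identifiability

Two structural limits of the three-alternative paradigm matter when
interpreting fits. First, once σ_V is small enough that visual estimates
essentially never cross a ±4.5° bin boundary (≈ below 2°), the likelihood
is flat in σ_V from below — it is identified only from above. Second,
`p_common` and σ_P trade off along a likelihood ridge: weaker priors with
smaller common-cause probability mimic stronger priors with larger ones,
and at 18 trials/condition single-participant estimates of `p_common`
scatter widely (SD ≈ 0.15–0.19) with a mild downward attenuation of
cohort means (≈ 0.05–0.1 for generating values near 0.7). The attenuation
is a property of the maximum-likelihood point estimate under count noise,
not of the optimizer: the likelihood at the generating parameters is
reliably below the returned optimum. Cohort-level recovery studies (below)
quantify both effects.

## Group-level model selection

Model identity per participant is treated as a random effect with a
symmetric Dirichlet(1) prior over population model frequencies. A
variational scheme iterates participant-wise model responsibilities and
Dirichlet concentration updates to convergence; exceedance probabilities
are estimated by direct Dirichlet sampling (10⁵ draws by default, seeded —
Monte-Carlo error well below 10⁻³ at the reported precision). The Bayesian
Omnibus Risk is the posterior probability of the null model in which all
frequencies equal 1/K, computed from the free energies of the two models,
and protected exceedance probabilities follow
`pEP = EP·(1 − BOR) + BOR/K`.

## Behavioural statistics

Trials are excluded in a fixed order: missed responses; premature
responses (RT < 100 ms); RT outliers, defined as `|rt − median| > 3·SD`
with the median and SD computed per participant across conditions after
the premature removal (the distance-from-median reading of an "RT more
than 3 SD from the median" rule); saccade trials (amplitude > 7°, half the
video width).

The w_AV index for an incongruent trial is
`(reported − baseline(s_A)) / (baseline(s_V) − baseline(s_A))` with
baselines taken from congruent-trial *reports* (absorbing constant
response biases), either pooled across participants and conditions for
precision or per participant × condition for bias-robustness; trial values
are averaged within disparity level (9° low, 18° high). Identical
baselines make a cell undefined and raise rather than silently propagate.

Permutation inference on within-participant contrasts relabels the
contrasted condition labels independently within each participant — for
two-level contrasts this is a sign flip of each participant's contrast
value. A between-participant relabeling reading exists but does not apply
cleanly to a fully within-subject factorial, so the within-participant
scheme is used. Defaults: 4,096 permutations; two-tailed
`p = (b + 1)/(m + 1)` (standard Monte-Carlo smoothing, so p > 0 always);
effect size = observed statistic − null mean; 95% CI from a 2,000-draw
participant-level bootstrap percentile interval (the CI's construction is
otherwise underdetermined). Pearson correlations report r, a two-tailed
t-based p, and the regression line with a pointwise 95% conditional-mean
band for plotting.

Power analysis inverts the exact noncentral-t power function of a
one-sample/matched-pairs t-test by integer search (the two designs
coincide for a given standardized effect size, which a Monte-Carlo oracle
confirms in the tests); camera geometry is `S = 2·D·tan(α/2)`.

## Validation studies and problem sizes

The `validate` module packages the self-validation studies used by the
test suite and `scripts/acceptance.py`.

* **Parameter recovery**: 34 participants × 648 trials under
  BCI-separated, generating priors 0.7 (communicative) vs 0.4
  (non-communicative), σ_P = 12°, σ_A = 4.0/4.85°, σ_V = 2.5° (placed in
  the identifiable interior — see above), between-participant logit-SD 0.4
  and log-SD 0.2; fits at 2,000 simulations/condition (20,000 in the
  polish stage). Reported: cohort-mean p_common error per intention,
  median relative σ errors, and the fraction of participants with a
  positive fitted prior difference.
* **Model recovery**: 20 participants per architecture, pooled fits of all
  four architectures at 2,000 simulations/condition, followed by
  random-effects model selection. Each architecture is simulated at a
  representative regime where its decision signature is expressed (BCI at
  p_common 0.7, σ_P 8°, σ_A 6°; the heuristics at σ_P 12°, σ_A 4.4°, k_C
  7°, η 0.55). This matters: in weak-prior regimes BCI and FC produce
  nearly indistinguishable predictions and confuse with each other — the
  mimicry that makes FC a serious competitor in the first place — so
  recovery there is uninformative about the machinery.
* **Statistics calibration**: type-I error of the permutation test over
  1,000 exchangeable null cohorts of 34; w_AV limits on ~10⁴ forced-fusion
  trials with strongly asymmetric reliabilities (auditory-report w_AV → 1
  when vision dominates, → 0 when audition dominates) and the decrease of
  auditory-report w_AV from 9° to 18° disparity under BCI.
* **Correlation study**: 34 participants whose noise SDs are shared across
  intentions while p_common differs (means 0.65 vs 0.45, logit-SD 0.5), so
  the prior difference is the primary driver of behavioural differences;
  fitted Δp_common is correlated with the observed auditory-report Δw_AV.

These sizes keep a full validation pass in the tens of minutes on one CPU
while leaving the fitting machinery identical to full-scale use (only
`n_sim` is reduced from the 10,000-draw default).

## Known limitations

* The heuristic architectures are fitted with the same simulation-based
  machinery as BCI; no closed-form shortcuts are exploited for FF even
  though its fused estimate is analytically Gaussian.
* σ_P is weakly constrained by a three-position design; its recovery is
  acceptable in the median but individual estimates can drift far along
  the p_common/σ_P ridge.
* The BMS null free energy uses the standard fixed-frequency bound; for
  very small cohorts the BOR is conservative.
* Group-level inference on parameters is two-stage (fit, then test point
  estimates); no hierarchical estimation or MCMC posterior inference is
  provided, and continuous-report likelihoods are out of scope.
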