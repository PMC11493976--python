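# Methods

## The decision problem

An observer watches a field of moving dots whose directions are drawn each
frame (120 Hz) from a von Mises distribution and must report, as quickly
and accurately as possible, whether the mean direction lies left or right
of vertical. Evidence quality is manipulated over the first second of the
2 s stimulus through the distribution's mean offset from the axis
(`delta`, degrees) and its concentration (`kappa`), in nine conditions:
ramps of the mean (up/down), ramps of the concentration (up/down), three
stable levels, and two opposed schedules of moderate net quality.

## Ideal-observer evidence

On each frame the observer fits a von Mises distribution to the dots
currently on screen (circular mean; ML concentration from the mean
resultant length via the standard truncated-series inverse of
`A(kappa) = I1/I0`, capped at 500 for degenerate samples). The momentary
evidence for "left" is

    nu_L = log p(mu < theta0 | mu_hat, kappa_hat),

the log probability mass of the fitted density in the left half-circle,
estimated by trapezoid integration on a 4096-point grid per half circle
(the normalisation constant cancels between numerator and denominator);
`nu_R = log(1 - exp(nu_L))` by the two-alternative structure. The frame's
circular variance `1 - I1(kappa_hat)/I0(kappa_hat)` is stored alongside.

Estimation pools all 100 dots visible on the frame. Because dots live for
10 staggered frames (one cohort of 10% is redrawn per frame), successive
estimates are strongly autocorrelated, exactly as in the display.

## Accumulation models

All variants accumulate, at the display frame rate (dt = 1/120 s), the
momentary evidence plus independent zero-mean Gaussian noise per side, with
variance `sigma^2 * circ_var_t` — internal noise scaled by the momentary
stimulus uncertainty. The scaling is applied in every variant for
comparability (switchable). One modelling choice deserves emphasis: the
accumulated increment is the log-likelihood ratio against an uninformative
frame, `nu - log(1/2)`, rather than the raw log probability. Raw log
probabilities are always negative, so a race of two such accumulators can
never reach a positive bound; measuring each frame against chance leaves
the left-right difference (and therefore the confidence read-out and the
sequential-probability-ratio-test interpretation) unchanged while making
the race well posed. After stimulus offset (2 s) evidence increments are
exactly zero and simulation continues to a hard 4 s horizon, after which
the larger accumulator determines the choice and the trial is flagged as
timed out. Non-decision time is folded Gaussian, `|N(mu_U, sigma_U^2)|`.

- **classic** — race of the primary accumulators to a fixed bound `b`
  (first past the bound, other side below it; simultaneous crossings go to
  the larger excursion, exact ties to a random draw).
- **weibull** — classic with bound collapsing along
  `b * (1 - (1 - a_w) * W(t; lambda_w, k_w))`, `W` the cumulative Weibull.
- **bottom_up** — classic with the evidence increment weighted by
  `beta / (beta + sigma2_cum)` as it is accumulated.
- **static_lit** — a motor accumulator re-integrates the primary one with
  constant leakage, `y_t = y_{t-1} + alpha (x_t - y_{t-1})`, and triggers
  the choice at its own bound.
- **conf_control** — the same double integration with the leakage set
  on-line from confidence:

      c_L = logistic((x_L - x_R) * beta / (beta + sigma2_cum)),
      alpha_L = max(c_L - p_c(t), 0),

  where `sigma2_cum` is the running sum of the per-frame noise variances
  (the variance of the accumulated evidence) and `p_c` is 0.5 until an
  urgency onset `t_d`, then decays linearly to 0 at stimulus offset. As
  `beta` grows, the read-out approaches the exact Bayesian posterior
  `logistic(x_L - x_R)`.

Free parameters of the confidence-control model are `sigma`, `beta`,
`t_d`, plus the two non-decision-time parameters; the motor bound is fixed
across subjects (`b = 6.0`, calibrated once on pilot simulations, see
below).

The terminating simulation kernel (numba) and a fully vectorised
reference path (numpy; used wherever latent time courses are needed) share
the same dynamics; a test asserts trial-by-trial agreement of their
outcomes. The dynamics have no post-commit feedback, so first crossings
derived from full paths equal the terminating kernel's.

## Fitting

Choice/RT likelihoods use the quantile Monte-Carlo method: per condition
and choice, observed RTs are binned into 10 empirical quantile bins (open
outer edges, half-open intervals, cells with fewer trials collapse to one
bin per trial); the model's cell masses are estimated from simulations of
each unique stimulus (weighted by trial frequency within condition) and
floored at `1/(2 n_sims)`; the NLL is the multinomial score of the
observed counts. Binning is per condition because per-stimulus cells would
be single-trial (switchable).

Simulation noise is held fixed across objective evaluations (common random
numbers; per-stimulus seeded generators, antithetic pairs) so the
objective is a deterministic, relatively smooth function of the
parameters. Optimisation is bounded Powell search with strictly positive
scale parameters (`sigma`, `beta`, `b`, `sigma_U`, ...) searched in log
space, seeded by the best points of a 30-point Latin-hypercube screen,
with multistarts and an optional refinement stage on a higher-precision
objective. Log-scale search matters: the likelihood surface has a
`beta`/`sigma` ridge that defeats linear-scale Powell.

Model comparison: BIC (`2 NLL + k ln n`) and random-effects Bayesian model
selection — variational Dirichlet posterior over model frequencies,
exceedance probabilities by Dirichlet Monte-Carlo, protected by the Bayes
omnibus risk (`PXP = EP * (1 - BOR) + BOR / K`), with `-BIC/2` as the
log-evidence approximation.

## Confidence prediction

Post-decision confidence is predicted with no additional parameters: 1000
noisy instances of the fitted process are simulated on the trial's
stimulus; instances reproducing the observed choice within 100 ms of the
observed RT are kept (window doubled up to 4x if empty, then the
nearest-RT instance with the observed choice); the prediction is the
median commit confidence of the chosen side, and response-locked medians
of the latent traces feed the encoding analysis. Predicted confidence is
correlated with within-subject z-scored ratings and Fisher-transformed.

## Sensor encoding

Multichannel response-locked epochs (250 Hz) are modelled as a linear
mixture of latent regressors, `Y = X w`, estimated by OLS and inverted by
least squares on the weight matrix to predict the latents from held-out
data (10-fold cross-validation, folds assigned by whole trials). The
regressors are the *slopes* of the primary and motor accumulators (plus an
intercept): the raw traces are strongly correlated ramps, while their
derivatives separate the near-linear primary profile from the accelerating
motor profile. Sensor slopes use a 6-sample sliding OLS window, latent
slopes a 3-sample window after linear interpolation of the 120 Hz traces
to the sensor grid; each slope is assigned to its window's final sample
and the series are paired per sample (the alignment rule is this
package's choice). An 8 Hz zero-phase 4th-order Butterworth lowpass
precedes the slope computation. Per-sensor precision maps use
single-sensor decoding via the pseudo-inverse. Confidence decoding encodes
the single per-trial rating at each post-response timepoint (0-200 ms),
selects the timepoint with the greatest cross-validated precision, and
applies those weights across pre-response time to obtain an online
confidence signal; the within-trial correlation of that signal with the
motor slope in the final 200 ms, median-split within subject and
condition, summarises confidence-control strength against accuracy and
median RT.

## Synthetic study conditions

The generator emulates the study design: a bank of unique stimuli per
condition sampled once and reused across trials, 100 trials per condition
(900 per subject), subject parameters drawn from truncated Gaussians
(sigma ~ N(1.2, 0.25) in [0.5, 2], beta ~ N(2.0, 0.6) in [0.3, 6],
t_d ~ N(1.0, 0.3) in [0.2, 1.8], mu_U ~ N(0.3, 0.05), sigma_U ~
N(0.15, 0.03)), the motor bound fixed at 6.0, and ratings generated as the
commit confidence perturbed by Gaussian noise (sd 0.5) on the log-odds
scale. Condition anchors are delta = 1.5/3.0/5.0 degrees and
kappa = 1.0/2.0/4.0. Anchors, bound and parameter centres were calibrated
once on pilot simulations to reproduce the qualitative behavioural
envelope of the task — accuracies spanning roughly 0.6-1.0 across
conditions, right-skewed RTs with condition medians between about 0.7 and
1.5 s, and a small proportion of very slow trials — and are not revisited.
Sensor epochs are a clean linear forward mixture of latent regressors plus
white Gaussian noise at a stated SNR; real sensor data additionally
contain artefacts, drift and correlated noise that the generator
deliberately omits, so passing recovery tests demonstrates correctness and
identifiability of the pipeline under the model, not validity of the model
for any particular dataset.

## Problem sizes used by the test suite and acceptance script

Analyses run at scaled-down sizes chosen as the package's own defaults:
termination comparison, 9 conditions x 1000 paired simulations (bank of 4
stimuli per condition); parameter recovery, 10 subjects x 900 trials
fitted with 500 simulations/stimulus, 3 multistarts and a 2000-simulation
refinement (bank of 2 stimuli per condition); model recovery, 10 subjects
x ~300 trials, both variants fitted per subject; confidence prediction, 6
subjects x 90 rated trials with 1000 conditioned simulations per trial;
encoding checks, 40-trial forward datasets, 100 topography runs, 50
shuffle nulls.

## Known limitations

- `beta` and `t_d` are weakly identified from choices and RTs at 900
  trials under these conditions: likelihood profiling at high Monte-Carlo
  precision shows changes of only a few NLL units across a factor-2 change
  in `beta` or +-0.6 s in `t_d`. `sigma` recovers to a few percent;
  `beta`/`t_d` estimates scatter correspondingly. Confidence ratings,
  which the fits deliberately exclude, are the natural source of the
  missing constraint.
- At ~300 trials per subject the classic and confidence-control models are
  statistically indistinguishable for a sizeable minority of cohort draws;
  clean separation (per-subject ΔBIC 15-60) emerges at the full 900-trial
  session length.
- The hard 4 s horizon and the uninformative post-offset evidence are
  simulation conveniences; trials reaching the horizon (a few percent at
  default parameters) are flagged `timed_out`.
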