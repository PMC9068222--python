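# Methods

## Models

Three trial-level architectures share the update `x(n+1) = a·x(n) + b·e(n)`
(retention `a` in (0, 1], error sensitivity `b` in [0, 1), angles in
degrees, states starting at 0):

* **Competition** — implicit and explicit learners both driven by target
  error `r − (x_i + x_e)`.  Coupled asymptote
  `x_i_ss = b_i(1 − a_e) r / D`, `x_e_ss = b_e(1 − a_i) r / D` with
  `D = (1 − a_i + b_i)(1 − a_e + b_e) − b_i b_e`.  `D` expands to
  `(1 − a_i)(1 − a_e) + (1 − a_i) b_e + b_i(1 − a_e)` and is therefore never
  negative; it vanishes only when both learners are pure integrators
  (`a_i = a_e = 1`), where simulation is fine but the asymptote split is
  degenerate — `coupled_steady_state` raises there rather than the
  constructor rejecting parameters that simulate perfectly well.
* **Independence** — the implicit learner is driven by the aim-anchored
  error `r − x_i`; its asymptote `b_i/(1 − a_i + b_i)·r` is unaffected by
  strategy.
* **Dual target error** — two implicit sub-modules, one fed the primary
  target error, the other the aim-anchored error, active only when an
  aiming landmark exists.  With constant aim `A` the summed asymptote is
  `b(2r − A)/(1 − a + 2b)`; the two modules share `(a, b)` by default, with
  a distinct second pair available.

The explicit state is either its own state-space learner or a prescribed
aim sequence (instructed experiments).  Probe trials (exclusion /
no-feedback) withhold the error entirely: states purely retain, matching
how retention is estimated from decay.  Clamped feedback pins both error
channels to the imposed clamp, giving the `b_i/(1 − a_i)·r` asymptote.
One update per trial; epoch- or cycle-level parameters are converted with
`convert_retention` (`a^(1/k)` / `a^k`) rather than simulated at epoch
granularity.  Sign convention: rotation positive, adaptive states positive
when opposing it.

Exposure-tagged schedules let sensitivities `(b_i, b_e)` switch at declared
block boundaries while retention stays fixed — savings and interference are
modelled as sensitivity changes, which is also what the tied fits estimate.

## Estimation

* **Retention** (`fit_retention`): least-squares `a` in `y(n) = a^n y_ss`
  over a no-feedback decay, bounded scalar minimization (tolerance 1e−10).
* **Empirical error sensitivity**: for consecutive visits to a target,
  `b(n1) = (y(n2) − a^(n2−n1) y(n1)) / e(n1)`.  Zero-error pairs are
  dropped and counted, never imputed.  Outliers are flagged when an
  estimate deviates from the median of a centred 10-epoch window by more
  than 3 raw median absolute deviations (edge windows truncate).  The
  steady-state summary is the mean of retained estimates over a terminal
  window — last 5 epochs by default, configurable to a cycle range; the
  recovery studies below use the last 10 epochs, where the estimate is
  stable at their noise level.
* **State-space fits**: bounded least squares (`a ∈ [0.5, 1]`,
  `b ∈ [0, 0.999]`) over the trial-level simulators, with a tie map
  declaring each of `a_i, a_e, b_i, b_e` shared, per-exposure,
  per-observation, or fixed.  The observation map states, per trial,
  whether the measured reach reports `x_i + x_e` (ordinary / high
  preparation time) or `x_i` alone (exclusion / low preparation time);
  fitting a competition model with free explicit parameters but no
  implicit-only observations is flagged as weakly identified rather than
  silently accepted.  The cost surface is nonconvex, so fits use 10
  seeded uniform restarts within bounds by default and keep the best
  optimum.
* **Exponential rates**: `y(n) = asy + (start − asy)·e^(−rate·n)` with the
  start pinned to the measured pre-onset baseline (n = 0; the first fitted
  sample is n = 1).  The x-intercept is solved analytically from the fit
  and exists only when start and asymptote have opposite signs.  Savings is
  quantified by the exposure-2/exposure-1 rate ratio plus the pre/post
  onset angle-difference contrast; anterograde interference by the B/A rate
  ratio after sign-flipping the opposite-direction B curve, optionally
  refit from the fitted zero crossing onward (start pinned to 0) to remove
  the influence of the initial opposite-sign error.
* **Bootstrap**: subject-level resampling with replacement, percentile
  (2.5, 97.5) intervals, fully determined by the seed.  Group-stratified
  resampling is used when a decomposition carries group labels.
* **AIC**: the Gaussian-likelihood form `n·ln(rss/n) + 2k` (undefined at
  rss = 0, which raises).  Winner counts are per-subject minima.

## Competition map

Percent change of the coupled implicit asymptote over a grid of percent
changes in `(b_i, b_e)` relative to a reference parameter set, retention
fixed; default grid −100%..+200% in 1% steps at r = 30°, tolerance 5%.
Because `x_i_ss ∝ b_i / D` with `D` bilinear, iso-change contours are
exactly affine in `(b_i, b_e)`; the Region-C bounds are returned in closed
form and every point on them evaluates back to ±tol exactly.  Region labels:
A matching decrease, D matching increase, B mismatching decrease,
E mismatching increase, C perceived invariance (closed region — boundary
ties break into C, since the defining condition is a strict "< tol").

## Rival models

The SPE+generalization account leaves the implicit asymptote at `p_i·r` but
attenuates the *measured* probe value by an aim-centred curve:
`x_i_measured = p_i·r·g(x_e)`, Gaussian `g` with σ = 37.76° by default (the
generalization width reported for aim-anchored adaptation), or a linear
curve whose default slope matches the Gaussian at 22.5°.  Generalization
applies only to the probe measurement, never to the learning dynamics.
`correct_explicit` inverts the attenuation by bracketed root-finding to
recover the actual strategy from an apparent one.  The explicit-responds
account, `x_e_ss = p_e (r − x_i_ss)` with `p_e < 1`, reverses two of the
three pairwise correlation signs; `correlation_sign_predictions` returns
the implied slopes for both accounts.

For model selection on decomposed cohorts, both candidate models predict
the probe-measured implicit value from measured **total** adaptation:
competition through its total-learning form `x_i = p(r − x_T)/(1 − p)`, the
rival through `p·r·g(x_T − p·r)`.  Predicting from total rather than from
the derived explicit measure keeps the comparison symmetric and avoids
handing either model the very probe measurement it must predict (explicit
is defined as total minus that probe, so probe noise enters it with
opposite sign and a naive comparison rewards the competition line for
fitting shared noise).  The gain is fitted at the group level on the final
block and individuals are scored on held-out blocks, mirroring the original
fit-one-block / predict-the-rest design.

## Synthetic cohorts

`make_schedule` builds trial-accurate designs: abrupt (10 baseline epochs,
60 rotation epochs of 4 trials, optional terminal exclusion probes and
15 no-feedback decay epochs), stepwise (15/30/45/60° blocks of 66 trials
with exclusion-probe sets at ~75% and at each block end), gradual ramp,
A–B interference (+30/−30 with a no-feedback break), invariant error clamp,
and washout savings (two same-sign exposures around a veridical washout,
exposure-tagged for sensitivity overrides).

`generate_cohort` samples per-subject parameters from truncated normals
(rejection sampling against the learner invariants).  By default only the
explicit side varies between subjects — strategy use is the dominant
individual difference — with implicit-side variability available as an
option, and the explicit-responds model varying the implicit side since its
strategy is reactive.  Motor noise is Gaussian, σ = 3° by default (typical
reach endpoint variability; the experimental designs emulated here do not
publish a trial-level noise figure).  The same noise draw that perturbs the
observed reach also shifts the errors the learners experience on feedback
trials (`noise_in_dynamics=True`): motor noise is executed, so the cursor
error the learner responds to contains it.  This coupling is what makes the
empirical error-sensitivity ratio consistent — with observation-only noise
the analyst divides by an error the learner never saw, and the estimator
acquires a large positive bias (measured at ~+0.12 at σ/e ≈ 0.7 in the
pilot design of the recovery study).  Observation-only noise remains
available for analyses that need it.  Exclusion probes report `x_i + ε`
with no state update; an optional generalization curve attenuates probe
observations for rival-model cohorts.  Every dataset retains its generating
truth for recovery reports (bias, RMSE, CI coverage).

What the generator does not emulate: reaction times and preparation-time
manipulation (low-PT trials are represented directly as implicit-only
observations), verbal aim reports, trial-to-trial drifts in retention,
target-specific adaptation states, and time-based decay during breaks
(probes apply zero-error retention only).  Passing recovery tests therefore
demonstrate estimator correctness under the stated noise model, not
robustness to every feature of real reach data.

## Study conditions used in the recovery and selection suites

* Recovery (limit-PT emulation): 30 subjects, abrupt 30° rotation, 60
  epochs of 4 trials, 15 decay epochs, σ = 3°, trial-level `a_i = 0.985`
  and `b_i = 0.0895`.  Analyses run on epoch means: the epoch retention is
  `0.985⁴ ≈ 0.941` and the epoch-level steady-state sensitivity has the
  closed form `b·(1 − a⁴)/(1 − a) = 0.35`, which is the recovery target.
  Epoch averaging halves the noise against a ~4° steady-state error;
  at trial resolution the ratio estimator's heavy tails make the summary
  unusable at this noise level, which is why the epoch level is the
  analysis default here.
* Regression/decomposition cohorts add a state-space explicit learner
  (`a_e = 0.95`, `b_e ~ N(0.15, 0.08)` truncated to [0.01, 0.6]) so that
  strategy carries the between-subject variability.
* Model selection: stepwise cohorts of 30 subjects, σ = 3°; the
  generalization-generated arm uses a modest implicit gain
  (`a_i = 0.98`, `b_i = 0.0125`, gain ≈ 0.38) with strategy doing the bulk
  of the learning — the regime in which the rival account is a live
  explanation; a gain of 0.86 under independence leaves strategies of a
  few degrees and nothing for the models to disagree about.
* Total-adaptation window: last 20 feedback trials per block (a last-10-
  epoch alternative is selectable); block probes are averaged across both
  probe sets.

## Numerical choices

* Degrees everywhere; 1-based trial/epoch indices in tables, 0-based
  arrays internally.
* Learner bounds in fits: `a ∈ [0.5, 1]`, `b ∈ [0, 0.999]`; parameter sets
  that leave the stable regime during optimization incur a large penalty
  residual instead of raising.
* Exponential fits: multi-start over rates {0.01, 0.05, 0.2, 0.7}, rate
  bounded to [0, 10]; an all-baseline curve short-circuits to rate 0.
* MAD filter uses raw (unscaled) median absolute deviations, threshold 3,
  centred 10-epoch windows.
* Map cells whose tested sensitivities leave the stable regime or the
  [0, 1) range are flagged invalid, not raised; the reference cell is set
  to exactly 0.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical configs give byte-identical
  datasets and bootstrap intervals.

## Known limitations

* The explicit percent change in tied two-exposure fits is weakly
  identified from behaviour alone: at 1° noise on the fitted curves its
  replicate-to-replicate spread is about ±5 points even with both high- and
  low-PT series observed (the implicit change is much tighter, ±2).
* Published parameter sets are reproduced as printed even where the source
  rounds inconsistently: the gain at `(a_i = 0.899, b_i = 0.193)` evaluates
  to 0.656 while 0.658 (and a slope of −0.665) appear in the original
  report, and `0.899^(1/4) = 0.9737` vs a printed 0.9738.  The formulas,
  not the rounded values, are authoritative here.
* Decomposition-based explicit measures share probe noise with the
  implicit measure by construction; analyses that regress one on the other
  inherit that artifact, which is why model selection predicts from total
  adaptation and why one falsification test in the suite lowers the noise
  to isolate the model signature.
* No reaction-time, aim-report, multi-rate (fast/slow), or continuous-time
  modelling; no proprioceptive error channel; no reward-based learning.
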