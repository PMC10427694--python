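# Methods

## The model

A point-to-point reach is scored against the minimum-jerk trajectory
(MJT): the movement from `x0` to `xf` over duration `d` that minimizes the
integrated squared jerk `∫ ‖x⃛(t)‖² dt` subject to zero velocity *and*
acceleration at both endpoints. The minimizer is the quintic
`x(t) = x0 + (xf−x0)(10τ³ − 15τ⁴ + 6τ⁵)`, `τ = t/d`, with closed-form
jerk cost `720 (xf−x0)² / d⁵` and peak speed `1.875 (xf−x0)/d` at
`τ = 0.5`. Note the constraint family matters: polynomials satisfying only
the position/velocity conditions (e.g. the cubic `3τ² − 2τ³`, whose
endpoint acceleration is nonzero) can have *lower* jerk cost; optimality
tests therefore perturb within the full six-constraint family
(`τ³(1−τ)³ ·` polynomial perturbations).

All positions are in percent of workspace width and the analysis is
strictly one-dimensional (a horizontal cursor); a unit helper converts to
physical length given the workspace width. Out-of-range evaluation of the
quintic raises; a clamped variant (flat at `x0` before onset, at `xf`
after the end) exists for overlays and the simulator.

## Trial segmentation and metrics

- **Velocity** is the backward difference `(x_i − x_{i−1})·fs` with
  `v_0 = 0`, optionally smoothed by a centred moving average. The default
  window is 5 samples (~83 ms at 60 Hz) for measured or noisy data and 1
  (off) for noise-free traces: raw finite differences at 60 Hz amplify
  sensor noise enough to make a sign-based onset rule meaningless.
- **Onset** is the first run of `debounce` consecutive samples with
  `v > eps`; the defaults `eps = 0, debounce = 1` implement the literal
  rule "first sample with positive movement velocity". Raising `debounce`
  suppresses isolated noise blips.
- **End** is the first sample strictly above 95% of the target distance
  (a tie at exactly the threshold does not terminate). Trials that never
  cross are kept as incomplete: they stay in completion-curve denominators
  and are excluded from metric aggregation.
- **Time to target** is end minus onset. Because the end rule fires at the
  95% crossing, the measured time to target of an ideal MJT of duration
  `d` is `τ₉₅·d` with `τ₉₅ ≈ 0.8107` (the root of the quintic at 0.95).
  This propagates into two deliberate consequences. First, the
  condition-level MJT reference — built, as the analysis prescribes, with
  duration equal to the condition's mean time to target — is a slightly
  time-compressed version of the underlying movement, so even noise-free
  MJT trials carry a nonzero RMS position error of a few percent of the
  amplitude (the same order as measured cohorts show); tests validate the
  error against the closed-form RMSE between the two quintics rather than
  against zero. Second, parameter-recovery checks compare the fitted
  time-to-target slope against `τ₉₅ ×` the generator's duration slope.
- **Position error** is the RMS difference between the onset-aligned
  observed trace, linearly interpolated onto the reference grid and held
  at its final value beyond its end, and the condition reference. The
  default granularity is per-trial error (then averaged per condition),
  since the rank tests need per-trial responses; a condition-mean-trace
  mode is available through `mean_position_trace`.
- **Path efficiency** is `100 × ideal / actual`, where ideal is the
  straight start-to-target-center distance and actual is the total
  traversed path `Σ|Δx|` from onset through settlement (the end of the
  trace, not the 95% crossing — cutting at the crossing would drop the
  deceleration tail and overstate efficiency). This orientation makes
  trials that settle at the target's *near edge* exceed 100%, matching how
  efficiencies above 100% arise in practice; the literal reciprocal
  (`actual/ideal`) is available via a mode switch.
- **Normalization**: per modality, each trial's peak velocity and time to
  target are divided by the mean over that modality's smallest-distance
  trials, yielding span ratios and per-distance ellipse summaries
  (center = mean normalized pair, axes = SDs).

## The statistical battery

The Scheirer–Ray–Hare (SRH) test is implemented directly: all responses
are jointly rank-transformed (average ranks on ties), a sequential
(Type I) sum-of-squares decomposition over modality, distance, and their
interaction is computed on the ranks via least squares, and each term's
`H = SS_term / (SS_total/(N−1))` is referred to chi-square at the term's
df. Computing `SS_total` from the tie-averaged ranks *is* the classical
tie correction — with one factor collapsed the statistic equals scipy's
tie-corrected Kruskal–Wallis H exactly, which the tests assert at 1e-10
along with equivalence to a statsmodels ANOVA on ranks. Sequential and
marginal SS coincide on balanced designs; the factor order is exposed for
unbalanced data. An all-tied response is flagged degenerate (`H = 0`,
`p = 1`).

The two-stage procedure runs SRH with interaction first; per response, a
non-significant interaction (at alpha, default 0.05) leads to an
interaction-free SRH refit, a significant one to two Kruskal–Wallis tests
over distance with modality fixed. Kruskal–Wallis and Brown–Forsythe
(ANOVA-F on absolute deviations from group medians, i.e. Levene with
median centering) are delegated to scipy; the variance-ratio F test is
two-sided (sidedness is a choice — the package defaults to the
conservative option); regressions are ordinary least squares. No
multiple-testing correction is applied by default, matching the analysis
design this package implements.

A caution from the rank scale: a "multiplicative" interaction (one
modality's distance slope inflated relative to the other's, same sign) is
largely absorbed by the main effects after rank transformation; crossing
patterns are what the SRH interaction term detects with power. The
two-stage branch tests use crossing-slope generators for that reason.

## The synthetic cohort

The generator emulates a two-modality target-acquisition study: 7 target
distances (12.5–87.5% in 12.5% steps) × 5 blocks per subject and modality
(35 trials each), sampled at 60 Hz over a 10 s trial window, with a target
half-width of 3.6% (a 5 cm target on a 68.6 cm wide workspace). Each
trial is a reaction-delay hold, an MJT rise to a scattered endpoint, and a
hold until the window closes. Stochastic structure, per modality:

| parameter | manipulandum-like | sonomyography-like | rationale |
|---|---|---|---|
| duration intercept (s) | 0.55 | 0.40 | longer times for the arm modality, shorter but more variable for signal-derived control |
| duration slope (s/%) | 0.01 | 0.01 | time to target grows ~0.01 s per % distance |
| duration jitter SD (s) | 0.06 | 0.18 | modality variance ordering |
| trajectory noise SD (%) | 1.5 | 5.0 | anchored to trace-SD ranges of ~0.5–2.4% vs ~4.3–5.8% |
| noise smoothing (samples) | 31 (~0.5 s) | 9 (~0.15 s) | arm movements wander slowly; signal jitter is faster |
| endpoint SD (%) | 0.4 | 1.2 | scatter truncated at the target half-width |
| onset delay (s) | 0.30 ± 0.05 | 0.30 ± 0.10 | reaction time before movement |

Trajectory noise is moving-average-filtered white noise rescaled to the
configured post-filter SD, added to the moving segment only and tapered to
zero at the segment ends (half-cosine ramps) so the hold phases stay clean
and onset detection remains meaningful. Endpoint scatter is truncated at
the target half-width, so subjects always settle inside the target band —
which is exactly what produces >100% path efficiencies for near-edge
stops. Durations are floored at 0.2 s (with a logged warning). All draws
come from a single seeded generator per cohort; identical seed and
configuration give bit-identical cohorts and byte-identical pipeline
outputs (the run manifest's wall-clock timestamp is the only
non-reproducible field, and the manifest's run id hashes only seed,
configuration and input digests).

What the generator does **not** emulate: corrective submovements and
overshoot (real deceleration phases differ between modalities), learning
across blocks, subject-level random effects (all subjects share one noise
model), within-trial drift of the biosignal mapping, and 2-D path
curvature. Passing tests therefore demonstrate that the pipeline recovers
the structure this model puts in — scaling, variance ordering, branch
logic, calibration — not that it certifies any property of real recordings.

## Numerical choices and problem sizes

- Jerk cost: composite trapezoid on the analytic third derivative (2001
  points) for parameter objects; repeated `np.gradient` differencing for
  sampled traces (≥ 4 samples required). Optimality comparisons use one
  quadrature scheme on both curves so discretization bias cancels.
- Sampling grids are endpoint-inclusive (`round(d·fs)+1` points); peak
  localization is asserted to one grid step.
- Velocity tie-breaks take the earliest maximum; onset uses the start of
  the qualifying run.
- Degenerate inputs raise typed errors (`OnsetNotFoundError`,
  `UndefinedMetricError`, `DesignError`) rather than returning NaN, except
  in the cohort driver where incomplete trials are represented as NaN rows.
- Simulation sizes: the test suite uses cohorts of 1–10 subjects;
  null-calibration checks use 10⁴ simulated 2×7 response tables with 5
  observations per cell; Monte-Carlo noise-recovery uses 500 trials.
  These sizes give comfortable margins for the assertions they feed
  (rejection-rate windows of ±1.5 percentage points, 15% relative SD
  recovery, 3-SE slope recovery).

## Known limitations

- The SRH interaction term has the usual rank-transform caveats (see
  above); conclusions about interactions are branch decisions, not effect
  estimates.
- Path efficiency in 1-D conflates backtracking with noise wiggle; a
  jittery but well-aimed controller scores low even when its endpoint is
  accurate.
- The condition reference inherits the 95%-crossing compression; position
  errors are comparable *across* conditions but are not absolute
  goodness-of-fit measures against the true underlying movement.
- Direction normalization flips negative-going (mirrored-convention)
  trials at load time using the dominant-excursion sign; trials that
  genuinely end below their start would be misread, but such trials are
  outside the task's design.
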