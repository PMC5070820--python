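# Methods

## Study design the package implements

The pipeline reproduces the standard field calibration of accelerometer
intensity cut points against momentary direct observation. Children wear a
hip-mounted device recording activity counts in 10-s epochs while an observer
codes their behaviour every 20 s (10-s observe / 10-s record, three
observations per minute) into five categories: 1 lying down, 2 sitting,
3 standing, 4 walking, 5 very active. If a child is transitioning between
behaviours at the sampling instant, the higher code is recorded. Two
consecutive 10-s count epochs are summed to one 20-s analysis epoch and
time-matched to the observation grid; invalid intervals (child out of the
hall) and optionally implausibly large counts are screened out. Participants
are split by session: a fixed number per session (default 2) is held out for
cross-validation, the rest calibrate.

Calibration converts observation categories to a binary criterion per
intensity — sedentary positives {1, 2}, moderate {4, 5}, vigorous {5} — and
sweeps an exhaustive ROC curve over every distinct observed 20-s count.
Sedentary is "positive-low" (positive when counts ≤ threshold); moderate,
vigorous and MVPA are "positive-high" (counts ≥ threshold). The optimal
threshold maximises Youden's index J = sensitivity + specificity − 1.
Because the moderate criterion {4, 5} is exactly the MVPA-versus-rest
contrast, the moderate lower boundary and the MVPA boundary come from a
single ROC analysis; the moderate upper boundary is the vigorous lower
boundary minus one count. Cross-validation classifies held-out epochs into
sedentary / light / moderate / vigorous (light is the residual band between
the sedentary and moderate boundaries) and reports per-intensity
sensitivity, specificity, total agreement and Cohen's kappa with SE.

## Statistical conventions

* **Candidate thresholds** are the observed distinct count values plus the
  two degenerate all-positive / all-negative endpoints, with inclusive
  comparisons. Reported integer boundaries (e.g. a sedentary cut at a
  specific observed count) are consistent with this convention; evaluating
  at midpoints instead could shift boundaries by one count unit.
* **Tie-breaks** for equal J: higher sensitivity first (as in screening
  practice), then the more sensitive threshold for the sweep direction
  (higher for positive-low, lower for positive-high). Applied ties are
  logged, so flat ROC regions are resolved deterministically and visibly.
* **AUC** is the rank-sum (Mann–Whitney) probability that a random positive
  epoch scores on the positive side of a random negative epoch, ties counted
  one half. The SE is Hanley–McNeil; the 95% CI is normal and clipped to
  [0, 1]. AUC labels: ≥ .90 excellent, .80–.89 good, .70–.79 fair, < .70
  poor.
* **Cohen's kappa** uses the 2×2 per-intensity table pooled over epochs;
  its SE is the asymptotic two-rater (Fleiss–Cohen–Everitt) variance,
  cross-checked in the tests against statsmodels. Labels: < 0 less than
  chance, ≤ .20 slight, ≤ .40 fair, ≤ .60 moderate, ≤ .80 substantial,
  ≤ 1.00 almost perfect. Degenerate margins (chance agreement 1) raise
  rather than returning 0; empty criterion margins yield a flagged
  (None) sensitivity or specificity rather than a silent zero.
* **Units.** The unit of record is counts/20-s; cpm values are the 20-s
  boundaries × 3, except the moderate upper bound in cpm, which follows the
  reporting convention vigorous_lower_cpm − 1 (one cpm below the vigorous
  boundary) rather than 3 × the 20-s moderate upper bound — the two differ
  by two counts. On integer 20-s counts the two unit systems classify
  identically (multiples of three never fall in the one-cpm gap); the gap
  only matters for data natively in cpm.
* **Moderate-row pairing.** Whether a predicted-vigorous epoch counts as a
  true positive for the moderate row is genuinely ambiguous when four-way
  predictions meet a binary criterion whose positives are {4, 5}. The
  default pairs predicted {moderate} only (strict); the pooled alternative
  ({moderate, vigorous}, identical to the MVPA row) is available via
  `moderate_includes_vigorous=True`. The strict pairing deliberately scores
  worse on perfect data and is reported alongside MVPA so both views are
  visible.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes, not
raw accelerometry:

* **Sessions.** Default 7 sessions with 8, 8, 9, 7, 7, 5, 6 children (50
  total), each following a four-phase 45-min plan (warm-up, instruction
  games, obstacle games, team games; 10 + 10 + 10 + 15 min) with a target
  behaviour mix per phase chosen so the session marginal is a few percent
  lying down, roughly a fifth each sitting, standing and very active, and
  about 30% walking.
* **Behaviour.** Per-second traces are renewal processes: bout category from
  the phase mix, bout duration exponential with mean `dwell_mean_s`
  (default 15 s — children's activity is sporadic).
* **Counts.** A 10-s epoch draws its vertical count from a rounded lognormal
  for the category occupying the majority of its window (ties to the later
  bout), parameterised by median and log-SD per category — defaults
  (medians 4, 40, 120, 260, 700; σ 1.0, 0.8, 0.6, 0.5, 0.5) give right-
  skewed, overlapping classes whose 20-s sums bracket typical published
  boundaries. The vector-magnitude count is the vertical count times a
  sampled factor ≥ 1 (1 + lognormal excess, default median factor 2.5), so
  vm ≥ vertical holds by construction. A per-child lognormal activity
  multiplier (mean 1, default SD 0.15) adds between-child heterogeneity.
* **Observation.** The momentary code is the trace value at the final second
  of the observe window, with the higher code on a one-second transition.
  Coding error replaces the code with an adjacent category with probability
  `mislabel_prob` (default 0.10, consistent with rater reliabilities in the
  80–90% range); `out_of_hall_prob` (default 0.02) flags intervals invalid.
  Traces are truncated to complete 20-s intervals; an odd trailing 10-s
  epoch is dropped rather than zero-padded (padding would bias the final
  interval downward).

Determinism: every random stream is derived from (seed, session,
participant, purpose), so identical configurations reproduce byte-identical
outputs regardless of call order.

What the generator does **not** emulate: raw 30 Hz waveforms, device-axis
biomechanics, autocorrelated count noise within a bout, systematic
observer drift, or population-specific movement differences. Passing tests
therefore show the *pipeline* is correct under the assumed statistical
structure; they cannot certify cut points for any real population.

## Analytic oracle and parameter recovery

`analytic_optimal_threshold` computes, by numeric search over convolved
integer pmfs, the J-maximising threshold for the idealized model in which a
20-s count is the sum of two independent 10-s draws from the distribution of
the *recorded* category (the adjacent-category mislabel kernel is folded
into the class mixtures; class weights come from the phase plan). Plateaus
of maximal J (disjoint classes) return the plateau midpoint. Identical class
distributions raise ("no discriminating threshold"). `analytic_auc` and
`analytic_youden` use the same mixtures; a Monte Carlo sampler provides an
independent check of the convolution machinery.

The recovery experiment (`run_threshold_recovery`) uses defaults except
mislabel 0.05, no participant multiplier and 90-s mean bouts, because the
oracle's model assumes behaviour constant within an interval and no
between-child scaling; 10 sessions × 8 participants supply 10,000 pooled
intervals per seed. Two effects bound what recovery can achieve and are
worth stating plainly:

1. the empirical Youden argmax is a cube-root-rate estimator — its sampling
   fluctuation at n = 10,000 spans tens of counts where the count grid is
   dense at one- or two-count spacing, so the recovered threshold cannot be
   expected to match the analytic optimum at grid resolution when classes
   overlap (with well-separated classes the optimum sits on a wide plateau
   and recovery at gap resolution does hold, and is tested);
2. with finite bouts a fraction of intervals mixes two behaviours, which the
   two-independent-draws model neglects; this attenuates empirical AUC
   relative to the analytic value by roughly 0.01–0.02 at the 90-s dwell
   (re-running with near-pure intervals collapses the gap).

`scripts/acceptance.py` reports the measured recovery quantities
(`recovery_*`) alongside the exact-arithmetic and determinism checks.

## Limitations

* Spurious-score screening has no principled universal definition; the
  default maximum plausible count is unset (no exclusions) to avoid
  silently discarding data.
* The manual video synchronisation of real studies is reduced to an integer
  interval offset parameter; sub-interval misalignment is not modelled.
* Agreement is computed on pooled epochs, not per-participant averages, so
  heavier-contributing children weigh more.
* Published reference sets are compared in cpm only and at face value; no
  device-generation count rescaling is attempted.
* Light intensity is defined residually; no light-specific ROC is fitted.
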