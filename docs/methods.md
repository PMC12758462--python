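# Methods

## Model

The classifier treats a subject's exertional-symptom record as a trajectory
`{(w_i, s_i)}`: Borg CR10 scores `s_i ∈ [0, 10]` at strictly increasing work
rates `w_i` (watts), one rating per stage of an incremental cycle-ergometer
test (stages of 1–2 min, increments of 10–20 W). The reference standard is a
family of seven curves per symptom/sex/age stratum — minimum, 5th, 25th,
50th, 75th, 95th centile and maximum of the healthy-subject Borg
distribution at each work rate — which partition the score axis into six
inter-centile bands. The question the algorithm answers is: which band best
represents the whole trajectory?

The method is deliberately training-free. All quantities are closed-form
functions of the trajectory, the curves, and a handful of fixed parameters;
improving the reference curves improves the classifier without refitting
anything.

### Fit score per curve

Each curve `c` receives a reciprocal-exponential-loss score

```
d_i   = min(|s_i − c(w_i)|, clamp_dev)
REL(c) = max(min_loss, Σ_i ω_i e^{−α d_i} / Σ_i ω_i)
```

The weighted *mean* (rather than a product over points) keeps REL in
(0, 1], makes it length-invariant (a 6-stage and a 15-stage test are on the
same scale), and gives it the two properties everything downstream relies
on: REL = 1 iff the trajectory lies exactly on the curve, and REL is
strictly decreasing in every unclamped deviation. The exponential makes the
score exquisitely sensitive near a curve and flat far from it, which is
what rewards *consistent* proximity over incidental crossings.

### Band probabilities and selection

Band score = product of the two bordering RELs; the six scores are
normalized to probabilities. Selection then runs a generalized binary
search over the severity-stratum boundaries (P50, P75, P95, in that order):
at each boundary that still splits the surviving bands, the probability
mass strictly below is compared with the mass at-or-above, and the heavier
side survives; once the survivors lie in one stratum, the
highest-probability survivor is reported. Comparing stratum masses rather
than picking the argmax band protects the mild stratum, whose mass is
diluted across three bands, and deliberately trades a little "leniency"
(willingness to choose a neighbouring band) for robustness when the
probability vector is nearly uniform.

Severity: bands up to P50 → mild, P50–P75 → moderate, P75–P95 → severe,
P95–MAX → very severe. The peak-score comparator maps the last rating:
0–2 mild, 3–4 moderate, 5–6 severe, ≥7 very severe; a non-integer rating
above a category's upper bound moves to the next category (2.5 → moderate,
6.5 → very severe), consistent with half-point Borg usage.

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| `alpha` | 1.0 | per Borg unit | loss steepness; larger ⇒ less lenient |
| `clamp_dev` | 5.0 | Borg | deviation cap; one wild outlier cannot zero a curve's REL |
| `min_loss` | 1e-4 | — | REL floor; keeps all band scores positive so normalization is defined |
| `inertial_weight` | 0.25 | — | weight of points where the P5–P95 spread is zero |
| `tie_rule` | higher | — | exact ties resolved toward the higher band (never understates burden) |
| `threshold_order` | P50, P75, P95 | — | search schedule = severity boundaries |

All six are grouped in `ClassifierConfig` and can be overridden from a
YAML/JSON file, so alternative choices need no code changes. The floor is
applied per curve *before* band scores are formed and normalized
(floor-then-normalize); applying it after normalization would break the
sum-to-one contract.

Points are "inertial" when the 5th–95th spread is exactly zero: there the
curves coincide, the point's position between centiles is undefined, and it
carries no discriminative information — hence the down-weighting rather
than any point-in-band logic (none exists anywhere in the pipeline, which
is also why coincident curves at single work rates are harmless: both
bordering curves simply receive the same per-point loss).

## Numerical choices

- **Interpolation**: curves are tabulated and evaluated with linear
  interpolation between knots and flat extrapolation beyond the table.
  Linear interpolation on a shared knot grid preserves the between-curve
  ordering at every query point; splines do not guarantee this.
- **Degenerate inputs**: an empty trajectory, a symptom/sex mismatch, or an
  age outside the table's band raise immediately. A trajectory far from
  every curve trips the `min_loss` floor and is flagged
  (`degenerate_floor`). A winning band below probability 0.35 is flagged
  `low_confidence` (an invented diagnostic, not part of the core method);
  fewer than 3 points flags `few_points`.
- **Determinism**: the pipeline is free of randomness; identical inputs and
  config give bit-identical results.
- **McNemar**: exact two-sided binomial p below 25 discordant pairs,
  continuity-corrected `(|b−c|−1)²/(b+c)` with χ²(1) otherwise. The
  severity scale is dichotomized at severe-or-worse (configurable) before
  the test. At exactly balanced tables the doubled exact p caps at 1 while
  the corrected approximation sits slightly below; away from balance the
  two agree to < 0.003 near the switchover.
- **Discrimination tables**: unoccupied severity rows are dropped before
  the Pearson test; a grouping that is constant (or leaves fewer than two
  occupied severity levels) is reported as non-discriminating with p = 1.

## Synthetic data

The published normative equations and the patient data are unavailable, so
the generator emulates their structure. Centile curve k is zero until an
onset work rate `o_k` (a fixed fraction of peak: 0.65, 0.55, 0.45, 0.30,
0.18, 0.08, 0 from minimum to maximum) and then rises as
`T_k·((w − o_k)/(W_peak − o_k))^1.8` to a terminal Borg value `T_k`
(2, 3, 5, 7, 8.5, 9.5, 10). The power-law form follows the psychophysics of
Borg ratings (perceived intensity grows as a power of the stimulus); the
exponent 1.8 and the onset stagger are plausible invented shapes, exposed
in `SyntheticSpec`. Because onsets decrease and terminals increase with the
centile level, cross-curve ordering holds at every work rate analytically,
and the minimum/5th/25th curves coincide at zero through at least the first
fifth of the test — reproducing the coincident low-load region that
motivates the inertial reweighing.

Trajectories are the midpoint of a target band plus Gaussian rating noise
(default sd 0.3 Borg units), optional sudden persistent +1.5 steps,
clipping to [0, 10], and rounding to the nearest half point (Borg scales
are used with half-point ratings in practice; both are configurable).
Cohorts draw a generating severity per symptom per subject, let more
severe subjects stop earlier (peak work rate shrinks ~12% per severity
rank), take the last-stage rating as the peak score, and draw the three
clinical group labels with adverse-group probability
`0.5 + coupling·(rank − 1.5)/3`, so `coupling = 0` gives labels independent
of severity (used to verify type-I error control of the discrimination
pipeline) and larger couplings give the discrimination analyses real
signal.

What passing tests on these data do and do not show: they verify the
algorithm's internal contracts (normalization, ordering, recovery of a
known generating band, selector correctness) under realistic trajectory
shapes, but they cannot validate the clinical accuracy of the published
reference curves, the behaviour of real patients whose trajectories follow
neither a band midpoint nor Gaussian noise, nor any claim about real COPD
cohorts. Problem sizes used throughout (200 trajectories for recovery,
1,000 vectors for the selector oracle, 100–200 subjects per simulated
cohort, 200 replicates for type-I control) were chosen as the smallest
sizes at which the checked proportions are stable.

## Known limitations

- Severity recovery is reported for trajectories generated *inside* a band;
  trajectories that genuinely straddle a boundary have no well-defined
  ground truth, and the probability vector (not the single selected band)
  is the honest output there.
- The reweighing rule keys on *exactly* zero spread; tables with tiny but
  non-zero spread at low load will not trigger it.
- MIN and MAX are treated as ordinary per-work-rate curves; reference
  systems that define them as global extremes should supply them as
  constant rows in the same schema.
- The stage-file schema carries no demographics; sex and age come from the
  cohort file when present, otherwise the classify command adopts the
  supplied table's stratum.
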