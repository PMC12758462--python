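"""Synthetic reference tables, trajectories, and cohorts.

The normative centile equations and the patient cohort behind the
method are not publicly available, so this module generates stand-ins
with the structural features the classifier depends on:

- centile curves that are zero through a low-load onset region (lower
  centiles stay at zero longer, so the minimum/5th/25th curves coincide
  at low work rates) and then rise as a power function of work rate —
  the psychophysical shape of Borg ratings against stimulus intensity;
- patient trajectories drawn around a target inter-centile band with
  Gaussian rating noise, optional sudden upward steps, clipping to the
  0-10 scale and rounding to half points (common Borg usage);
- cohorts whose clinical group labels can be coupled to the generating
  severity, so discrimination analyses have signal to find (and none
  when the coupling is zero).

Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .centiles import (
    INTERCENTILE_RANGES,
    CentileGrid,
    CentileLabel,
    CentileSet,
    IntercentileRange,
    evaluate_centile,
    validate_centile_set,
)
from .classifier import (
    ClassifierConfig,
    SeverityCategory,
    SymptomTrajectory,
    classify,
    severity_from_range,
)
from .cohort import GROUP_LABELS, CohortRecord

__all__ = [
    "SyntheticSpec",
    "SyntheticCohort",
    "generate_centile_table",
    "generate_trajectory",
    "generate_cohort",
    "ranges_for_severity",
]

# Onset (fraction of peak work rate at which each curve leaves zero) and
# terminal Borg value at peak, per centile.  Lower centiles switch on
# later and top out lower; all shapes share the power-law exponent.
_DEFAULT_ONSET_FRACTIONS = {
    CentileLabel.MIN: 0.65,
    CentileLabel.P5: 0.55,
    CentileLabel.P25: 0.45,
    CentileLabel.P50: 0.30,
    CentileLabel.P75: 0.18,
    CentileLabel.P95: 0.08,
    CentileLabel.MAX: 0.0,
}
_DEFAULT_TERMINALS = {
    CentileLabel.MIN: 2.0,
    CentileLabel.P5: 3.0,
    CentileLabel.P25: 5.0,
    CentileLabel.P50: 7.0,
    CentileLabel.P75: 8.5,
    CentileLabel.P95: 9.5,
    CentileLabel.MAX: 10.0,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic protocol, curves, and noise.

    The exercise protocol is stepwise incremental cycling: stages of
    1-2 minutes with 10-20 W increments up to ``peak_work_rate``.
    ``noise_sd`` is the rating noise in Borg units; ``n_events`` adds
    sudden persistent +``event_step`` jumps at random stages.
    """

    stage_duration_min: float = 2.0
    increment_w: float = 10.0
    peak_work_rate: float = 200.0
    onset_fractions: dict[CentileLabel, float] = field(
        default_factory=lambda: dict(_DEFAULT_ONSET_FRACTIONS)
    )
    terminal_values: dict[CentileLabel, float] = field(
        default_factory=lambda: dict(_DEFAULT_TERMINALS)
    )
    exponent: float = 1.8
    noise_sd: float = 0.3
    n_events: int = 0
    event_step: float = 1.5
    round_to_half: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 10 <= self.increment_w <= 20:
            raise ValueError("increment_w must lie in [10, 20] W")
        if not 1 <= self.stage_duration_min <= 2:
            raise ValueError("stage_duration_min must lie in [1, 2]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        terms = [self.terminal_values[lab] for lab in CentileLabel]
        if np.any(np.diff(terms) < 0):
            raise ValueError("terminal values must be non-decreasing across centiles")
        onsets = [self.onset_fractions[lab] for lab in CentileLabel]
        if np.any(np.diff(onsets) > 0):
            raise ValueError("onset fractions must be non-increasing across centiles")


def generate_centile_table(
    spec: SyntheticSpec,
    symptom: str = "dyspnea",
    sex: str = "M",
    age_band: tuple[int, int] = (40, 85),
) -> CentileSet:
    """Build a reference table from the power-law curve family.

    Curve k is zero until its onset work rate ``o_k`` and then
    ``T_k * ((w - o_k) / (W_peak - o_k)) ** exponent`` up to its
    terminal value ``T_k`` at the peak of the grid.  Because onsets
    decrease and terminals increase with the centile level, the seven
    curves are ordered at every work rate and the table passes
    validation by construction.
    """
    peak = spec.peak_work_rate
    work_rates = np.arange(0.0, peak + 0.5 * spec.increment_w, spec.increment_w)
    values = np.empty((work_rates.size, len(CentileLabel)))
    for lab in CentileLabel:
        onset = spec.onset_fractions[lab] * peak
        span = max(peak - onset, 1e-12)
        x = np.clip((work_rates - onset) / span, 0.0, None)
        values[:, int(lab)] = spec.terminal_values[lab] * x**spec.exponent
    values = np.clip(values, 0.0, 10.0)
    cset = CentileSet(
        symptom=symptom,
        sex=sex,
        age_band=age_band,
        grid=CentileGrid(work_rates, values),
        source="synthetic power-law curves",
    )
    violations = validate_centile_set(cset)
    if violations:  # spec invariants should make this unreachable
        raise ValueError(f"generated table is invalid: {violations}")
    return cset


def ranges_for_severity(severity: SeverityCategory) -> list[IntercentileRange]:
    """The inter-centile bands mapping onto a severity category."""
    return [r for r in INTERCENTILE_RANGES if severity_from_range(r) == severity]


def generate_trajectory(
    cset: CentileSet,
    target: IntercentileRange,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    subject_age: float | None = None,
    subject_id: str | None = None,
    peak_work_rate: float | None = None,
) -> tuple[SymptomTrajectory, SeverityCategory]:
    """Draw one noisy trajectory around the midpoint of a target band.

    Stage work rates follow the protocol (one rating per increment up
    to the subject's peak).  The latent curve is the midpoint of the
    target band at each stage (where the band has zero width this is
    just the shared curve value); observations add Gaussian noise and
    any step events, are clipped to [0, 10] and rounded to the nearest
    half point.  Returns the trajectory and its generating severity.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    peak = peak_work_rate if peak_work_rate is not None else spec.peak_work_rate
    work_rates = np.arange(spec.increment_w, peak + 0.5 * spec.increment_w, spec.increment_w)
    lo = np.asarray(evaluate_centile(cset, target.lower, work_rates))
    hi = np.asarray(evaluate_centile(cset, target.upper, work_rates))
    latent = 0.5 * (lo + hi)
    scores = latent + rng.normal(0.0, spec.noise_sd, size=latent.shape)
    for _ in range(spec.n_events):
        stage = rng.integers(0, work_rates.size)
        scores[stage:] += spec.event_step
    scores = np.clip(scores, 0.0, 10.0)
    if spec.round_to_half:
        scores = np.round(scores * 2.0) / 2.0
    age = subject_age if subject_age is not None else 0.5 * sum(cset.age_band)
    traj = SymptomTrajectory(
        symptom=cset.symptom,
        subject_sex=cset.sex,
        subject_age=age,
        work_rates=work_rates,
        scores=scores,
        subject_id=subject_id,
    )
    return traj, severity_from_range(target)


@dataclass
class SyntheticCohort:
    """A simulated cohort with everything needed downstream."""

    records: list[CohortRecord]
    trajectories: dict[tuple[str, str], SymptomTrajectory]  # (subject_id, symptom)
    centile_sets: dict[tuple[str, str], CentileSet]  # (symptom, sex)
    ground_truth: dict[tuple[str, str], SeverityCategory]  # (subject_id, symptom)
    demographics: dict[str, tuple[str, float]]  # subject_id -> (sex, age)


def generate_cohort(
    n: int,
    severity_mix: dict[SeverityCategory, float] | None = None,
    coupling: float = 0.8,
    seed: int = 0,
    spec: SyntheticSpec | None = None,
    config: ClassifierConfig | None = None,
) -> SyntheticCohort:
    """Simulate ``n`` subjects and classify them with both methods.

    Each subject draws a generating severity per symptom from
    ``severity_mix``, a sex, an age, and a peak work rate (more severe
    subjects tend to stop earlier); trajectories for dyspnea and leg
    effort are generated around the corresponding bands, peak scores
    are the last-stage ratings, and the three clinical group labels are
    drawn with adverse-group probability increasing with the dyspnea
    generating severity at strength ``coupling`` in [0, 1] (0 means the
    labels are independent of severity).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= coupling <= 1:
        raise ValueError("coupling must lie in [0, 1]")
    if severity_mix is None:
        severity_mix = {
            SeverityCategory.MILD: 0.3,
            SeverityCategory.MODERATE: 0.3,
            SeverityCategory.SEVERE: 0.25,
            SeverityCategory.VERY_SEVERE: 0.15,
        }
    mix = np.array([severity_mix.get(s, 0.0) for s in SeverityCategory], dtype=float)
    if np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("severity mix must be non-negative and sum to 1")
    if spec is None:
        spec = SyntheticSpec(seed=seed)
    if config is None:
        config = ClassifierConfig()
    rng = np.random.default_rng(seed)

    centile_sets = {
        (symptom, sex): generate_centile_table(spec, symptom=symptom, sex=sex)
        for symptom in ("dyspnea", "leg_effort")
        for sex in ("M", "F")
    }

    records: list[CohortRecord] = []
    trajectories: dict[tuple[str, str], SymptomTrajectory] = {}
    ground_truth: dict[tuple[str, str], SeverityCategory] = {}
    demographics: dict[str, tuple[str, float]] = {}
    for i in range(n):
        sid = f"S{i + 1:04d}"
        sex = "M" if rng.random() < 0.5 else "F"
        age = float(rng.uniform(45, 80))
        demographics[sid] = (sex, age)

        severities = {
            symptom: SeverityCategory(int(rng.choice(4, p=mix)))
            for symptom in ("dyspnea", "leg_effort")
        }
        # more impaired subjects terminate exercise earlier
        rank = int(severities["dyspnea"])
        frac = float(rng.uniform(0.95 - 0.12 * rank, 1.0 - 0.12 * rank))
        peak_wr = max(3 * spec.increment_w, round(frac * spec.peak_work_rate / spec.increment_w) * spec.increment_w)

        peaks: dict[str, float] = {}
        atlas: dict[str, object] = {}
        for symptom in ("dyspnea", "leg_effort"):
            cset = centile_sets[(symptom, sex)]
            candidates = ranges_for_severity(severities[symptom])
            target = candidates[int(rng.integers(len(candidates)))]
            traj, truth = generate_trajectory(
                cset, target, spec, rng,
                subject_age=age, subject_id=sid, peak_work_rate=peak_wr,
            )
            trajectories[(sid, symptom)] = traj
            ground_truth[(sid, symptom)] = truth
            peaks[symptom] = float(traj.scores[-1])
            atlas[symptom] = classify(traj, cset, config)

        rank = int(severities["dyspnea"])
        p_adverse = float(np.clip(0.5 + coupling * (rank - 1.5) / 3.0, 0.0, 1.0))
        labels = {}
        for name, (reference, adverse) in GROUP_LABELS.items():
            labels[name] = adverse if rng.random() < p_adverse else reference

        records.append(
            CohortRecord(
                subject_id=sid,
                peak_dyspnea=peaks["dyspnea"],
                peak_leg_effort=peaks["leg_effort"],
                atlas_dyspnea=atlas["dyspnea"],
                atlas_leg_effort=atlas["leg_effort"],
                **labels,
            )
        )
    return SyntheticCohort(records, trajectories, centile_sets, ground_truth, demographics)
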