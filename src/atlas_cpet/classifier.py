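"""Core ATLAS algorithm.

Given a subject's Borg symptom trajectory (score vs work rate over the
stages of an incremental exercise test) and a matching set of reference
centile curves, the classifier answers: which inter-centile band best
describes the whole trajectory?

Pipeline
--------
1.  *Reweighing*: points in the zero-spread low-load region (where the
    5th and 95th centiles coincide) are down-weighted; they carry no
    information about which band the subject occupies.
2.  *Reciprocal exponential loss* (REL): each of the seven reference
    curves gets a fit score in (0, 1] — the weighted mean of
    ``exp(-alpha * |deviation|)`` over trajectory points, with the
    deviation clamped so one wild outlier cannot annihilate a curve's
    score, and the aggregate floored at a small minimal loss value so
    every band score stays strictly positive.  A trajectory lying
    exactly on a curve scores 1; the score decays exponentially with
    distance, rewarding trajectories consistently near a curve.
3.  Each of the six bands is scored by the product of its two bordering
    curves' RELs, and the six scores are normalized to probabilities.
4.  A generalized binary search over the severity-stratum boundaries
    (P50, P75, P95) picks the representative band: at each boundary the
    probability mass below is compared against the mass at-or-above and
    the heavier side survives.  Searching over strata rather than bands
    avoids biasing against the mild stratum, which spans three bands
    while the others span one.
5.  The selected band maps onto a four-level severity scale.

A conventional peak-score classifier (severity from the single Borg
rating at maximal exercise) is provided for comparison.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .centiles import (
    INTERCENTILE_RANGES,
    CentileLabel,
    CentileSet,
    IntercentileRange,
    centile_spread,
    evaluate_centile,
)

__all__ = [
    "SymptomTrajectory",
    "ClassifierConfig",
    "RangeProbabilities",
    "SeverityCategory",
    "ClassificationResult",
    "compute_weights",
    "rel",
    "range_scores",
    "normalize",
    "select_range",
    "severity_from_range",
    "classify",
    "classify_peak",
]


class SeverityCategory(enum.IntEnum):
    """Four-level whole-test symptom burden, mild < very severe."""

    MILD = 0
    MODERATE = 1
    SEVERE = 2
    VERY_SEVERE = 3

    def __str__(self) -> str:
        return self.name.lower()


@dataclass(frozen=True, eq=False)
class SymptomTrajectory:
    """One subject's ordered (work rate, Borg score) observations.

    Scores are the ratings given in the last 30 s of each stage of an
    incremental test; work rates must be strictly increasing.
    """

    symptom: str
    subject_sex: str
    subject_age: float
    work_rates: np.ndarray
    scores: np.ndarray
    subject_id: str | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.work_rates, dtype=float)
        s = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "work_rates", w)
        object.__setattr__(self, "scores", s)
        if w.ndim != 1 or s.shape != w.shape:
            raise ValueError("work_rates and scores must be 1-D arrays of equal length")
        if w.size < 1:
            raise ValueError("trajectory must contain at least one point")
        if np.any(np.diff(w) <= 0):
            raise ValueError("work rates must be strictly increasing")
        if np.any((s < 0) | (s > 10)):
            raise ValueError("Borg scores must lie in [0, 10]")

    def __len__(self) -> int:
        return int(self.work_rates.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SymptomTrajectory):
            return NotImplemented
        return (
            self.symptom == other.symptom
            and self.subject_sex == other.subject_sex
            and self.subject_age == other.subject_age
            and self.subject_id == other.subject_id
            and np.array_equal(self.work_rates, other.work_rates)
            and np.array_equal(self.scores, other.scores)
        )


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable parameters of the classifier.

    alpha
        Steepness of the exponential loss, per Borg unit.  Larger alpha
        makes the fit less lenient: neighbouring bands lose probability
        faster as the trajectory hugs one curve.
    min_loss
        Floor on each curve's aggregated REL, keeping all band scores
        strictly positive so normalization is always well defined.
    clamp_dev
        Cap (Borg units) on the per-point deviation entering the loss.
    inertial_weight
        Weight in (0, 1] given to points in the zero-spread region.
    tie_rule
        "higher" (default, clinically conservative: never understates
        burden) or "lower"; applied at exact probability ties.
    threshold_order
        Centile boundaries visited by the binary search, outermost
        first.  The default mirrors the severity strata.
    """

    alpha: float = 1.0
    min_loss: float = 1e-4
    clamp_dev: float = 5.0
    inertial_weight: float = 0.25
    tie_rule: str = "higher"
    threshold_order: tuple[CentileLabel, ...] = (
        CentileLabel.P50,
        CentileLabel.P75,
        CentileLabel.P95,
    )

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if not 0 < self.min_loss < 1:
            raise ValueError("min_loss must lie in (0, 1)")
        if not 0 < self.clamp_dev <= 10:
            raise ValueError("clamp_dev must lie in (0, 10]")
        if not 0 < self.inertial_weight <= 1:
            raise ValueError("inertial_weight must lie in (0, 1]")
        if self.tie_rule not in ("higher", "lower"):
            raise ValueError("tie_rule must be 'higher' or 'lower'")
        object.__setattr__(
            self,
            "threshold_order",
            tuple(CentileLabel(t) for t in self.threshold_order),
        )


@dataclass(frozen=True, eq=False)
class RangeProbabilities:
    """Probability that each of the six bands is the representative one."""

    probabilities: np.ndarray  # aligned with INTERCENTILE_RANGES

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RangeProbabilities):
            return NotImplemented
        return np.array_equal(self.probabilities, other.probabilities)

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.shape != (len(INTERCENTILE_RANGES),):
            raise ValueError(f"expected {len(INTERCENTILE_RANGES)} probabilities")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be non-negative and sum to 1")

    def __getitem__(self, r: IntercentileRange) -> float:
        return float(self.probabilities[INTERCENTILE_RANGES.index(r)])

    def as_dict(self) -> dict[str, float]:
        return {str(r): float(p) for r, p in zip(INTERCENTILE_RANGES, self.probabilities)}


@dataclass(frozen=True)
class ClassificationResult:
    """Full output for one trajectory."""

    range_probabilities: RangeProbabilities
    selected_range: IntercentileRange
    severity: SeverityCategory
    flags: frozenset[str]
    centile_rels: dict[CentileLabel, float]

    def as_dict(self) -> dict:
        return {
            "range_probabilities": {
                k: round(v, 6) for k, v in self.range_probabilities.as_dict().items()
            },
            "selected_range": str(self.selected_range),
            "severity": str(self.severity),
            "flags": sorted(self.flags),
            "centile_rels": {lab.name: float(r) for lab, r in self.centile_rels.items()},
        }


def _check_match(traj: SymptomTrajectory, cset: CentileSet) -> None:
    if traj.symptom != cset.symptom:
        raise ValueError(
            f"trajectory symptom {traj.symptom!r} does not match centile set "
            f"symptom {cset.symptom!r}"
        )


def compute_weights(
    traj: SymptomTrajectory, cset: CentileSet, cfg: ClassifierConfig
) -> np.ndarray:
    """Per-point weights: inertial points down-weighted, then rescaled.

    A point is inertial when the P5-P95 spread at its work rate is zero.
    Raw weights (``inertial_weight`` there, 1 elsewhere) are rescaled to
    sum to the number of points, so REL remains a weighted mean on the
    same scale regardless of how many inertial points there are.
    """
    _check_match(traj, cset)
    spread = np.asarray(centile_spread(cset, traj.work_rates), dtype=float)
    raw = np.where(spread == 0.0, cfg.inertial_weight, 1.0)
    return raw * (len(traj) / raw.sum())


def rel(
    traj: SymptomTrajectory,
    cset: CentileSet,
    label: CentileLabel,
    cfg: ClassifierConfig,
    weights: np.ndarray | None = None,
) -> float:
    """Reciprocal-exponential-loss fit of the trajectory to one curve.

    ``d_i = min(|s_i - c(w_i)|, clamp_dev)`` and
    ``REL = max(min_loss, sum_i w_i exp(-alpha d_i) / sum_i w_i)``.
    Equals 1 iff every deviation is zero; strictly decreasing in each
    unclamped deviation.
    """
    _check_match(traj, cset)
    if weights is None:
        weights = compute_weights(traj, cset, cfg)
    ref = np.asarray(evaluate_centile(cset, label, traj.work_rates), dtype=float)
    dev = np.minimum(np.abs(traj.scores - ref), cfg.clamp_dev)
    score = float(np.sum(weights * np.exp(-cfg.alpha * dev)) / np.sum(weights))
    return max(cfg.min_loss, score)


def range_scores(
    traj: SymptomTrajectory,
    cset: CentileSet,
    cfg: ClassifierConfig,
    weights: np.ndarray | None = None,
) -> tuple[dict[IntercentileRange, float], dict[CentileLabel, float]]:
    """Score each band as the product of its bordering curves' RELs.

    Returns the six band scores and, for diagnostics, the seven
    per-curve RELs.  The score of the P25-P50 band, for example, is
    ``REL(P25) * REL(P50)``.
    """
    if weights is None:
        weights = compute_weights(traj, cset, cfg)
    rels = {lab: rel(traj, cset, lab, cfg, weights) for lab in CentileLabel}
    scores = {r: rels[r.lower] * rels[r.upper] for r in INTERCENTILE_RANGES}
    return scores, rels


def normalize(scores: dict[IntercentileRange, float]) -> RangeProbabilities:
    """Turn the six band scores into probabilities summing to one."""
    vals = np.array([scores[r] for r in INTERCENTILE_RANGES], dtype=float)
    total = vals.sum()
    if not total > 0:
        raise ValueError("band scores sum to zero; min_loss floor not applied?")
    return RangeProbabilities(vals / total)


def severity_from_range(r: IntercentileRange) -> SeverityCategory:
    """Map a band onto the severity scale.

    Everything up to the 50th centile is mild; P50-P75 moderate;
    P75-P95 severe; above the 95th centile very severe.
    """
    if r.upper <= CentileLabel.P50:
        return SeverityCategory.MILD
    if r.upper == CentileLabel.P75:
        return SeverityCategory.MODERATE
    if r.upper == CentileLabel.P95:
        return SeverityCategory.SEVERE
    return SeverityCategory.VERY_SEVERE


def _stratum_of(r: IntercentileRange) -> SeverityCategory:
    return severity_from_range(r)


def select_range(
    probs: RangeProbabilities, cfg: ClassifierConfig | None = None
) -> IntercentileRange:
    """Pick the representative band by generalized binary search.

    Starting from all six bands, visit each threshold centile in
    ``cfg.threshold_order`` that still splits the surviving bands:
    compare the total probability of surviving bands entirely below the
    threshold against that of bands at or above it, and keep the heavier
    side (ties resolved by ``cfg.tie_rule``).  When the survivors all
    belong to one severity stratum, return the highest-probability
    survivor (ties again by ``tie_rule``).  Deterministic for a fixed
    config.
    """
    if cfg is None:
        cfg = ClassifierConfig()
    prefer_higher = cfg.tie_rule == "higher"
    surviving = list(INTERCENTILE_RANGES)

    for threshold in cfg.threshold_order:
        below = [r for r in surviving if r.upper <= threshold]
        above = [r for r in surviving if r.lower >= threshold]
        if not below or not above:
            continue  # threshold does not split the survivors
        mass_below = sum(probs[r] for r in below)
        mass_above = sum(probs[r] for r in above)
        if mass_above > mass_below or (mass_above == mass_below and prefer_higher):
            surviving = above
        else:
            surviving = below
    best = surviving[0]
    for r in surviving[1:]:  # ascending order: ties resolved by tie_rule
        if probs[r] > probs[best] or (probs[r] == probs[best] and prefer_higher):
            best = r
    return best


def classify(
    traj: SymptomTrajectory, cset: CentileSet, cfg: ClassifierConfig | None = None
) -> ClassificationResult:
    """Run the full pipeline on one trajectory.

    Flags:

    - ``few_points``: fewer than 3 observations;
    - ``low_confidence``: the winning band's probability is below 0.35
      (an invented diagnostic threshold, not part of the core method);
    - ``degenerate_floor``: at least one curve's REL hit the min_loss
      floor, i.e. the trajectory is far from that curve everywhere.
    """
    if cfg is None:
        cfg = ClassifierConfig()
    _check_match(traj, cset)
    if traj.subject_sex != cset.sex:
        raise ValueError(
            f"subject sex {traj.subject_sex!r} does not match centile set "
            f"sex {cset.sex!r}"
        )
    lo, hi = cset.age_band
    if not lo <= traj.subject_age <= hi:
        raise ValueError(
            f"subject age {traj.subject_age} outside centile set age band {cset.age_band}"
        )

    weights = compute_weights(traj, cset, cfg)
    scores, rels = range_scores(traj, cset, cfg, weights)
    probs = normalize(scores)
    selected = select_range(probs, cfg)
    severity = severity_from_range(selected)

    flags = set()
    if len(traj) < 3:
        flags.add("few_points")
    if probs[selected] < 0.35:
        flags.add("low_confidence")
    if any(v <= cfg.min_loss for v in rels.values()):
        flags.add("degenerate_floor")

    return ClassificationResult(
        range_probabilities=probs,
        selected_range=selected,
        severity=severity,
        flags=frozenset(flags),
        centile_rels=rels,
    )


def classify_peak(peak_score: float) -> SeverityCategory:
    """Severity from the single Borg rating at maximal exercise.

    0-2 mild, 3-4 moderate, 5-6 severe, >= 7 very severe.  A
    non-integer score above a category's upper bound moves up to the
    next category (2.5 is moderate, 4.5 severe, 6.5 very severe).
    """
    if not 0 <= peak_score <= 10:
        raise ValueError(f"peak Borg score must lie in [0, 10]; got {peak_score}")
    if peak_score <= 2:
        return SeverityCategory.MILD
    if peak_score <= 4:
        return SeverityCategory.MODERATE
    if peak_score <= 6:
        return SeverityCategory.SEVERE
    return SeverityCategory.VERY_SEVERE
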