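"""Reference centile curves for exertional Borg symptoms.

A centile set holds, for one symptom (dyspnea or leg effort) and one
sex/age stratum, seven reference curves over a work-rate grid: the
minimum, 5th, 25th, 50th, 75th, 95th centiles and the maximum of the
Borg 0-10 score reported by healthy sedentary subjects at each work
rate.  Trajectories recorded during incremental exercise are scored
against these curves, so the module guarantees the two orderings every
downstream computation relies on: at any work rate the seven curves
are non-decreasing from minimum to maximum, and each curve is
non-decreasing in work rate.

Curves are tabulated, not equation-based: tables are supplied as JSON
(or generated synthetically) and evaluated by linear interpolation
between tabulated work rates, with flat extrapolation beyond the table.
Linear interpolation on a shared knot grid preserves the between-curve
ordering, which higher-order schemes do not guarantee.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CentileLabel",
    "CentileGrid",
    "CentileSet",
    "IntercentileRange",
    "INTERCENTILE_RANGES",
    "validate_centile_set",
    "evaluate_centile",
    "centile_spread",
    "list_ranges",
]

BORG_MIN = 0.0
BORG_MAX = 10.0


class CentileLabel(enum.IntEnum):
    """The seven reference curves, in ascending order."""

    MIN = 0
    P5 = 1
    P25 = 2
    P50 = 3
    P75 = 4
    P95 = 5
    MAX = 6

    @property
    def key(self) -> str:
        """Lower-case key used in the JSON table schema (``min``, ``p5``, ...)."""
        return self.name.lower()


N_LABELS = len(CentileLabel)


@dataclass(frozen=True, order=True)
class IntercentileRange:
    """Band between two adjacent reference curves, e.g. P25-P50."""

    lower: CentileLabel
    upper: CentileLabel

    def __post_init__(self) -> None:
        if int(self.upper) != int(self.lower) + 1:
            raise ValueError(
                f"upper centile must immediately follow lower: got "
                f"{self.lower.name}-{self.upper.name}"
            )

    def __str__(self) -> str:
        return f"{self.lower.name}-{self.upper.name}"

    @classmethod
    def from_string(cls, text: str) -> "IntercentileRange":
        lo, _, hi = text.partition("-")
        return cls(CentileLabel[lo.strip().upper()], CentileLabel[hi.strip().upper()])


#: The six adjacent bands, ascending: MIN-P5, P5-P25, ..., P95-MAX.
INTERCENTILE_RANGES: tuple[IntercentileRange, ...] = tuple(
    IntercentileRange(CentileLabel(i), CentileLabel(i + 1)) for i in range(N_LABELS - 1)
)


@dataclass
class CentileGrid:
    """Tabulated centile values on an ascending work-rate grid.

    Parameters
    ----------
    work_rates
        Ascending, non-negative work rates in watts (>= 2 entries).
    values
        Array of shape ``(len(work_rates), 7)``; column ``k`` is the curve
        for ``CentileLabel(k)``.  Values are Borg scores in [0, 10].
    """

    work_rates: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.work_rates = np.asarray(self.work_rates, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.work_rates.ndim != 1 or self.work_rates.size < 2:
            raise ValueError("work_rates must be a 1-D array with >= 2 entries")
        if self.values.shape != (self.work_rates.size, N_LABELS):
            raise ValueError(
                f"values must have shape ({self.work_rates.size}, {N_LABELS}); "
                f"got {self.values.shape}"
            )


@dataclass
class CentileSet:
    """A symptom's reference curves plus the stratum they apply to."""

    symptom: str  # "dyspnea" | "leg_effort"
    sex: str  # "M" | "F"
    age_band: tuple[int, int]
    grid: CentileGrid
    source: str = ""

    def __post_init__(self) -> None:
        self.age_band = (int(self.age_band[0]), int(self.age_band[1]))


_SYMPTOMS = ("dyspnea", "leg_effort")
_SEXES = ("M", "F")


def validate_centile_set(cset: CentileSet) -> list[str]:
    """Check every invariant of a centile set; return violation messages.

    An empty list means the set is valid.  Violations name the offending
    grid row (work-rate index) and column (centile label) so a bad table
    can be fixed by hand.
    """
    violations: list[str] = []
    if cset.symptom not in _SYMPTOMS:
        violations.append(f"symptom must be one of {_SYMPTOMS}; got {cset.symptom!r}")
    if cset.sex not in _SEXES:
        violations.append(f"sex must be one of {_SEXES}; got {cset.sex!r}")
    if cset.age_band[0] > cset.age_band[1]:
        violations.append(f"age_band lower bound exceeds upper: {cset.age_band}")

    grid = cset.grid
    w = grid.work_rates
    v = grid.values
    if np.any(w < 0):
        for i in np.nonzero(w < 0)[0]:
            violations.append(f"work rate at row {i} is negative: {w[i]}")
    if np.any(np.diff(w) <= 0):
        for i in np.nonzero(np.diff(w) <= 0)[0]:
            violations.append(
                f"work rates not strictly ascending between rows {i} and {i + 1}"
            )
    bad = (v < BORG_MIN) | (v > BORG_MAX) | ~np.isfinite(v)
    for i, k in zip(*np.nonzero(bad)):
        violations.append(
            f"range violation: value {v[i, k]} at row {i} "
            f"({CentileLabel(k).name}) outside Borg [0, 10]"
        )
    # ordering across labels at each work rate
    for i, k in zip(*np.nonzero(np.diff(v, axis=1) < 0)):
        violations.append(
            f"column order violation at row {i} (work rate {w[i]} W): "
            f"{CentileLabel(k + 1).name} < {CentileLabel(k).name}"
        )
    # each curve non-decreasing in work rate
    for i, k in zip(*np.nonzero(np.diff(v, axis=0) < 0)):
        violations.append(
            f"monotonicity violation in {CentileLabel(k).name} between rows "
            f"{i} and {i + 1}"
        )
    return violations


def evaluate_centile(
    cset: CentileSet, label: CentileLabel, work_rate: float | Sequence[float]
) -> float | np.ndarray:
    """Evaluate one reference curve at the given work rate(s).

    Exact at tabulated work rates; linear between them; flat (nearest
    table value) beyond either end of the grid.  Returns a scalar for a
    scalar query, else an array.
    """
    try:
        col = CentileLabel(label)
    except ValueError as exc:
        raise ValueError(f"unknown centile label: {label!r}") from exc
    w = np.asarray(work_rate, dtype=float)
    out = np.interp(w, cset.grid.work_rates, cset.grid.values[:, int(col)])
    return float(out) if np.isscalar(work_rate) or w.ndim == 0 else out


def centile_spread(
    cset: CentileSet, work_rate: float | Sequence[float]
) -> float | np.ndarray:
    """Width of the P5-P95 band at the given work rate(s), in Borg units.

    Zero spread marks the early low-load region where nearly all healthy
    subjects report no symptom and points carry little discriminative
    information (the "inertial" region).
    """
    hi = evaluate_centile(cset, CentileLabel.P95, work_rate)
    lo = evaluate_centile(cset, CentileLabel.P5, work_rate)
    return hi - lo


def list_ranges(cset: CentileSet) -> list[IntercentileRange]:
    """The six inter-centile bands of a set, ascending."""
    return list(INTERCENTILE_RANGES)
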