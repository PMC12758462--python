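"""File formats: centile tables (JSON), stage ratings (CSV), cohort
metadata (CSV), classifier configuration (YAML/JSON).

All formats are plain text.  Readers validate strictly and report every
offending line or field at once rather than stopping at the first.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .centiles import CentileGrid, CentileLabel, CentileSet, validate_centile_set
from .classifier import ClassifierConfig, SymptomTrajectory
from .cohort import GROUP_LABELS

__all__ = [
    "read_centile_json",
    "write_centile_json",
    "read_stage_csv",
    "write_stage_csv",
    "read_cohort_csv",
    "write_cohort_csv",
    "load_config",
]

_CENTILE_KEYS = [lab.key for lab in CentileLabel]

STAGE_HEADER = ["subject_id", "stage", "work_rate_w", "dyspnea_borg", "leg_effort_borg"]
COHORT_HEADER = [
    "subject_id",
    "sex",
    "age",
    "gold_stage",
    "mechanical_constraint",
    "low_peak_vo2",
    "peak_dyspnea",
    "peak_leg_effort",
]

SYMPTOM_COLUMNS = {"dyspnea": "dyspnea_borg", "leg_effort": "leg_effort_borg"}


def read_centile_json(path: str | Path) -> CentileSet:
    """Parse and validate a centile table file.

    The schema is an object with ``symptom``, ``sex``, ``age_band``
    ([lo, hi] years), ``work_rates`` (ascending array), ``centiles``
    (object mapping ``min``/``p5``/``p25``/``p50``/``p75``/``p95``/
    ``max`` to equal-length arrays) and ``source``.  Unknown centile
    keys are rejected.
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    problems: list[str] = []
    for key in ("symptom", "sex", "age_band", "work_rates", "centiles"):
        if key not in raw:
            problems.append(f"missing key {key!r}")
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    centiles = raw["centiles"]
    unknown = sorted(set(centiles) - set(_CENTILE_KEYS))
    if unknown:
        problems.append(f"unknown centile keys {unknown}; allowed: {_CENTILE_KEYS}")
    missing = sorted(set(_CENTILE_KEYS) - set(centiles))
    if missing:
        problems.append(f"missing centile keys {missing}")
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    work_rates = np.asarray(raw["work_rates"], dtype=float)
    n = work_rates.size
    for key in _CENTILE_KEYS:
        if len(centiles[key]) != n:
            problems.append(
                f"centile {key!r} has {len(centiles[key])} values; expected {n}"
            )
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    values = np.column_stack([np.asarray(centiles[k], dtype=float) for k in _CENTILE_KEYS])
    cset = CentileSet(
        symptom=str(raw["symptom"]),
        sex=str(raw["sex"]),
        age_band=tuple(raw["age_band"]),
        grid=CentileGrid(work_rates, values),
        source=str(raw.get("source", "")),
    )
    violations = validate_centile_set(cset)
    if violations:
        raise ValueError(f"{path}: " + "; ".join(violations))
    return cset


def write_centile_json(cset: CentileSet, path: str | Path) -> None:
    payload = {
        "symptom": cset.symptom,
        "sex": cset.sex,
        "age_band": list(cset.age_band),
        "work_rates": cset.grid.work_rates.tolist(),
        "centiles": {
            lab.key: cset.grid.values[:, int(lab)].tolist() for lab in CentileLabel
        },
        "source": cset.source,
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")


def read_stage_csv(
    path: str | Path,
    subjects: Mapping[str, tuple[str, float]] | None = None,
    default_sex: str = "M",
    default_age: float = 60.0,
) -> dict[tuple[str, str], SymptomTrajectory]:
    """Read per-stage Borg ratings into one trajectory per (subject, symptom).

    The header must be exactly ``subject_id,stage,work_rate_w,
    dyspnea_borg,leg_effort_borg``.  A row may leave either symptom's
    score blank; the row is then omitted from that symptom's trajectory
    only.  Work rates and stage indices must be strictly increasing
    within a subject and scores must lie in [0, 10]; all violations are
    reported with their line numbers.

    ``subjects`` maps subject ids to (sex, age); ids not found there
    fall back to ``default_sex``/``default_age`` (the stage file itself
    carries no demographics).
    """
    df = pd.read_csv(path, dtype={"subject_id": str}, skip_blank_lines=False)
    if list(df.columns) != STAGE_HEADER:
        raise ValueError(
            f"{path}: malformed header {list(df.columns)}; expected {STAGE_HEADER}"
        )
    errors: list[str] = []
    lines = df.index + 2  # 1-based, after the header
    for col in ("dyspnea_borg", "leg_effort_borg"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & ((vals < 0) | (vals > 10) | vals.isna())
        for ln in lines[bad]:
            errors.append(f"line {ln}: {col} out of Borg range [0, 10]")
        df[col] = vals
    if (df["work_rate_w"] < 0).any():
        for ln in lines[df["work_rate_w"] < 0]:
            errors.append(f"line {ln}: negative work rate")
    for sid, group in df.groupby("subject_id", sort=False):
        if (np.diff(group["work_rate_w"].to_numpy()) <= 0).any():
            errors.append(f"subject {sid}: work rates not strictly increasing")
        if (np.diff(group["stage"].to_numpy()) <= 0).any():
            errors.append(f"subject {sid}: stage indices not strictly increasing")
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))

    out: dict[tuple[str, str], SymptomTrajectory] = {}
    for sid, group in df.groupby("subject_id", sort=False):
        sex, age = (subjects or {}).get(sid, (default_sex, default_age))
        for symptom, col in SYMPTOM_COLUMNS.items():
            present = group[group[col].notna()]
            if present.empty:
                continue
            out[(sid, symptom)] = SymptomTrajectory(
                symptom=symptom,
                subject_sex=sex,
                subject_age=age,
                work_rates=present["work_rate_w"].to_numpy(float),
                scores=present[col].to_numpy(float),
                subject_id=sid,
            )
    return out


def write_stage_csv(
    trajectories: Mapping[tuple[str, str], SymptomTrajectory], path: str | Path
) -> None:
    """Write trajectories back to the stage CSV schema.

    Trajectories for the two symptoms of one subject are merged on work
    rate; a symptom missing at a work rate leaves its cell blank.
    """
    rows: dict[tuple[str, float], dict] = {}
    for (sid, symptom), traj in trajectories.items():
        for w, s in zip(traj.work_rates, traj.scores):
            row = rows.setdefault(
                (sid, float(w)), {"subject_id": sid, "work_rate_w": float(w)}
            )
            row[SYMPTOM_COLUMNS[symptom]] = float(s)
    records = sorted(rows.values(), key=lambda r: (r["subject_id"], r["work_rate_w"]))
    sid_prev, stage = None, 0
    for row in records:
        stage = stage + 1 if row["subject_id"] == sid_prev else 1
        sid_prev = row["subject_id"]
        row["stage"] = stage
    df = pd.DataFrame(records, columns=STAGE_HEADER)
    df.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read cohort metadata; validates header, labels, and peak scores."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    if list(df.columns) != COHORT_HEADER:
        raise ValueError(
            f"{path}: malformed header {list(df.columns)}; expected {COHORT_HEADER}"
        )
    errors = []
    for name, allowed in GROUP_LABELS.items():
        bad = ~df[name].isin(allowed)
        for sid in df.loc[bad, "subject_id"]:
            errors.append(f"subject {sid}: invalid {name}")
    for col in ("peak_dyspnea", "peak_leg_effort"):
        bad = (df[col] < 0) | (df[col] > 10)
        for sid in df.loc[bad, "subject_id"]:
            errors.append(f"subject {sid}: {col} out of range")
    if df["subject_id"].duplicated().any():
        errors.append("duplicate subject ids")
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    return df


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=COHORT_HEADER)


def load_config(path: str | Path | None) -> ClassifierConfig:
    """Load a classifier config from YAML or JSON; missing keys default.

    Recognized keys: ``alpha``, ``min_loss``, ``clamp_dev``,
    ``inertial_weight``, ``tie_rule``, ``threshold_order`` (list of
    centile names such as ``["P50", "P75", "P95"]``).
    """
    if path is None:
        return ClassifierConfig()
    text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text) or {}
    allowed = {"alpha", "min_loss", "clamp_dev", "inertial_weight", "tie_rule", "threshold_order"}
    unknown = sorted(set(raw) - allowed)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {unknown}")
    if "threshold_order" in raw:
        raw["threshold_order"] = tuple(
            CentileLabel[str(t).upper()] for t in raw["threshold_order"]
        )
    return ClassifierConfig(**raw)
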