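"""File formats: subjects/measurements/chart CSV, ROI JSON, manifests.

All tables are plain UTF-8 CSV with a mandatory header row and '.'
decimal separator. Readers validate schemas strictly: missing required
columns raise, unknown columns warn, and value errors name the
offending row. Areas are written to 2 decimals; everything else at full
precision.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Sequence

import pandas as pd

from .planimetry import BONES, HANDS, RoiPolygon
from .reference import SEXES, GrowthChart

SUBJECT_COLUMNS = [
    "subject_id",
    "sex",
    "age_months",
    "height_cm",
    "hands_available",
    "chronic_illness",
    "other_ethnicity",
    "excluded_reason",
]
MEASUREMENT_COLUMNS = ["subject_id", "hand", "bone", "reviewer", "area_mm2"]
CHART_COLUMNS = ["sex", "age_months", "p50_height_cm"]


class SchemaError(ValueError):
    """A file does not match its expected schema."""


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{what}: ignoring unknown columns {extra}", stacklevel=3)


def write_subjects_csv(subjects: pd.DataFrame, path: str | Path) -> None:
    subjects.to_csv(path, index=False, columns=SUBJECT_COLUMNS)


def read_subjects_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    _check_columns(df, SUBJECT_COLUMNS, f"subjects CSV {path}")
    df = df[SUBJECT_COLUMNS].copy()
    df["excluded_reason"] = df["excluded_reason"].fillna("")
    df["age_months"] = df["age_months"].astype(int)
    bad = df.index[df["age_months"] < 0]
    if len(bad):
        raise SchemaError(f"subjects CSV {path}: negative age at row {bad[0] + 2}")
    bad = df.index[~df["sex"].isin(SEXES)]
    if len(bad):
        raise SchemaError(f"subjects CSV {path}: unknown sex at row {bad[0] + 2}")
    return df


def write_measurements_csv(measurements: pd.DataFrame, path: str | Path) -> None:
    out = measurements[MEASUREMENT_COLUMNS].copy()
    out["area_mm2"] = out["area_mm2"].round(2)
    out.to_csv(path, index=False)


def read_measurements_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "reviewer": str})
    _check_columns(df, MEASUREMENT_COLUMNS, f"measurements CSV {path}")
    df = df[MEASUREMENT_COLUMNS].copy()
    # header is line 1, so dataframe row i lives on file line i + 2
    bad = df.index[df["area_mm2"] <= 0]
    if len(bad):
        raise SchemaError(
            f"measurements CSV {path}: non-positive area at row {bad[0] + 2}"
        )
    bad = df.index[~df["hand"].isin(HANDS) | ~df["bone"].isin(BONES)]
    if len(bad):
        raise SchemaError(
            f"measurements CSV {path}: unknown hand/bone at row {bad[0] + 2}"
        )
    return df


def write_chart_csv(chart: GrowthChart, path: str | Path) -> None:
    chart.table.to_csv(path, index=False, columns=CHART_COLUMNS)


def read_chart_csv(path: str | Path) -> GrowthChart:
    df = pd.read_csv(path)
    _check_columns(df, CHART_COLUMNS, f"growth chart CSV {path}")
    return GrowthChart(df[CHART_COLUMNS])


def write_roi_json(rois: Sequence[RoiPolygon], path: str | Path) -> None:
    records = [
        {
            "subject_id": r.subject_id,
            "hand": r.hand,
            "bone": r.bone,
            "reviewer_id": r.reviewer_id,
            "vertices": [list(v) for v in r.vertices],
        }
        for r in rois
    ]
    Path(path).write_text(json.dumps(records, indent=2))


def read_roi_json(path: str | Path) -> list[RoiPolygon]:
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, list):
        raise SchemaError(f"ROI JSON {path}: expected a list of ROI records")
    rois = []
    for i, rec in enumerate(raw):
        try:
            rois.append(
                RoiPolygon(
                    subject_id=str(rec["subject_id"]),
                    hand=rec["hand"],
                    bone=rec["bone"],
                    reviewer_id=str(rec["reviewer_id"]),
                    vertices=tuple(tuple(v) for v in rec["vertices"]),
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise SchemaError(f"ROI JSON {path}: record {i}: {exc}") from exc
    return rois


# ---------------------------------------------------------------------------
# manifests


def config_hash(config_json: str) -> str:
    return hashlib.sha256(config_json.encode()).hexdigest()[:16]


def write_manifest(
    path: str | Path,
    stages: list[dict],
    seed: int,
    config_digest: str,
) -> None:
    from . import __version__

    Path(path).write_text(
        json.dumps(
            {
                "package_version": __version__,
                "seed": seed,
                "config_hash": config_digest,
                "stages": stages,
            },
            indent=2,
        )
    )
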