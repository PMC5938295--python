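"""End-to-end pipeline: simulate → measure → fit → estimate → agree → report.

Each stage is a pure function of (config, upstream artifacts) and writes
its outputs under the configured directory; a run manifest records the
seed, a config digest and each stage's outputs so any artifact can be
reproduced from the repository alone. Stages can be disabled, in which
case downstream stages read their inputs from the output directory
(e.g. a `measurements.csv` produced elsewhere).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import agreement, growth, io, reference
from .cohort import Cohort, SimulationConfig, simulate_cohort, simulate_gp_rater, simulate_reviewer_measurements
from .planimetry import BONES, CalibrationFiducial, calibrate, consensus_area

logger = logging.getLogger("chplanimetry")

STAGES = ("simulate", "measure", "fit", "estimate", "agree", "report")


class CalibrationRecord(BaseModel):
    model_config = ConfigDict(extra="forbid")

    true_diameter_mm: float = 26.51
    measured_diameter_mm: float | None = 26.53
    measured_diameter_px: float | None = None


class PipelineConfig(BaseModel):
    """Configuration for a full pipeline run (single mandatory seed)."""

    model_config = ConfigDict(extra="forbid")

    simulation: SimulationConfig
    calibration: CalibrationRecord = Field(default_factory=CalibrationRecord)
    stages: tuple[str, ...] = STAGES
    hand: str = "left"  # hand whose model is used for bone-age estimation
    deming_lambda: float = 1.0
    output_dir: str = "chplanimetry_out"
    log_level: str = "INFO"

    @property
    def seed(self) -> int:
        return self.simulation.seed


def consensus_ch_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-subject/hand consensus areas and CH score from two reviewers.

    Applies the >10 % rule per bone: concordant pairs are averaged;
    discordant pairs are flagged ``needs_remeasure`` and (in this
    simulated setting, where reviewer errors are unbiased) resolved to
    the two-reviewer mean as the stand-in consensus re-measurement.
    Returns columns subject_id, hand, capitate_mm2, hamate_mm2,
    ch_area_mm2, n_discordant.
    """
    wide = measurements.pivot_table(
        index=["subject_id", "hand", "bone"],
        columns="reviewer",
        values="area_mm2",
        aggfunc="first",
    )
    reviewers = list(wide.columns)
    if len(reviewers) != 2:
        raise ValueError(f"expected exactly two reviewers, got {reviewers}")
    wide = wide.dropna()
    a1 = wide[reviewers[0]].to_numpy()
    a2 = wide[reviewers[1]].to_numpy()
    values = np.empty(a1.size)
    discordant = np.zeros(a1.size, dtype=bool)
    for i in range(a1.size):
        res = consensus_area(a1[i], a2[i])
        discordant[i] = res.needs_remeasure
        values[i] = res.value if res.value is not None else 0.5 * (a1[i] + a2[i])
    cons = wide.reset_index()[["subject_id", "hand", "bone"]]
    cons["area_mm2"] = values
    cons["discordant"] = discordant
    per_hand = cons.pivot_table(
        index=["subject_id", "hand"], columns="bone", values="area_mm2"
    ).reset_index()
    per_hand = per_hand.dropna(subset=list(BONES))  # CH needs both bones
    per_hand = per_hand.rename(
        columns={"capitate": "capitate_mm2", "hamate": "hamate_mm2"}
    )
    per_hand["ch_area_mm2"] = per_hand["capitate_mm2"] + per_hand["hamate_mm2"]
    n_disc = cons.groupby(["subject_id", "hand"])["discordant"].sum().reset_index()
    per_hand = per_hand.merge(n_disc, on=["subject_id", "hand"])
    return per_hand.rename(columns={"discordant": "n_discordant"})


def fit_models(
    subjects: pd.DataFrame, ch_table: pd.DataFrame, hand: str
) -> list[growth.BoneAgeLinearModel]:
    """Per-sex OLS fits (capitate, hamate, CH vs age) on one hand.

    Uses consensus areas of subjects passing the inclusion filters.
    """
    included, _ = reference.apply_inclusion_filters(subjects)
    data = ch_table[ch_table["hand"] == hand].merge(
        included[["subject_id", "sex", "age_months"]], on="subject_id"
    )
    models = []
    for sex in reference.SEXES:
        sub = data[data["sex"] == sex]
        for target, col in (
            ("capitate", "capitate_mm2"),
            ("hamate", "hamate_mm2"),
            ("CH", "ch_area_mm2"),
        ):
            models.append(
                growth.fit_growth_model(
                    sub["age_months"], sub[col], sex=sex, hand=hand, target=target
                )
            )
    return models


def estimate_bone_ages(
    subjects: pd.DataFrame,
    measurements: pd.DataFrame,
    models: list[growth.BoneAgeLinearModel],
    hand: str,
) -> pd.DataFrame:
    """Per-reviewer CH bone-age estimates for each subject on one hand.

    Each reviewer's own CH area (their capitate + hamate measurement) is
    inverted through the sex-specific CH growth model fitted on the
    consensus data. Returns subject_id, reviewer, method,
    bone_age_months, clamped.
    """
    ch_models = {
        m.sex: m for m in models if m.target == "CH" and m.hand == hand
    }
    meas = measurements.merge(
        subjects[["subject_id", "sex", "age_months"]], on="subject_id"
    )
    meas = meas[meas["hand"] == hand]
    wide = meas.pivot_table(
        index=["subject_id", "sex", "reviewer"],
        columns="bone",
        values="area_mm2",
        aggfunc="first",
    ).reset_index()
    wide = wide.dropna(subset=list(BONES))
    rows = []
    for sex, grp in wide.groupby("sex"):
        model = ch_models[sex]
        ages, clamped = model.estimate_age(
            grp["capitate"].to_numpy() + grp["hamate"].to_numpy()
        )
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": grp["subject_id"].to_numpy(),
                    "reviewer": grp["reviewer"].to_numpy(),
                    "method": "CH_planimetry",
                    "bone_age_months": ages,
                    "clamped": clamped,
                }
            )
        )
    return pd.concat(rows, ignore_index=True).sort_values(
        ["subject_id", "reviewer"], kind="stable"
    ).reset_index(drop=True)


def reference_subgroup(subjects: pd.DataFrame) -> pd.DataFrame:
    """Included subjects whose height brackets the chart median (50th pct)."""
    included, _ = reference.apply_inclusion_filters(subjects)
    chart = reference.synthetic_growth_chart()
    return reference.select_fiftieth_percentile(included, chart)


def agreement_from_estimates(
    ch_est: pd.DataFrame,
    gp_est: pd.DataFrame,
    subgroup: pd.DataFrame,
) -> agreement.AgreementReport:
    """Assemble the agreement report on the reference subgroup."""
    ids = subgroup["subject_id"]
    ch = ch_est[ch_est["subject_id"].isin(ids)]
    gp = gp_est[gp_est["subject_id"].isin(ids)]
    ch_wide = ch.pivot_table(
        index="subject_id", columns="reviewer", values="bone_age_months"
    ).dropna()
    gp_wide = gp.pivot_table(
        index="subject_id", columns="rater", values="bone_age_months"
    ).dropna()
    common = ch_wide.index.intersection(gp_wide.index)
    sub = subgroup.set_index("subject_id").loc[common]
    return agreement.build_agreement_report(
        {r: ch_wide.loc[common, r].to_numpy() for r in ch_wide.columns},
        {r: gp_wide.loc[common, r].to_numpy() for r in gp_wide.columns},
        sub["age_months"].to_numpy(dtype=float),
        subject_ids=list(common),
    )


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None) -> Path:
    """Execute the enabled stages in order; returns the output directory.

    Artifacts: subjects.csv, truth.csv, measurements.csv, ch_scores.csv,
    models.json, estimates.csv, report.json, report.md, manifest.json.
    """
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    digest = io.config_hash(config.model_dump_json())
    stage_log: list[dict] = []
    enabled = set(config.stages)

    def record(stage: str, outputs: list[str], inputs: list[str] = ()) -> None:
        stage_log.append(
            {"stage": stage, "inputs": list(inputs), "outputs": outputs}
        )
        logger.info("stage %s: wrote %s", stage, ", ".join(outputs))

    scale, rel_err = calibrate(
        CalibrationFiducial(**config.calibration.model_dump())
    )

    cohort: Cohort | None = None
    if "simulate" in enabled:
        cohort = simulate_cohort(config.simulation)
        io.write_subjects_csv(cohort.subjects, outdir / "subjects.csv")
        cohort.truth.to_csv(outdir / "truth.csv", index=False)
        record("simulate", ["subjects.csv", "truth.csv"])
    subjects = (
        cohort.subjects if cohort is not None
        else io.read_subjects_csv(outdir / "subjects.csv")
    )

    if "measure" in enabled:
        truth = (
            cohort.truth if cohort is not None
            else pd.read_csv(outdir / "truth.csv", dtype={"subject_id": str})
        )
        measurements = simulate_reviewer_measurements(truth, config.simulation)
        io.write_measurements_csv(measurements, outdir / "measurements.csv")
        # downstream stages consume the published 2-decimal precision, so
        # in-memory and from-file runs produce identical results
        measurements = io.read_measurements_csv(outdir / "measurements.csv")
        ch_table = consensus_ch_table(measurements)
        ch_table.to_csv(outdir / "ch_scores.csv", index=False)
        record("measure", ["measurements.csv", "ch_scores.csv"], ["truth.csv"])
    else:
        measurements = io.read_measurements_csv(outdir / "measurements.csv")
        ch_table = consensus_ch_table(measurements)

    models: list[growth.BoneAgeLinearModel] | None = None
    if "fit" in enabled:
        models = fit_models(subjects, ch_table, config.hand)
        growth.save_models(models, outdir / "models.json")
        record("fit", ["models.json"], ["subjects.csv", "ch_scores.csv"])
    else:
        models = growth.load_models(outdir / "models.json")

    ch_est = gp_est = None
    if "estimate" in enabled:
        ch_est = estimate_bone_ages(subjects, measurements, models, config.hand)
        gp_est = simulate_gp_rater(subjects, config.simulation)
        ch_est.to_csv(outdir / "estimates.csv", index=False)
        gp_est.to_csv(outdir / "gp_estimates.csv", index=False)
        record(
            "estimate",
            ["estimates.csv", "gp_estimates.csv"],
            ["measurements.csv", "models.json"],
        )
    elif {"agree", "report"} & enabled:
        ch_est = pd.read_csv(outdir / "estimates.csv", dtype={"subject_id": str})
        gp_est = pd.read_csv(outdir / "gp_estimates.csv", dtype={"subject_id": str})

    report = None
    if "agree" in enabled:
        subgroup = reference_subgroup(subjects)
        report = agreement_from_estimates(ch_est, gp_est, subgroup)
        report.to_json(outdir / "report.json")
        record("agree", ["report.json"], ["estimates.csv", "gp_estimates.csv"])

    if "report" in enabled:
        if report is None:
            report = agreement.AgreementReport.from_json(outdir / "report.json")
        md = [report.to_markdown()]
        if rel_err is not None:
            md.append(f"Fiducial calibration relative error: {rel_err:.2f} %\n")
        if scale is not None:
            md.append(f"Fiducial scale: {scale:.4f} mm/px\n")
        (outdir / "report.md").write_text("\n".join(md))
        record("report", ["report.md"], ["report.json"])

    io.write_manifest(outdir / "manifest.json", stage_log, config.seed, digest)
    return outdir
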