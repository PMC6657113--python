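"""Per-subject orchestration and the rest-vs-stress study report.

A subject is described by a YAML/JSON config pointing at the NIfTI
velocity triplets and mask series for each condition (rest, stress),
with VENC, heart rate, cycle duration, the systole/diastole phase
partition, and optionally a rigid transform aligning the segmentation to
the velocity acquisition plus an aliasing-correction switch.

The study stage pairs every metric across conditions, runs the gated
paired comparison, and correlates each metric's relative rest-stress
difference with VO2max. Subjects with a missing condition are excluded
explicitly — never silently dropped — and the exclusion table is part of
the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import energetics, stats, volumetrics
from .energetics import EnergeticsParams, EnergeticsSummary, EnergeticsTimeSeries
from .grid import (
    PhasePartition,
    RigidTransform,
    apply_rigid_to_mask,
    read_mask_nifti,
    read_velocity_nifti,
    unwrap_velocity,
)
from .volumetrics import VolumetricSummary

log = logging.getLogger("ventriflow")

#: metric column stems expected in a cohort table
DEFAULT_METRICS = ("ke", "el", "vort")


class ConfigError(ValueError):
    """Invalid or incomplete subject/study configuration."""


@dataclass(frozen=True)
class ConditionConfig:
    velocity_paths: tuple[str, str, str]
    mask_path: str
    heart_rate_bpm: float
    rr_ms: float
    partition: PhasePartition
    rigid_transform: RigidTransform | None = None
    unwrap: bool = False


@dataclass(frozen=True)
class SubjectConfig:
    subject_id: str
    venc: float
    conditions: dict[str, ConditionConfig]
    params: EnergeticsParams = EnergeticsParams()

    @classmethod
    def from_file(cls, path) -> "SubjectConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base_dir=path.parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "SubjectConfig":
        base = Path(base_dir) if base_dir is not None else Path(".")

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        try:
            conditions = {}
            for name, c in raw["conditions"].items():
                vel = tuple(str(resolve(p)) for p in c["velocity"])
                if len(vel) != 3:
                    raise ConfigError(f"{name}: need three velocity component paths")
                rt = None
                if c.get("rigid_transform") is not None:
                    rt = RigidTransform.from_flat(c["rigid_transform"])
                conditions[name] = ConditionConfig(
                    velocity_paths=vel,
                    mask_path=str(resolve(c["mask"])),
                    heart_rate_bpm=float(c["heart_rate_bpm"]),
                    rr_ms=float(c.get("rr_ms", 60000.0 / float(c["heart_rate_bpm"]))),
                    partition=PhasePartition(c["systole_frames"], c["diastole_frames"]),
                    rigid_transform=rt,
                    unwrap=bool(c.get("unwrap", False)),
                )
        except KeyError as e:
            raise ConfigError(f"missing config key: {e}") from e
        params = EnergeticsParams(
            rho=float(raw.get("rho", EnergeticsParams().rho)),
            mu=float(raw.get("mu", EnergeticsParams().mu)),
        )
        return cls(
            subject_id=str(raw.get("subject_id", "subject")),
            venc=float(raw["venc"]),
            conditions=conditions,
            params=params,
        )


@dataclass
class SubjectResult:
    subject_id: str
    condition: str
    energetics: EnergeticsSummary
    volumetrics: VolumetricSummary
    timeseries: EnergeticsTimeSeries

    def phase_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "phase": np.arange(len(self.timeseries.ke_mj)),
            "ke_mJ": self.timeseries.ke_mj,
            "el_mW": self.timeseries.el_mw,
            "vortvol_mL_s": self.timeseries.vortvol_ml_s,
        })

    def summary_table(self) -> pd.DataFrame:
        rows = {**self.energetics.as_rows(), **self.volumetrics.as_rows()}
        return pd.DataFrame(
            {"parameter": list(rows), "value": list(rows.values())}
        )

    def metric_row(self) -> dict[str, float]:
        """The three cycle-average metrics that feed the cohort stage."""
        return {
            "ke": self.energetics.ke_avg_cycle,
            "el": self.energetics.el_avg_cycle,
            "vort": self.energetics.vortvol_avg_cycle,
        }


def run_subject(config: SubjectConfig, condition: str) -> SubjectResult:
    """End-to-end per-subject analysis for one condition.

    Reads the velocity triplet and mask, optionally applies the rigid
    alignment to the mask and corrects aliasing, then computes the
    energetics time series, phase averages, volumetrics and the
    SV-normalised parameters. Deterministic given its inputs.
    """
    if condition not in config.conditions:
        raise ConfigError(f"unknown condition {condition!r}; have {sorted(config.conditions)}")
    cond = config.conditions[condition]
    for p in (*cond.velocity_paths, cond.mask_path):
        if not Path(p).exists():
            raise ConfigError(f"input file not found: {p}")
    log.info(
        "subject=%s condition=%s rho=%g g/mL mu=%g Pa.s venc=%g m/s "
        "systole=%s diastole=%s stencils=masked-central/one-sided",
        config.subject_id, condition, config.params.rho, config.params.mu,
        config.venc, sorted(cond.partition.systole_frames),
        sorted(cond.partition.diastole_frames),
    )
    try:
        fld = read_velocity_nifti(cond.velocity_paths, venc=config.venc, rr_ms=cond.rr_ms)
        mask = read_mask_nifti(cond.mask_path, rr_ms=cond.rr_ms)
    except Exception as e:
        raise ConfigError(f"[load] {e}") from e
    cond.partition.validate_for(fld.grid.nt)
    if cond.rigid_transform is not None:
        mask = apply_rigid_to_mask(mask, cond.rigid_transform)
    if cond.unwrap:
        fld = unwrap_velocity(fld, mask)
    series = energetics.compute_timeseries(fld, mask, config.params)
    summary = energetics.phase_average(series, cond.partition)
    vols = volumetrics.summarize_mask(mask, cond.heart_rate_bpm)
    if vols.sv_ml > 0:
        energetics.normalize_by_sv(summary, vols.sv_ml)
    return SubjectResult(config.subject_id, condition, summary, vols, series)


# ---------------------------------------------------------------------------
# Cohort / study stage
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    """Cohort-level rest-vs-stress report.

    `subjects` holds the per-subject rows (rest, stress, absolute and
    relative difference per metric); `comparisons` the gated paired test
    per metric; `correlations` the association of each metric's relative
    difference with VO2max; `excluded` the subjects left out and why.
    """

    subjects: pd.DataFrame
    comparisons: dict[str, stats.ComparisonResult]
    correlations: dict[str, stats.CorrelationResult]
    excluded: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["subject_id", "reason"]))

    def comparison_table(self) -> pd.DataFrame:
        rows = []
        for name, c in self.comparisons.items():
            rest = stats.describe(self.subjects[f"{name}_rest"])
            stress = stats.describe(self.subjects[f"{name}_stress"])
            rows.append({
                "parameter": name,
                "Rest": str(rest),
                "Stress": str(stress),
                "Difference": str(c.diff),
                "Difference (%)": str(c.relative_diff),
                "P-value": c.p_value,
                "test": c.test_used,
            })
        return pd.DataFrame(rows)

    def correlation_table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"parameter": name, "r": c.r, "P-value": c.p_value,
             "method": c.method, "strength": c.strength, "n": c.n}
            for name, c in self.correlations.items()
        ])

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(out / "subjects.csv", index=False)
        self.comparison_table().to_csv(out / "comparisons.csv", index=False)
        self.correlation_table().to_csv(out / "correlations.csv", index=False)
        self.excluded.to_csv(out / "excluded.csv", index=False)


def analyze_cohort(table: pd.DataFrame, metrics=DEFAULT_METRICS,
                   vo2_col: str = "vo2max") -> StudyReport:
    """Run the statistical stage on a paired rest/stress cohort table.

    Expects columns `<metric>_rest` / `<metric>_stress` per metric plus a
    VO2max column. Subjects with any missing metric value are excluded
    (with reason) before testing.
    """
    df = table.copy()
    needed = [f"{m}_{c}" for m in metrics for c in ("rest", "stress")]
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise ConfigError(f"cohort table missing columns: {missing_cols}")
    incomplete = df[needed].isna().any(axis=1)
    excluded = pd.DataFrame({
        "subject_id": df.loc[incomplete, "subject_id"] if "subject_id" in df else df.index[incomplete],
        "reason": "missing rest or stress measurement",
    })
    df = df.loc[~incomplete].reset_index(drop=True)
    if len(df) < 3:
        raise ConfigError("need at least 3 subjects with complete rest/stress data")
    comparisons, correlations = {}, {}
    for m in metrics:
        rest, stress = df[f"{m}_rest"], df[f"{m}_stress"]
        df[f"{m}_diff"] = stress - rest
        df[f"{m}_rel_diff_pct"] = stats.relative_difference(rest, stress)
        comparisons[m] = stats.paired_compare(rest, stress)
        if vo2_col in df:
            try:
                correlations[m] = stats.correlate(df[f"{m}_rel_diff_pct"], df[vo2_col])
            except ValueError as e:  # zero-variance differences etc.
                log.warning("correlation with %s skipped for %s: %s", vo2_col, m, e)
    return StudyReport(subjects=df, comparisons=comparisons,
                       correlations=correlations, excluded=excluded)


def run_study(manifest_path) -> StudyReport:
    """Run every subject in a study manifest end to end, then the stats.

    The manifest (YAML) lists subjects with a config path, VO2max and the
    conditions to pair (default rest/stress). Subjects whose configs or
    inputs fail to load are excluded with the logged reason.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise ConfigError(f"manifest not found: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    rows, excluded = [], []
    for entry in manifest["subjects"]:
        sid = str(entry.get("id", entry.get("config")))
        try:
            cfg_path = Path(entry["config"])
            if not cfg_path.is_absolute():
                cfg_path = manifest_path.parent / cfg_path
            cfg = SubjectConfig.from_file(cfg_path)
            row = {"subject_id": sid, "vo2max": float(entry["vo2max"])}
            for condition in ("rest", "stress"):
                res = run_subject(cfg, condition)
                for m, val in res.metric_row().items():
                    row[f"{m}_{condition}"] = val
            rows.append(row)
        except (ConfigError, KeyError) as e:
            log.warning("excluding subject %s: %s", sid, e)
            excluded.append({"subject_id": sid, "reason": str(e)})
    report = analyze_cohort(pd.DataFrame(rows))
    report.excluded = pd.concat(
        [report.excluded, pd.DataFrame(excluded, columns=["subject_id", "reason"])],
        ignore_index=True,
    )
    return report


def write_subject_outputs(result: SubjectResult, out_dir) -> None:
    """Per-subject CSV (per-phase + summary block) and JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"{result.subject_id}_{result.condition}"
    result.phase_table().to_csv(out / f"{stem}_phases.csv", index=False)
    result.summary_table().to_csv(out / f"{stem}_summary.csv", index=False)
    payload = {
        "subject_id": result.subject_id,
        "condition": result.condition,
        "energetics": result.energetics.as_rows(),
        "volumetrics": result.volumetrics.as_rows(),
    }
    with open(out / f"{stem}_summary.json", "w") as fh:
        json.dump(payload, fh, indent=2)
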