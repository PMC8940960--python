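"""End-to-end orchestration: synthesis/ingest -> RR cleaning -> HRV features
-> cohort statistics, with a declarative run configuration and a JSON run
report.

A run consumes exactly one input mode:

* ``synthetic`` — generate a paired cohort (no external data needed);
* ``rr_files`` — a manifest CSV pointing at RR text files;
* ``ecg_files`` — a manifest CSV pointing at ECG CSV traces, which are
  filtered and R-peak-detected first.

Outputs under ``out_dir``: the per-(subject, state) feature table, the
overall and gender-stratified comparison tables, the percent-change
summary, FS-14 score comparisons, per-feature density grids, and a JSON
report echoing the full resolved configuration (every defaulted parameter
included) so a run is reproducible from its report alone.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ecg import artifact_filter, bandpass_filter, detect_r_peaks, rr_from_peaks
from .errors import HRVError, ParameterError
from .io import (
    FEATURE_COLUMNS,
    fs14_row,
    read_ecg_csv,
    read_fs14_csv,
    read_manifest,
    read_rr_text,
    write_fs14_csv,
    write_json,
    write_manifest,
    write_rr_text,
)
from .nonlinear import entropy_panel, poincare_descriptors
from .stats import compare_states, estimate_pdf, score_fs14
from .synthetic import FATIGUE_PROFILE, NONFATIGUE_PROFILE, generate_cohort
from .time_frequency import (
    DEFAULT_RESAMPLE_HZ,
    HF_BAND,
    LF_BAND,
    VLF_BAND,
    band_powers,
    compute_time_domain,
    estimate_psd,
    resample_tachogram,
)
from .types import RRSeries

__all__ = ["RunConfig", "RunReport", "run_pipeline", "validate_config",
           "extract_features", "score_fs14_table"]

log = logging.getLogger("hrvfatigue")

STATES = ("nonfatigue", "fatigue")


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    mode: str = "synthetic"                  # synthetic | rr_files | ecg_files
    out_dir: str = "results/run"
    seed: int = 0
    # synthetic mode
    n_male: int = 38
    n_female: int = 27
    between_subject_sd: float = 0.08
    duration: float = 300.0
    # file modes
    manifest: str | None = None
    fs14_table: str | None = None
    ecg_fs: float | None = None              # override rate when reading ECG CSVs
    # spectral analysis
    vlf_band: tuple[float, float] = VLF_BAND
    lf_band: tuple[float, float] = LF_BAND
    hf_band: tuple[float, float] = HF_BAND
    psd_method: str = "welch"
    resample_rate: float = DEFAULT_RESAMPLE_HZ
    # sample entropy
    entropy_m: int = 2
    entropy_r_coef: float = 0.2
    entropy_tau: int = 1
    # ECG preprocessing
    band_low: float = 0.5
    band_high: float = 40.0
    # artifact filter
    artifact_max_rel_jump: float = 0.3
    artifact_min_ms: float = 300.0
    artifact_max_ms: float = 2000.0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for name in ("vlf_band", "lf_band", "hf_band"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for name in ("vlf_band", "lf_band", "hf_band"):
            d[name] = list(d[name])
        return d


@dataclass
class RunReport:
    """Machine-readable account of one run."""

    config: dict
    version: str = __version__
    n_subjects_input: int = 0
    n_subjects_retained: int = 0
    excluded_subjects: list[dict] = field(default_factory=list)
    artifact_removals: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    outputs: dict = field(default_factory=dict)
    consistency_ok: bool = True

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_config(config: RunConfig) -> list[dict]:
    """Static checks; returns an empty list iff the config is runnable.

    Each finding is ``{"field": ..., "reason": ...}``.
    """
    findings: list[dict] = []

    def bad(fieldname: str, reason: str) -> None:
        findings.append({"field": fieldname, "reason": reason})

    if config.mode not in ("synthetic", "rr_files", "ecg_files"):
        bad("mode", f"unknown mode {config.mode!r}")
    if config.seed < 0:
        bad("seed", "seed must be a non-negative integer")
    if config.mode == "synthetic":
        if config.n_male + config.n_female < 2:
            bad("n_male/n_female", "cohort needs at least 2 subjects")
        if config.duration <= 0:
            bad("duration", "record duration must be positive")
    else:
        if not config.manifest:
            bad("manifest", f"mode {config.mode!r} requires a manifest path")
        elif not Path(config.manifest).exists():
            bad("manifest", f"manifest {config.manifest!r} does not exist")
    for name in ("vlf_band", "lf_band", "hf_band"):
        lo, hi = getattr(config, name)
        if not 0 <= lo < hi:
            bad(name, f"band edges ({lo}, {hi}) must satisfy 0 <= low < high")
    if config.vlf_band[1] > config.lf_band[0]:
        bad("vlf_band/lf_band", "VLF and LF bands overlap")
    if config.lf_band[1] > config.hf_band[0]:
        bad("lf_band/hf_band", "LF and HF bands overlap")
    if config.resample_rate <= 2 * config.hf_band[1]:
        bad("resample_rate", "must exceed twice the HF upper edge")
    if config.psd_method not in ("welch", "ar"):
        bad("psd_method", f"unknown method {config.psd_method!r}")
    if not 0 < config.entropy_r_coef < 1:
        bad("entropy_r_coef", "must be in (0, 1)")
    if config.entropy_m < 1 or config.entropy_tau < 1:
        bad("entropy_m/entropy_tau", "must be positive integers")
    if not 0 < config.band_low < config.band_high:
        bad("band_low/band_high", "need 0 < low < high")
    if not 0 < config.artifact_min_ms < config.artifact_max_ms:
        bad("artifact_min_ms/artifact_max_ms", "need 0 < min < max")
    return findings


def extract_features(rr: RRSeries, config: RunConfig | None = None) -> dict[str, float]:
    """All HRV features of one cleaned RR series as a flat column dict.

    Feature blocks whose data requirements are not met (e.g. spectral
    analysis of a series shorter than a minute) are filled with NaN so a
    degenerate record still yields a table row.
    """
    config = config or RunConfig()
    feats: dict[str, float] = {c: math.nan for c in FEATURE_COLUMNS}
    try:
        feats.update(compute_time_domain(rr).as_dict())
    except HRVError as exc:
        log.warning("time-domain features unavailable: %s", exc)
    try:
        uniform = resample_tachogram(rr, rate=config.resample_rate)
        psd = estimate_psd(uniform, method=config.psd_method)
        feats.update(
            band_powers(
                psd,
                vlf_band=config.vlf_band,
                lf_band=config.lf_band,
                hf_band=config.hf_band,
            ).as_dict()
        )
    except HRVError as exc:
        log.warning("spectral features unavailable: %s", exc)
    try:
        feats.update(poincare_descriptors(rr).as_dict())
    except HRVError as exc:
        log.warning("Poincare features unavailable: %s", exc)
    try:
        panel = entropy_panel(
            rr, m=config.entropy_m, r_coef=config.entropy_r_coef,
            tau=config.entropy_tau,
        )
        for name, res in panel.items():
            feats[name] = res.value if res is not None else math.nan
    except HRVError as exc:
        log.warning("entropy features unavailable: %s", exc)
    return feats


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute a full run and write every output under ``config.out_dir``."""
    findings = validate_config(config)
    if findings:
        raise ParameterError(f"invalid config: {findings}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.as_dict())
    log.info("resolved configuration: %s", config.as_dict())

    series, fs14_df = _load_inputs(config, out, report)
    report.n_subjects_input = len({s["subject_id"] for s in series})

    clean = _clean_series(config, series, report)
    retained_ids = sorted(
        {s["subject_id"] for s in clean}
        - {e["subject_id"] for e in report.excluded_subjects}
    )
    report.n_subjects_retained = len(retained_ids)
    log.info(
        "retained %d of %d subjects", report.n_subjects_retained,
        report.n_subjects_input,
    )

    feature_df = _feature_table(config, clean, retained_ids)
    feature_path = out / "features.csv"
    feature_df.to_csv(feature_path, index=False)
    report.outputs["features"] = str(feature_path)

    _write_comparisons(config, feature_df, fs14_df, out, report)
    _write_densities(feature_df, out, report)

    report.consistency_ok = _check_consistency(feature_df, out)
    if not report.consistency_ok:
        report.warnings.append("comparison tables inconsistent with feature table")
    report_path = out / "report.json"
    write_json(report.as_dict(), report_path)
    report.outputs["report"] = str(report_path)
    return report


# ---------------------------------------------------------------------------
# stages


def _load_inputs(
    config: RunConfig, out: Path, report: RunReport
) -> tuple[list[dict], pd.DataFrame | None]:
    """Return per-(subject, state) RR series rows and the FS-14 table."""
    rows: list[dict] = []
    if config.mode == "synthetic":
        cohort = generate_cohort(
            n_male=config.n_male,
            n_female=config.n_female,
            nonfatigue_profile=dataclasses.replace(
                NONFATIGUE_PROFILE, duration=config.duration
            ),
            fatigue_profile=dataclasses.replace(
                FATIGUE_PROFILE, duration=config.duration
            ),
            between_subject_sd=config.between_subject_sd,
            seed=config.seed,
        )
        rr_dir = out / "rr"
        rr_dir.mkdir(exist_ok=True)
        manifest_rows, fs14_rows = [], []
        for subj in cohort:
            for state in STATES:
                rr = getattr(subj, f"rr_{state}")
                path = rr_dir / f"{subj.subject_id}_{state}.txt"
                write_rr_text(rr, path)
                rows.append(
                    {"subject_id": subj.subject_id, "gender": subj.gender,
                     "state": state, "rr": rr}
                )
                manifest_rows.append(
                    {"subject_id": subj.subject_id, "gender": subj.gender,
                     "state": state, "rr_path": str(path)}
                )
                fs14_rows.append(
                    fs14_row(subj.subject_id, subj.gender, state,
                             getattr(subj, f"fs14_{state}"))
                )
        report.outputs["manifest"] = str(write_manifest(manifest_rows, out / "manifest.csv"))
        report.outputs["fs14"] = str(write_fs14_csv(fs14_rows, out / "fs14.csv"))
        fs14_df = read_fs14_csv(out / "fs14.csv")
        return rows, fs14_df

    manifest = read_manifest(config.manifest)
    for _, entry in manifest.iterrows():
        path = Path(entry["rr_path"])
        if not path.exists():
            raise HRVError(f"input file {path} does not exist")
        if config.mode == "rr_files":
            rr = read_rr_text(path)
        else:
            ecg = read_ecg_csv(path, fs=config.ecg_fs)
            filtered = bandpass_filter(ecg, config.band_low, config.band_high)
            peaks = detect_r_peaks(filtered)
            rr = rr_from_peaks(peaks)
        rows.append(
            {"subject_id": str(entry["subject_id"]), "gender": str(entry["gender"]),
             "state": str(entry["state"]), "rr": rr}
        )
    fs14_df = read_fs14_csv(config.fs14_table) if config.fs14_table else None
    return rows, fs14_df


def _clean_series(
    config: RunConfig, series: list[dict], report: RunReport
) -> list[dict]:
    clean = []
    for row in series:
        filtered, art = artifact_filter(
            row["rr"],
            max_rel_jump=config.artifact_max_rel_jump,
            min_ms=config.artifact_min_ms,
            max_ms=config.artifact_max_ms,
        )
        key = f"{row['subject_id']}/{row['state']}"
        report.artifact_removals[key] = {
            "n_removed": art.n_removed,
            "fraction": art.fraction_removed,
            "removed_indices": art.removed_indices,
        }
        if not art.quality_ok:
            report.excluded_subjects.append(
                {"subject_id": row["subject_id"], "state": row["state"],
                 "reason": f"artifact filter removed {art.fraction_removed:.0%}"}
            )
        clean.append({**row, "rr": filtered})
    return clean


def _feature_table(
    config: RunConfig, clean: list[dict], retained_ids: list[str]
) -> pd.DataFrame:
    records = []
    for row in clean:
        if row["subject_id"] not in retained_ids:
            continue
        feats = extract_features(row["rr"], config)
        records.append(
            {"subject_id": row["subject_id"], "gender": row["gender"],
             "state": row["state"], **feats}
        )
    df = pd.DataFrame(records)
    ordered = ["subject_id", "gender", "state"] + [
        c for c in FEATURE_COLUMNS if c in df.columns
    ]
    return df[ordered]


def _write_comparisons(
    config: RunConfig,
    feature_df: pd.DataFrame,
    fs14_df: pd.DataFrame | None,
    out: Path,
    report: RunReport,
) -> None:
    states_present = set(feature_df["state"].unique())
    if len(states_present) < 2:
        report.warnings.append(
            "only one state present; comparison stage skipped (no pairing)"
        )
        return
    overall = compare_states(feature_df)
    overall_path = out / "comparison_overall.csv"
    overall.to_csv(overall_path, index=False)
    report.outputs["comparison_overall"] = str(overall_path)

    by_gender = compare_states(feature_df, stratify_gender=True)
    gender_path = out / "comparison_by_gender.csv"
    by_gender.to_csv(gender_path, index=False)
    report.outputs["comparison_by_gender"] = str(gender_path)

    rates = overall[["Parameter", "Nonfatigue mean", "Fatigue mean", "Rate (%)"]]
    rates_path = out / "change_rates.csv"
    rates.to_csv(rates_path, index=False)
    report.outputs["change_rates"] = str(rates_path)

    if fs14_df is not None:
        scored = score_fs14_table(fs14_df)
        fs14_cmp = compare_states(
            scored, feature_columns=["FS14 total", "FS14 physical", "FS14 mental"]
        )
        fs14_path = out / "comparison_fs14.csv"
        fs14_cmp.to_csv(fs14_path, index=False)
        report.outputs["comparison_fs14"] = str(fs14_path)


def score_fs14_table(fs14_df: pd.DataFrame) -> pd.DataFrame:
    """Score an FS-14 item table into total/physical/mental columns."""
    item_cols = [f"item{i:02d}" for i in range(1, 15)]
    rows = []
    for _, r in fs14_df.iterrows():
        rec = score_fs14([int(r[c]) for c in item_cols])
        rows.append(
            {"subject_id": r["subject_id"], "gender": r.get("gender", ""),
             "state": r["state"], "FS14 total": rec.total,
             "FS14 physical": rec.physical, "FS14 mental": rec.mental}
        )
    return pd.DataFrame(rows)


def _write_densities(feature_df: pd.DataFrame, out: Path, report: RunReport) -> None:
    """Gender x state kernel-density grids for each feature, long CSV."""
    if "gender" not in feature_df.columns:
        return
    rows = []
    feats = [c for c in feature_df.columns if c in FEATURE_COLUMNS]
    for (gender, state), sub in feature_df.groupby(["gender", "state"]):
        for feat in feats:
            vals = sub[feat].dropna().to_numpy()
            if vals.size < 5 or np.ptp(vals) == 0:
                continue
            de = estimate_pdf(vals, label=f"{gender}/{state}")
            rows.extend(
                {"feature": feat, "gender": gender, "state": state,
                 "x": x, "density": d}
                for x, d in zip(de.grid, de.density)
            )
    if rows:
        path = out / "densities.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        report.outputs["densities"] = str(path)


def _check_consistency(feature_df: pd.DataFrame, out: Path) -> bool:
    """Every comparison mean must be recomputable from the feature table."""
    path = out / "comparison_overall.csv"
    if not path.exists():
        return True
    cmp_df = pd.read_csv(path)
    for _, row in cmp_df.iterrows():
        feat = row["Parameter"]
        if feat not in feature_df.columns:
            return False
        for state, col in (("nonfatigue", "Nonfatigue mean"), ("fatigue", "Fatigue mean")):
            expected = feature_df.loc[feature_df["state"] == state, feat].dropna().mean()
            if not (math.isnan(row[col]) and math.isnan(expected)) and not math.isclose(
                row[col], expected, rel_tol=1e-9, abs_tol=1e-12
            ):
                return False
    return True
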