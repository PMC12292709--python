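"""End-to-end pipeline: simulate -> metrics -> melatonin -> associate -> rhythm.

Every stage communicates through the text formats in :mod:`circalipid.io`,
so the chained run exercises the same readers and writers as the CLI.  A
manifest (config hash, seed, package version, SHA-256 of every table) is
written last; re-running with the same configuration reproduces all tables
byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import (association_battery, cohort_frame, demographic_model,
                    LIPID_COLUMNS)
from .config import PipelineConfig
from .errors import CircalipidError, InsufficientDataError
from .io import (read_epoch_csv, read_melatonin_tsv, read_table,
                 write_light_csv, write_melatonin_tsv, write_table)
from .melatonin import melatonin_acrophase, qc_filter
from .metrics import EpochSeries, fit_cosinor, nonparametric_metrics
from .rhythm import correlation_rhythm, epoch_exposure_matrix, plot_rhythms
from .synth import (EffectSpec, default_profiles, generate_cohort)

logger = logging.getLogger(__name__)


def build_profiles(config: PipelineConfig) -> dict:
    profiles = default_profiles()
    for season, overrides in (config.profiles or {}).items():
        profiles[season] = dataclasses.replace(profiles[season], **overrides)
    return profiles


def build_effects(config: PipelineConfig) -> EffectSpec:
    kwargs = {}
    if config.effects is not None:
        kwargs["effects"] = config.effects
    if config.residual_sd is not None:
        kwargs["residual_sd"] = config.residual_sd
    if config.lipid_scales is not None:
        scales = dict(EffectSpec().lipid_scales)
        scales.update({k: tuple(v) for k, v in config.lipid_scales.items()})
        kwargs["lipid_scales"] = scales
    return EffectSpec(**kwargs)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, out_dir: Path) -> None:
    """Generate the cohort and write light CSVs, cohort.tsv, melatonin.tsv."""
    out_dir.mkdir(parents=True, exist_ok=True)
    light_dir = out_dir / "light"
    light_dir.mkdir(exist_ok=True)
    participants = generate_cohort(
        config.n_subjects, profiles=build_profiles(config),
        effects=build_effects(config), seed=config.seed,
        seasons=tuple(config.seasons), n_days=config.n_days,
        melatonin_fraction=config.melatonin_fraction, keep_series=True,
        epoch_min=config.epoch_min)

    cohort_rows = []
    mel_profiles = []
    for p in participants:
        write_light_csv(
            light_dir / f"{p.subject}_{p.season}.csv",
            p.series["blue_irradiance"], p.series["white_lux"],
            p.series["activity"])
        cohort_rows.append({
            "subject": p.subject, "season": p.season, "age": p.age,
            "sex": p.sex, "indigeneity": p.indigeneity,
            "photoperiod_h": p.photoperiod_h, "meq": p.meq,
            "tc": p.tc, "ldl": p.ldl, "hdl": p.hdl, "tg": p.tg,
        })
        if p.melatonin_profile is not None:
            mel_profiles.append(p.melatonin_profile)
    write_table(pd.DataFrame(cohort_rows), out_dir / "cohort.tsv")
    write_melatonin_tsv(mel_profiles, out_dir / "melatonin.tsv")
    logger.info("simulate: %d subject-seasons written", len(participants))


METRIC_COLUMNS = ("mesor", "amplitude", "acrophase_h", "m10", "m10_onset_h",
                  "l5", "l5_onset_h", "ra", "na")


def stage_metrics(light_dir: Path, out_path: Path,
                  basis: str = "composite", log_light: bool = False) -> None:
    """Read per-minute CSVs and write one metrics row per subject-season."""
    files = sorted(Path(light_dir).glob("*.csv"))
    if not files:
        raise CircalipidError(f"no light CSVs found under {light_dir}")
    rows = []
    for path in files:
        subject, season = path.stem.rsplit("_", 1)
        row = {"subject": subject, "season": season}
        for channel, prefix in (("blue_irradiance", "ble"),
                                ("white_lux", "le")):
            series = read_epoch_csv(path, channel=channel)
            if log_light:
                series = EpochSeries(series.start_time,
                                     np.log10(series.values + 1.0),
                                     series.channel)
            cos = fit_cosinor(series)
            nonpar = nonparametric_metrics(series, cos, basis=basis)
            vals = (cos.mesor, cos.amplitude, cos.acrophase_h,
                    nonpar.m10, nonpar.m10_onset_h, nonpar.l5,
                    nonpar.l5_onset_h, nonpar.ra, nonpar.na)
            row.update({f"{prefix}_{c}": v
                        for c, v in zip(METRIC_COLUMNS, vals)})
        rows.append(row)
    write_table(pd.DataFrame(rows), out_path)
    logger.info("metrics: %d series processed", len(rows))


def stage_melatonin(melatonin_tsv: Path, out_dir: Path) -> None:
    """QC-filter melatonin profiles and write acrophases + QC audit."""
    profiles = read_melatonin_tsv(melatonin_tsv)
    acro_rows, audit_rows = [], []
    for prof in profiles:
        filtered = qc_filter(prof)
        for entry in filtered.qc_audit:
            audit_rows.append({
                "subject": prof.subject, "season": prof.season,
                "time": entry["time"].isoformat(timespec="seconds"),
                "reason": entry["reason"]})
        acro = np.nan
        if filtered.usable:
            try:
                acro = melatonin_acrophase(filtered).acrophase_h
            except CircalipidError as exc:
                logger.warning("melatonin %s/%s: %s",
                               prof.subject, prof.season, exc)
        acro_rows.append({"subject": prof.subject, "season": prof.season,
                          "n_valid": len(filtered.valid_samples()),
                          "usable": filtered.usable,
                          "melatonin_acrophase_h": acro})
    write_table(pd.DataFrame(acro_rows), out_dir / "melatonin_acrophase.tsv")
    write_table(
        pd.DataFrame(audit_rows,
                     columns=["subject", "season", "time", "reason"]),
        out_dir / "melatonin_qc_audit.tsv")
    logger.info("melatonin: %d profiles, %d samples removed",
                len(acro_rows), len(audit_rows))


def load_analysis_frame(out_dir: Path) -> pd.DataFrame:
    """Join cohort demographics/lipids, light metrics and melatonin acrophases."""
    cohort = read_table(out_dir / "cohort.tsv")
    metrics = read_table(out_dir / "metrics.tsv")
    df = cohort.merge(metrics, on=["subject", "season"], how="inner")
    mel_path = out_dir / "melatonin_acrophase.tsv"
    if mel_path.exists():
        mel = read_table(mel_path)[
            ["subject", "season", "melatonin_acrophase_h"]]
        df = df.merge(mel, on=["subject", "season"], how="left")
    df["male"] = (df["sex"] == "male").astype(float)
    df["nn"] = (df["indigeneity"] == "NN").astype(float)
    df["tg_hdl"] = df["tg"] / df["hdl"]
    return df


def stage_associate(out_dir: Path, fdr: float = 0.1,
                    bh_family: str = "global") -> None:
    """Write the correlation/adjusted/demographic association tables."""
    df = load_analysis_frame(out_dir)
    battery = association_battery(df, fdr=fdr, bh_family=bh_family)
    write_table(battery[battery.model == "simple"],
                out_dir / "table1_correlations.tsv")
    write_table(battery[battery.model == "photoperiod_adjusted"],
                out_dir / "table2_adjusted.tsv")
    fig1 = battery[(battery.model == "fully_adjusted")]
    write_table(fig1, out_dir / "fig1_matrix.tsv")
    demo = []
    for outcome in LIPID_COLUMNS:
        try:
            demo.extend(demographic_model(df, outcome))
        except InsufficientDataError as exc:
            logger.warning("table4 %s skipped: %s", outcome, exc)
    write_table(pd.DataFrame([{
        "outcome": r.outcome, "predictor": r.predictor,
        "estimate": r.estimate,
        "variance_explained": r.variance_explained, "p": r.p, "n": r.n,
    } for r in demo]), out_dir / "table4_demographics.tsv")
    logger.info("associate: %d model rows", len(battery))


def stage_rhythm(out_dir: Path, outcomes=("hdl", "tg"),
                 epoch_min: int = 30, fdr: float = 0.1,
                 make_plot: bool = True) -> None:
    """Correlation rhythmometry per lipid from the written light CSVs."""
    cohort = read_table(out_dir / "cohort.tsv")
    series = [read_epoch_csv(out_dir / "light" / f"{r.subject}_{r.season}.csv")
              for r in cohort.itertuples()]
    matrix = epoch_exposure_matrix(series, epoch_min=epoch_min, min_days=3)
    cohort["tg_hdl"] = cohort["tg"] / cohort["hdl"]
    rhythms = []
    summary = []
    for outcome in outcomes:
        rhy = correlation_rhythm(matrix, cohort[outcome].to_numpy(),
                                 outcome=outcome, epoch_min=epoch_min, fdr=fdr)
        rhythms.append(rhy)
        write_table(pd.DataFrame({
            "epoch_center_h": rhy.epoch_centers_h,
            "r": rhy.r_values, "p": rhy.p_values,
            "flagged": rhy.significant_mask,
        }), out_dir / f"rhythm_{outcome}.tsv")
        est = rhy.r_cosinor
        summary.append({
            "lipid": outcome, "acrophase_h": est.acrophase_h,
            "amplitude": est.amplitude, "mesor": est.mesor,
            "f_zero_amp": est.f_zero_amp, "p_zero_amp": est.p_zero_amp,
            "n_rows": rhy.n})
    write_table(pd.DataFrame(summary), out_dir / "rhythm_summary.tsv")
    if make_plot:
        plot_rhythms(rhythms, str(out_dir / "rhythm.png"))
    logger.info("rhythm: %d lipids analysed over %d rows",
                len(outcomes), matrix.shape[0])


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run all stages and write ``manifest.json``; returns the artifact dir."""
    config.validate()
    out_dir = Path(out_dir)
    stages = [
        ("simulate", lambda: stage_simulate(config, out_dir)),
        ("metrics", lambda: stage_metrics(
            out_dir / "light", out_dir / "metrics.tsv",
            basis=config.metric_basis, log_light=config.log_light)),
        ("melatonin", lambda: stage_melatonin(
            out_dir / "melatonin.tsv", out_dir)),
        ("associate", lambda: stage_associate(
            out_dir, fdr=config.fdr, bh_family=config.bh_family)),
        ("rhythm", lambda: stage_rhythm(
            out_dir, outcomes=tuple(config.rhythm_outcomes),
            epoch_min=config.epoch_min, fdr=config.fdr)),
    ]
    for name, fn in stages:
        try:
            fn()
        except Exception as exc:
            raise CircalipidError(f"stage {name!r} failed: {exc}") from exc

    hashes = {}
    for path in sorted(out_dir.rglob("*")):
        if path.suffix in (".tsv", ".csv") and path.is_file():
            hashes[str(path.relative_to(out_dir))] = hashlib.sha256(
                path.read_bytes()).hexdigest()
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": config.digest(),
        "config": json.loads(config.canonical_json()),
        "tables": hashes,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out_dir
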