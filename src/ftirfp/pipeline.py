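"""End-to-end orchestration: simulate or load -> preprocess -> region PCA
-> ratios -> statistics -> machine-readable report.

One YAML config drives both simulation and analysis; unknown keys are a
hard error so typos never silently change a run. The report is a
schema-validated JSON document (pydantic models; the JSON schema ships
with the package) and every table is also written as tidy CSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ConfigDict

from . import __version__
from .spectra_io import SpectraSet, read_spectra_csv, write_spectra_csv
from .preprocess import PreprocessConfig, preprocess_pipeline, select_region
from .chemometrics import pca, pc_side_separation, quadrant_assign, loading_peaks, best_separating_pc
from .bands import default_band_table, assign_band, compute_ratios, ratios_to_frame
from . import stats as fstats
from .simulate import default_profiles, simulate_cohort, SCENARIOS

__all__ = ["AnalysisReport", "load_config", "validate_config", "run"]

log = logging.getLogger("ftirfp")


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict[str, Any] = {
    "alpha": 0.05,
    "replicate_handling": "average",   # average technical replicates per sample | pool
    "k_components": 4,
    "min_prominence": 0.1,
    "search_halfwidth": 15.0,
    "preprocess": {
        "baseline": "rubberband",
        "normalization": "area",
        "sg_half_width": 1,
        "sg_polyorder": 2,
        "derivative_order": 2,
        "regions": [[2800, 3000], [1500, 1800], [900, 1200]],
    },
    "simulate": {
        "scenario": "coriell",
        "n_samples_per_group": 4,
        "replicates_per_sample": 3,
        "spacing": 2.0,
        "noise_sd": 0.002,
        "amplitude_cv": 0.08,
        "seed": 0,
    },
    "input": {
        "spectra_csv": None,
        "metadata_csv": None,
    },
}


def _merge_checked(defaults: dict, user: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, value in user.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown config key: {where!r}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge_checked(defaults[key], value, where)
        else:
            out[key] = value
    return out


def load_config(config_path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    """Defaults merged with a YAML file and programmatic overrides.

    Any key absent from the default config raises (no silent typos).
    """
    cfg = DEFAULT_CONFIG
    if config_path is not None:
        with open(config_path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError("config file must hold a mapping")
        cfg = _merge_checked(cfg, user)
    if overrides:
        cfg = _merge_checked(cfg, overrides)
    return cfg


def _preprocess_config(cfg: dict) -> PreprocessConfig:
    p = cfg["preprocess"]
    return PreprocessConfig(
        baseline_method=p["baseline"], normalization=p["normalization"],
        sg_half_width=int(p["sg_half_width"]), sg_polyorder=int(p["sg_polyorder"]),
        derivative_order=int(p["derivative_order"]),
        regions=tuple((float(lo), float(hi)) for lo, hi in p["regions"]),
    )


def validate_config(config_path: str | Path) -> list[str]:
    """Check a config file without running anything; returns problems ([] = ok)."""
    problems: list[str] = []
    try:
        cfg = load_config(config_path)
    except (ValueError, OSError, yaml.YAMLError) as exc:
        return [str(exc)]
    try:
        _preprocess_config(cfg)
    except ValueError as exc:
        problems.append(f"preprocess: {exc}")
    if not 0 < cfg["alpha"] < 1:
        problems.append("alpha must be in (0, 1)")
    if cfg["replicate_handling"] not in ("average", "pool"):
        problems.append("replicate_handling must be 'average' or 'pool'")
    if cfg["k_components"] < 1:
        problems.append("k_components must be >= 1")
    if not 0 < cfg["min_prominence"] <= 1:
        problems.append("min_prominence must be in (0, 1]")
    if cfg["search_halfwidth"] <= 0:
        problems.append("search_halfwidth must be positive")
    sim = cfg["simulate"]
    if sim["scenario"] not in SCENARIOS:
        problems.append(f"simulate.scenario must be one of {SCENARIOS}")
    for key in ("n_samples_per_group", "replicates_per_sample"):
        if sim[key] < 1:
            problems.append(f"simulate.{key} must be >= 1")
    if sim["spacing"] <= 0:
        problems.append("simulate.spacing must be positive")
    if sim["noise_sd"] < 0:
        problems.append("simulate.noise_sd must be >= 0")
    return problems


# ---------------------------------------------------------------------------
# report models
# ---------------------------------------------------------------------------

class LoadingPeakModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    wavenumber: float
    value: float
    side: str
    mode: Optional[str] = None
    assignment: Optional[str] = None


class SideTableModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pc_index: int
    positive_fraction: dict[str, float]
    clean_separation: bool
    positive_groups: list[str]
    negative_groups: list[str]


class QuadrantModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pc_pair: tuple[int, int]
    majority_quadrant: dict[str, str]
    purity: dict[str, float]
    n_on_axis: int


class RegionPCAModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    region: tuple[float, float]
    n_components: int
    explained_variance_pct: list[float]
    discriminating_pc: Optional[int]
    side_tables: list[SideTableModel]
    quadrants: QuadrantModel
    loading_peaks: list[LoadingPeakModel]


class StatTestModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    test: str
    ratio: str
    comparison: str
    statistic: float
    df: Optional[float] = None
    p_value: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    adjusted: bool = False
    significant: Optional[bool] = None
    note: str = ""


class RatioRowModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sample_id: str
    group: str
    replicate: int
    ratio: str
    value: Optional[float] = None
    error: Optional[str] = None


class AnalysisReport(BaseModel):
    model_config = ConfigDict(extra="forbid")
    version: str
    config_hash: str
    seed: Optional[int]
    alpha: float
    groups: list[str]
    n_rows: int
    regions: list[RegionPCAModel]
    ratios: list[RatioRowModel]
    stats: list[StatTestModel]


def report_json_schema() -> dict:
    return AnalysisReport.model_json_schema()


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------

def _ratio_groups(df: pd.DataFrame, ratio: str, handling: str):
    """Ordered (group_names, value_lists) for one ratio, replicate-aware."""
    sub = df[(df["ratio"] == ratio) & df["value"].notna()]
    if handling == "average":
        sub = sub.groupby(["group", "sample_id"], as_index=False)["value"].mean()
    names, values = [], []
    for g in sorted(sub["group"].unique()):
        names.append(g)
        values.append(sub.loc[sub["group"] == g, "value"].to_numpy())
    return names, values


def _stats_battery(ratio_df: pd.DataFrame, alpha: float, handling: str) -> list[StatTestModel]:
    out: list[StatTestModel] = []
    for ratio in ("ch2_ch3", "carbonyl_total_lipid", "unsat_sat"):
        names, values = _ratio_groups(ratio_df, ratio, handling)
        if len(names) < 2 or any(len(v) == 0 for v in values):
            continue
        pooled = np.concatenate(values)
        norm = fstats.normality_screen(pooled, alpha=alpha)
        out.append(StatTestModel(
            test=norm.test_name, ratio=ratio, comparison="pooled",
            statistic=float(norm.statistic) if np.isfinite(norm.statistic) else 0.0,
            df=None, p_value=norm.p_value, significant=norm.significant, note=norm.note,
        ))
        try:
            kw = fstats.kruskal_wallis(values, names=names, alpha=alpha)
            out.append(StatTestModel(
                test=kw.test_name, ratio=ratio, comparison="omnibus",
                statistic=kw.statistic, df=kw.df, p_value=kw.p_value,
                significant=kw.significant,
            ))
        except ValueError as exc:
            out.append(StatTestModel(test="kruskal_wallis", ratio=ratio, comparison="omnibus",
                                     statistic=0.0, note=str(exc)))
            continue
        control_idx = names.index("control") if "control" in names else 0
        if all(len(v) >= 2 for v in values):
            for res in fstats.manytoone_rank_posthoc(values, control_index=control_idx,
                                                     names=names, alpha=alpha):
                out.append(StatTestModel(
                    test=res.test_name, ratio=ratio,
                    comparison=f"{res.comparison[0]} vs {res.comparison[1]}",
                    statistic=res.statistic, p_value=res.p_value, adjusted=res.adjusted,
                    significant=res.significant, note=res.note,
                ))
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                mw = fstats.mann_whitney_u(values[i], values[j], alpha=alpha,
                                           names=(names[i], names[j]))
                out.append(StatTestModel(
                    test=mw.test_name, ratio=ratio,
                    comparison=f"{names[i]} vs {names[j]}",
                    statistic=mw.statistic, p_value=mw.p_value,
                    significant=mw.significant, note=mw.note,
                ))
                if len(values[i]) >= 2 and len(values[j]) >= 2:
                    try:
                        wt = fstats.welch_t(values[i], values[j], alpha=alpha,
                                            names=(names[i], names[j]))
                    except ValueError:
                        continue
                    out.append(StatTestModel(
                        test=wt.test_name, ratio=ratio,
                        comparison=f"{names[i]} vs {names[j]}",
                        statistic=wt.statistic, df=wt.df, p_value=wt.p_value,
                        significant=wt.significant,
                    ))
    return out


def _analyze_region(full_deriv: SpectraSet, region: tuple[float, float], k: int,
                    min_prominence: float, band_table) -> RegionPCAModel:
    sub = select_region(full_deriv, *region)
    k_eff = max(1, min(k, sub.n_samples - 1, sub.grid.size))
    res = pca(sub, k=k_eff)
    side_tables = [pc_side_separation(res, i) for i in range(1, k_eff + 1)]
    best = best_separating_pc(res)
    disc = best.pc_index if best is not None else None
    peaks = []
    if disc is not None:
        for p in loading_peaks(res, disc, min_prominence=min_prominence):
            hit = assign_band(p.wavenumber, band_table)
            peaks.append(LoadingPeakModel(
                wavenumber=p.wavenumber, value=p.value, side=p.side,
                mode=hit.mode if hit else None,
                assignment=hit.assignment if hit else None,
            ))
    quad = quadrant_assign(res, 1, min(2, k_eff) if k_eff >= 2 else 1)
    return RegionPCAModel(
        region=(float(min(region)), float(max(region))),
        n_components=k_eff,
        explained_variance_pct=[float(v) for v in res.explained_variance_pct],
        discriminating_pc=disc,
        side_tables=[SideTableModel(
            pc_index=s.pc_index, positive_fraction=s.positive_fraction,
            clean_separation=s.clean_separation,
            positive_groups=list(s.positive_groups), negative_groups=list(s.negative_groups),
        ) for s in side_tables],
        quadrants=QuadrantModel(
            pc_pair=quad.pc_pair, majority_quadrant=quad.majority_quadrant,
            purity=quad.purity, n_on_axis=int(sum(quad.on_axis)),
        ),
        loading_peaks=peaks,
    )


def run(config_path: str | Path | None = None, seed: int | None = None,
        out_dir: str | Path | None = None, overrides: dict | None = None) -> AnalysisReport:
    """Execute the full pipeline and (optionally) write its output files.

    Input is either a wide spectra CSV named in the config or, when no
    input files are configured, a simulated cohort from the configured
    scenario. ``seed`` overrides the config's simulation seed. When
    ``out_dir`` is given, report.json, spectra.csv, ratios.csv, stats.csv
    and one pca_region_<lo>-<hi>.csv per region are written there.
    """
    cfg = load_config(config_path, overrides)
    if seed is not None:
        cfg = dict(cfg)
        cfg["simulate"] = dict(cfg["simulate"], seed=int(seed))
    pp_cfg = _preprocess_config(cfg)
    alpha = float(cfg["alpha"])

    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]

    if cfg["input"]["spectra_csv"]:
        log.info("loading spectra from %s", cfg["input"]["spectra_csv"])
        sset = read_spectra_csv(cfg["input"]["spectra_csv"], cfg["input"]["metadata_csv"])
    else:
        sim = cfg["simulate"]
        log.info("simulating scenario %r (seed=%s)", sim["scenario"], sim["seed"])
        sim_cfg = default_profiles(
            sim["scenario"], amplitude_cv=float(sim["amplitude_cv"]),
            n_samples_per_group=int(sim["n_samples_per_group"]),
            replicates_per_sample=int(sim["replicates_per_sample"]),
            spacing=float(sim["spacing"]), noise_sd=float(sim["noise_sd"]),
            seed=int(sim["seed"]),
        )
        sset, _truth = simulate_cohort(sim_cfg)

    log.info("preprocessing %d spectra: baseline=%s normalization=%s sg_half_width=%d "
             "sg_polyorder=%d derivative_order=%d", sset.n_samples, pp_cfg.baseline_method,
             pp_cfg.normalization, pp_cfg.sg_half_width, pp_cfg.sg_polyorder,
             pp_cfg.derivative_order)
    full_deriv = preprocess_pipeline(sset, pp_cfg)

    band_table = default_band_table()
    regions = []
    for region in pp_cfg.regions:
        regions.append(_analyze_region(full_deriv, region, int(cfg["k_components"]),
                                       float(cfg["min_prominence"]), band_table))

    ratio_results = compute_ratios(full_deriv, search_halfwidth=float(cfg["search_halfwidth"]))
    ratio_df = ratios_to_frame(ratio_results)
    stats_models = _stats_battery(ratio_df, alpha, cfg["replicate_handling"])

    report = AnalysisReport(
        version=__version__,
        config_hash=cfg_hash,
        seed=cfg["simulate"]["seed"] if not cfg["input"]["spectra_csv"] else None,
        alpha=alpha,
        groups=sorted(set(sset.labels)),
        n_rows=sset.n_samples,
        regions=regions,
        ratios=[RatioRowModel(
            sample_id=r["sample_id"], group=r["group"], replicate=int(r["replicate"]),
            ratio=r["ratio"], value=None if pd.isna(r["value"]) else float(r["value"]),
            error=r["error"] if isinstance(r["error"], str) else None,
        ) for r in ratio_df.to_dict("records")],
        stats=stats_models,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.model_dump_json(indent=2) + "\n")
        write_spectra_csv(sset, out / "spectra.csv", out / "metadata.csv")
        ratio_df.to_csv(out / "ratios.csv", index=False)
        pd.DataFrame([s.model_dump() for s in stats_models]).to_csv(out / "stats.csv", index=False)
        for region, model in zip(pp_cfg.regions, regions):
            sub = select_region(full_deriv, *region)
            res = pca(sub, k=model.n_components)
            df = pd.DataFrame(res.scores, columns=[f"PC{i+1}" for i in range(res.k)])
            df.insert(0, "sample_id", res.sample_ids)
            df.insert(1, "group", res.labels)
            df.to_csv(out / f"pca_region_{int(min(region))}-{int(max(region))}.csv", index=False)
        log.info("wrote report and tables to %s", out)
    return report
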