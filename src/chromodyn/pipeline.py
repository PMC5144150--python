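"""End-to-end orchestration: simulate -> segment -> coloc -> morpho ->
frap -> severity, with a YAML config, per-stage CSV outputs and a
reproducibility manifest (seed, config hash, package version)."""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .colocalization import classify_binding_pattern, classify_localization, pearson_coloc
from .frap import fit_recovery, normalize_trace, summarize_constructs
from .morphometry import aggregate_construct, compare_to_wt
from .reference import FRAP_REFERENCE, load_css_table
from .segmentation import detect_chromocenters, segment_nuclei
from .severity import SeverityRecord, aggregate_css, compute_fss, correlate_severity
from .synthetic import FrapSimParams, SceneParams, generate_frap_trace, generate_nucleus_image

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "run_pipeline"]

STAGES = ("imaging", "frap", "severity")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "chromodyn_out",
    "log_level": "INFO",
    "figures": False,
    "image": {
        "n_cells": 6,
        "chromocenters_mean": 15.0,
        "chromocenters_sd": 3.0,
        "radius_mean_px": 5.0,
        "radius_sd_px": 0.8,
        "noise_sd": 0.02,
        "pixel_size_um": 0.1,
    },
    "segmentation": {
        "min_nucleus_area": 1000,
        "threshold_k": 2.0,
        "h_seed": 0.1,
        "min_spot_px": 4,
    },
    "morphometry": {"alpha": 0.05},
    # Synthetic construct panel: cn_factor scales the expected chromocenter
    # count, cs_factor the expected spot area, relative to WT.
    "constructs": {
        "WT": {"cn_factor": 1.0, "cs_factor": 1.0, "coloc_mode": "colocalized"},
        "P152A": {"cn_factor": 1.05, "cs_factor": 0.95, "coloc_mode": "colocalized"},
        "R167W": {"cn_factor": 1.4, "cs_factor": 0.75, "coloc_mode": "colocalized"},
        "P152H": {"cn_factor": 1.6, "cs_factor": 0.6, "coloc_mode": "colocalized"},
        "N126I": {"cn_factor": 1.8, "cs_factor": 0.5, "coloc_mode": "colocalized"},
        "F157I": {"cn_factor": 2.0, "cs_factor": 0.4, "coloc_mode": "colocalized"},
        "R111G": {"cn_factor": 1.0, "cs_factor": 1.0,
                  "coloc_mode": "diffuse_mislocalized"},
    },
    "frap": {
        "n_traces": 5,
        "n_pre": 25,
        "n_post": 600,
        "dt_s": 0.2,
        "bleach_depth": 0.8,
        "noise_sd": 0.02,
        "model": "single_exp",
        "constructs": ["WT", "P152A", "P152H", "P152R", "T158M", "R111G"],
    },
    "severity": {"weights": [0.5, 0.5], "css_table": "packaged"},
}

_CONSTRUCT_KEYS = {"cn_factor", "cs_factor", "coloc_mode"}


def validate_config(config: dict, reference: dict | None = None,
                    path: str = "") -> None:
    """Reject configs containing keys the pipeline does not know about,
    naming the offending key."""
    if reference is None:
        reference = DEFAULT_CONFIG
    for key, value in config.items():
        here = f"{path}.{key}" if path else str(key)
        if key == "constructs" and path == "":
            for name, sub in value.items():
                for k in sub:
                    if k not in _CONSTRUCT_KEYS:
                        raise ValueError(f"unknown config key: constructs.{name}.{k}")
            continue
        if key not in reference:
            raise ValueError(f"unknown config key: {here}")
        if isinstance(reference[key], dict) and isinstance(value, dict):
            validate_config(value, reference[key], here)


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, optionally updated from a YAML file and an override dict."""
    config = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst, src):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    for source in (path, overrides):
        if source is None:
            continue
        data = (yaml.safe_load(Path(source).read_text()) or {}
                if not isinstance(source, dict) else source)
        validate_config(data)
        merge(config, data)
    return config


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def _scene_params(cfg: dict, construct_cfg: dict, seed: int) -> SceneParams:
    img = cfg["image"]
    # cs_factor scales area, hence radius by its square root
    return SceneParams(
        n_nuclei=1,
        chromocenters_mean=img["chromocenters_mean"] * construct_cfg["cn_factor"],
        chromocenters_sd=img["chromocenters_sd"],
        radius_mean_px=img["radius_mean_px"] * math.sqrt(construct_cfg["cs_factor"]),
        radius_sd_px=img["radius_sd_px"] * math.sqrt(construct_cfg["cs_factor"]),
        coloc_mode=construct_cfg["coloc_mode"],
        noise_sd=img["noise_sd"],
        pixel_size_um=img["pixel_size_um"],
        seed=seed,
    )


def run_imaging_stage(cfg: dict) -> dict[str, pd.DataFrame]:
    """Simulate, segment and score the construct panel.

    Returns ``{"coloc": per-nucleus table, "morphometry": per-construct
    summary}``.
    """
    seg = cfg["segmentation"]
    rng = np.random.default_rng(cfg["seed"])
    coloc_rows = []
    stats_by_construct = {}
    r_p_by_construct = {}
    for construct, ccfg in cfg["constructs"].items():
        cells = []
        r_ps = []
        for _ in range(cfg["image"]["n_cells"]):
            sp = _scene_params(cfg, ccfg, int(rng.integers(2**31)))
            scene = generate_nucleus_image(sp)
            nuclei = segment_nuclei(scene.dapi, seg["min_nucleus_area"])
            for nuc in nuclei:
                ccs = detect_chromocenters(
                    scene.dapi, nuc,
                    threshold_k=seg["threshold_k"],
                    h_seed=seg["h_seed"],
                    min_spot_px=seg["min_spot_px"],
                    pixel_size_um=cfg["image"]["pixel_size_um"],
                )
                r_p = pearson_coloc(scene.dapi, scene.gfp, nuc)
                cells.append(ccs)
                r_ps.append(r_p)
                coloc_rows.append({
                    "construct": construct,
                    "nucleus_label": nuc.label,
                    "r_p": r_p,
                    "category": classify_localization(r_p),
                    "CN": ccs.cn,
                    "CS_px2": ccs.cs_px2,
                    "CS_um2": ccs.cs_um2,
                })
        stats_by_construct[construct] = aggregate_construct(cells, construct)
        r_p_by_construct[construct] = float(np.median(r_ps))

    wt_stats = stats_by_construct["WT"]
    rows = []
    for construct, stats in stats_by_construct.items():
        comp = compare_to_wt(stats, wt_stats, alpha=cfg["morphometry"]["alpha"])
        med_r = r_p_by_construct[construct]
        pattern, borderline = classify_binding_pattern(
            med_r,
            cn_significant_increase=comp.cn_significant_increase,
            cs_significant_decrease=comp.cs_significant_decrease,
            identifiable_chromocenters=not comp.not_analyzable,
        )
        rows.append({
            "construct": construct,
            "n": stats.n_cells,
            "median_r_p": med_r,
            "category": classify_localization(med_r),
            "pattern": pattern,
            "borderline": borderline,
            "mean_CN": stats.mean_cn,
            "sem_CN": stats.sem_cn,
            "mean_CS_px2": stats.mean_cs,
            "sem_CS_px2": stats.sem_cs,
            "U_CN": comp.cn_test.u if comp.cn_test else np.nan,
            "p_CN": comp.cn_test.p_two_sided if comp.cn_test else np.nan,
            "U_CS": comp.cs_test.u if comp.cs_test else np.nan,
            "p_CS": comp.cs_test.p_two_sided if comp.cs_test else np.nan,
            "tier_CN": comp.tier_cn,
            "tier_CS": comp.tier_cs,
            "not_analyzable": comp.not_analyzable,
        })
    return {"coloc": pd.DataFrame(coloc_rows),
            "morphometry": pd.DataFrame(rows)}


def run_frap_stage(cfg: dict) -> pd.DataFrame:
    """Simulate and fit FRAP traces for each kinetic construct, using the
    reported per-construct half-time and mobile fraction as the generating
    parameters."""
    f = cfg["frap"]
    rng = np.random.default_rng(cfg["seed"] + 1)
    fits = {}
    for construct in f["constructs"]:
        ref = FRAP_REFERENCE[construct]
        group = []
        for _ in range(f["n_traces"]):
            params = FrapSimParams(
                mobile_fraction=ref.mobile_fraction,
                t_half_s=ref.t_half_s,
                bleach_depth=f["bleach_depth"],
                n_pre=f["n_pre"],
                n_post=f["n_post"],
                dt_s=f["dt_s"],
                noise_sd=f["noise_sd"],
                seed=int(rng.integers(2**31)),
            )
            trace = generate_frap_trace(params)
            trace.construct = construct
            group.append(fit_recovery(normalize_trace(trace), f["model"]))
        fits[construct] = group
    return summarize_constructs(fits, wt="WT")


def run_severity_stage(cfg: dict, morpho: pd.DataFrame) -> dict:
    """FSS from the morphometry summary, CSS from the packaged table,
    correlation across mutations with both defined."""
    css = aggregate_css(load_css_table())
    css_map = dict(zip(css["mutation"], css["css"]))
    n_map = dict(zip(css["mutation"], css["n_participants"]))
    wt = morpho[morpho["construct"] == "WT"].iloc[0]
    records = []
    for _, row in morpho.iterrows():
        if row["construct"] == "WT":
            continue
        if row["not_analyzable"] or row["pattern"] in (
                "abolished_binding", "abolished_clustering"):
            # FSS is defined only where the mutation left chromocenter
            # binding and clustering measurable
            fss = None
            cn_rel = cs_rel = None
        else:
            cn_rel = row["mean_CN"] / wt["mean_CN"]
            cs_rel = row["mean_CS_px2"] / wt["mean_CS_px2"]
            fss = compute_fss(row["mean_CN"], row["mean_CS_px2"],
                              wt["mean_CN"], wt["mean_CS_px2"],
                              weights=tuple(cfg["severity"]["weights"]))
        records.append(SeverityRecord(
            mutation=row["construct"],
            cn_rel=cn_rel, cs_rel=cs_rel, fss=fss,
            css=css_map.get(row["construct"]),
            n_participants=int(n_map.get(row["construct"], 0)),
        ))
    report = None
    complete = [r for r in records if r.fss is not None and r.css is not None]
    if len(complete) >= 3:
        report = correlate_severity(records)
    table = pd.DataFrame([{
        "mutation": r.mutation, "CN_rel": r.cn_rel, "CS_rel": r.cs_rel,
        "FSS": r.fss, "CSS": r.css, "n_participants": r.n_participants,
    } for r in records])
    return {"records": records, "table": table, "correlation": report}


def run_pipeline(config: dict | None = None, config_path=None,
                 stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in order, writing per-stage CSVs and a
    manifest to ``output_dir``; returns the manifest dict."""
    cfg = config if config is not None else load_config(config_path)
    validate_config(cfg)
    logging.basicConfig(level=getattr(logging, cfg["log_level"], logging.INFO))
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)

    manifest = {
        "package": "chromodyn",
        "version": __version__,
        "seed": cfg["seed"],
        "config_hash": _config_hash(cfg),
        "stages": {},
        "outputs": [],
    }

    morpho = None
    if "imaging" in stages:
        tables = run_imaging_stage(cfg)
        for name, df in tables.items():
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            manifest["outputs"].append(str(p))
        morpho = tables["morphometry"]
        manifest["stages"]["imaging"] = "ok"
        if cfg["figures"]:
            from .plotting import plot_morphometry_bars
            plot_morphometry_bars(morpho, out / "morphometry.png")
            manifest["outputs"].append(str(out / "morphometry.png"))

    if "frap" in stages:
        frap_summary = run_frap_stage(cfg)
        p = out / "frap_summary.csv"
        frap_summary.to_csv(p, index=False)
        manifest["outputs"].append(str(p))
        manifest["stages"]["frap"] = "ok"

    if "severity" in stages:
        if morpho is None:
            p = out / "morphometry.csv"
            if not p.exists():
                raise FileNotFoundError(
                    "severity stage needs the morphometry summary; run the "
                    "'imaging' stage first")
            morpho = pd.read_csv(p)
        sev = run_severity_stage(cfg, morpho)
        p = out / "severity.csv"
        sev["table"].to_csv(p, index=False)
        manifest["outputs"].append(str(p))
        if sev["correlation"] is not None:
            (out / "severity_correlation.json").write_text(
                json.dumps(sev["correlation"], indent=1))
            manifest["outputs"].append(str(out / "severity_correlation.json"))
        manifest["stages"]["severity"] = "ok"
        if cfg["figures"]:
            from .plotting import plot_fss_vs_css
            plot_fss_vs_css(sev["records"], out / "fss_vs_css.png")
            manifest["outputs"].append(str(out / "fss_vs_css.png"))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
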