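"""End-to-end orchestration: simulate (or load) -> correct -> segment ->
features -> bouts -> PCA detection -> aggregate -> model -> evaluate.

Every stage writes plain CSV/JSON artifacts into the run directory, and a
manifest records the seed, config hash and per-stage counts, so a completed
run is regenerable from the manifest alone. With a fixed seed the whole
artifact set is byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aggregate import build_all_tables, standardize
from .bouts import BoutFitError, allocate_bouts
from .config import PipelineConfig
from .evaluate import loocv
from .features import add_features
from .models import (ModelError, aicc_weights, enumerate_and_rank,
                     model_average, ranked_model_frame)
from .pca import assign_events_to_dives, detect_events
from .segmentation import correct_surface_offset, segment_dives
from .series import AccelSeries, DepthSeries
from .synthetic import SimConfig, simulate_trip

log = logging.getLogger("foragedive")

_CSV_FMT = "%.8g"


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_CSV_FMT)


def process_individual(individual_id: str, depth: DepthSeries, accel: AccelSeries,
                       cfg: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Signal-level stages for one animal: offset correction, segmentation,
    features, bouts, event detection and per-dive counts."""
    corrected = correct_surface_offset(depth, cfg.segmentation)
    dives = segment_dives(corrected, cfg.segmentation)
    dives = add_features(dives, corrected, cfg.segmentation, cfg.features)
    try:
        dives, crit = allocate_bouts(dives, cfg.bouts)
        crit_info = {"bec_s": crit.bec_s, "mean_fast": crit.mean_fast,
                     "mean_slow": crit.mean_slow, "p_fast": crit.p_fast}
    except BoutFitError as err:
        log.warning("%s: bout criterion failed (%s); single bout assumed",
                    individual_id, err)
        dives["bout_id"] = 1
        dives["included"] = False
        crit_info = {"error": str(err)}
    events = detect_events(accel, cfg.pca)
    dives, surface_events = assign_events_to_dives(events, dives)
    dives.insert(0, "individual_id", individual_id)
    info = {
        "individual_id": individual_id,
        "n_dives": int(len(dives)),
        "n_deep": int(dives["deep"].sum()),
        "n_included": int(dives["included"].sum()),
        "n_events": int(len(events)),
        "n_surface_events": int(len(surface_events)),
        "bout_criterion": crit_info,
    }
    return dives, info


def run_pipeline(out_dir: str | Path, cfg: PipelineConfig,
                 sim_cfg: SimConfig | None = None,
                 input_dir: str | Path | None = None,
                 force: bool = False) -> dict:
    """Execute the full pipeline and write all artifacts under ``out_dir``.

    Either ``sim_cfg`` (simulate the deployment) or ``input_dir`` (read
    ``depth_<id>.csv`` / ``accel_<id>.csv`` / ``nights.json``) must be given.
    Returns the manifest dictionary. A completed run (matching seed and
    config hash in ``out_dir/manifest.json``) is not recomputed unless
    ``force`` is set.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prior = out / "manifest.json"
    if prior.exists() and not force:
        old = json.loads(prior.read_text())
        if old.get("seed") == cfg.seed and \
                old.get("config_hash") == cfg.content_hash():
            log.info("run already complete (config %s); use force to redo",
                     old["config_hash"])
            return old
    manifest = {"package_version": __version__, "seed": cfg.seed,
                "config_hash": cfg.content_hash(), "stages": {}}
    cfg.to_yaml(out / "config.yaml")

    # ---- acquire per-individual streams -------------------------------
    streams = []
    night_windows = {}
    spans = {}
    if sim_cfg is not None:
        sim_cfg.seed = cfg.seed
        for i in range(sim_cfg.n_individuals):
            ind = f"ID{i + 1:03d}"
            depth, accel, truth = simulate_trip(sim_cfg, ind)
            depth.write_csv(out / f"depth_{ind}.csv")
            truth.write_json(out / f"truth_{ind}.json")
            if cfg.write_raw_accel:
                accel.write_csv(out / f"accel_{ind}.csv")
            night_windows[ind] = truth.night_windows
            spans[ind] = (float(depth.time[0]), float(depth.time[-1]))
            streams.append((ind, depth, accel))
        manifest["sim"] = {"n_individuals": sim_cfg.n_individuals,
                           "n_nights": sim_cfg.n_nights}
    elif input_dir is not None:
        input_dir = Path(input_dir)
        nights = json.loads((input_dir / "nights.json").read_text())
        for dpath in sorted(input_dir.glob("depth_*.csv")):
            ind = dpath.stem.split("_", 1)[1]
            apath = input_dir / f"accel_{ind}.csv"
            if not apath.exists():
                raise FileNotFoundError(f"missing acceleration file {apath}")
            depth = DepthSeries.read_csv(dpath, ind)
            accel = AccelSeries.read_csv(apath, ind,
                                         sensor_kind=cfg.pca.sensor_kind)
            night_windows[ind] = [tuple(w) for w in nights[ind]]
            spans[ind] = (float(depth.time[0]), float(depth.time[-1]))
            streams.append((ind, depth, accel))
        if not streams:
            raise FileNotFoundError(f"no depth_*.csv found in {input_dir}")
    else:
        raise ValueError("run_pipeline needs either sim_cfg or input_dir")

    # ---- signal-level stages ------------------------------------------
    all_dives = []
    stage_info = []
    for ind, depth, accel in streams:
        dives, info = process_individual(ind, depth, accel, cfg)
        all_dives.append(dives)
        stage_info.append(info)
        log.info("%s: %d dives (%d deep, %d included), %d events",
                 ind, info["n_dives"], info["n_deep"], info["n_included"],
                 info["n_events"])
    dives = pd.concat(all_dives, ignore_index=True)
    _write(dives, out / "dives.csv")
    manifest["stages"]["individuals"] = stage_info
    (out / "bout_criteria.json").write_text(json.dumps(
        {info["individual_id"]: info["bout_criterion"] for info in stage_info},
        indent=1, sort_keys=True))

    # ---- aggregation ---------------------------------------------------
    agg = build_all_tables(dives, night_windows, spans, cfg.aggregate,
                           cfg.scales)
    tables = agg["tables"]
    manifest["stages"]["aggregate"] = {
        "rows": {s: int(len(t.df)) for s, t in tables.items()},
        "skipped": agg["skipped"],
    }
    for scale, table in tables.items():
        _write(table.df, out / f"table_{scale}.csv")

    # ---- selection, averaging, evaluation ------------------------------
    model_info = {}
    for scale, table in tables.items():
        use_re = cfg.models.random_intercept.get(scale, True)
        n = len(table.df)
        candidates = tuple(p for p in table.predictors
                           if table.df[p].std(ddof=0) > 1e-12)
        cap = min(cfg.models.max_vars.get(scale, len(candidates)),
                  len(candidates), n // cfg.models.rows_per_variable)
        if cap < 1 or n < 3:
            model_info[scale] = {"skipped": f"too few rows (n={n})"}
            continue
        std = standardize(table)
        try:
            fits = enumerate_and_rank(std, candidates, cap, use_re, cfg.models)
        except ModelError as err:
            model_info[scale] = {"skipped": str(err)}
            continue
        w = aicc_weights(fits)
        _write(ranked_model_frame(fits, w), out / f"models_{scale}.csv")
        avg = model_average(fits, w, cfg.models.weight_threshold, scale, use_re)
        _write(avg.to_frame(), out / f"averaged_{scale}.csv")
        info = {"n_models": len(fits), "cap": cap,
                "cumulative_weight": avg.cumulative_weight}

        n_ind = table.df["individual_id"].nunique()
        if cfg.run_loocv and n_ind >= 3:
            cv = loocv(table, candidates, cap, use_re, cfg.models)
            _write(cv.folds, out / f"cv_folds_{scale}.csv")
            scatter = pd.DataFrame({"individual_id": cv.individuals,
                                    "observed": cv.observed,
                                    "predicted": cv.predicted})
            _write(scatter, out / f"cv_scatter_{scale}.csv")
            info.update({"pooled_c": cv.pooled_c, "fold_mean_c": cv.fold_mean_c,
                         "full_data_c": cv.full_data_c, "label": cv.label})
        model_info[scale] = info
    manifest["stages"]["models"] = model_info

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest
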