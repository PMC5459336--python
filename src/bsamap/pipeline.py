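"""Whole-pipeline orchestration: preprocess -> ICA -> label -> activity -> ROI stats.

A run consumes one config mapping (flat YAML on disk) and writes a fixed
output layout::

    outdir/
      maps/        activity map, ICA maps, optional SUVR map (NIfTI)
      tables/      ROI stats, component labels, time courses (TSV)
      manifest.json

The manifest records the package version, the SHA-256 hash of the canonical
config, every stage executed, and every seed used — enough to reproduce the
run byte-for-byte. All randomized stages require an explicit seed in the
config; a missing seed is a configuration error, not a silent default.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity import ActivityConfig, activity_map, roi_means, whole_brain_activity
from .errors import ConfigError, DataError
from .io import (
    load_label_atlas,
    read_mask,
    read_volume,
    roi_volume_fractions,
    write_volume,
)
from .ica import decompose
from .labeling import label_components, load_templates
from .pet import suvr_map, voxelwise_correlation
from .phantom import PhantomSpec, generate_subject
from .preprocess import PreprocConfig, preprocess

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "config_hash"]


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()


def _require_seed(config: dict, key: str) -> int:
    val = config.get(key)
    if val is None:
        raise ConfigError(f"config key '{key}' (an explicit seed) is required")
    return int(val)


def _load_series(config: dict):
    if config.get("input") == "simulate":
        seed = _require_seed(config, "simulate.seed")
        spec = PhantomSpec()
        series, truth = generate_subject(spec, seed)
        return series, truth
    path = config.get("input")
    if not path:
        raise ConfigError("config key 'input' must be a 4D NIfTI path or 'simulate'")
    series = read_volume(path, tr_seconds=config.get("tr_seconds"))
    if not hasattr(series, "n_volumes"):
        raise DataError(f"input {path} is not a 4D series")
    if config.get("mask"):
        _, mask = read_mask(config["mask"])
        series = series.with_mask(mask)
    return series, None


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the full pipeline described by ``config``; returns the manifest.

    Stage errors propagate as package exceptions with the stage name attached;
    the CLI maps them to exit codes.
    """
    outdir = Path(outdir)
    maps_dir = outdir / "maps"
    tables_dir = outdir / "tables"
    maps_dir.mkdir(parents=True, exist_ok=True)
    tables_dir.mkdir(parents=True, exist_ok=True)

    stages: list[str] = []
    seeds: dict[str, int] = {}
    stage = "input"
    try:
        series, truth = _load_series(config)
        if config.get("input") == "simulate":
            seeds["simulate"] = _require_seed(config, "simulate.seed")
        stages.append(stage)

        stage = "preprocess"
        pcfg = PreprocConfig(
            fwhm_mm=float(config.get("preproc.fwhm_mm", 6.0)),
            band_low_hz=float(config.get("preproc.band_low_hz", 0.01)),
            band_high_hz=float(config.get("preproc.band_high_hz", 0.1)),
            detrend=bool(config.get("preproc.detrend", True)),
        )
        pre = preprocess(series, pcfg)
        stages.append(stage)

        stage = "ica"
        ica_seed = _require_seed(config, "ica.seed")
        seeds["ica"] = ica_seed
        dec = decompose(pre, n_components=int(config.get("ica.n_components", 30)),
                        seed=ica_seed)
        dec.save(tables_dir, prefix="ica")
        stages.append(stage)

        stage = "label"
        if truth is not None and not config.get("templates"):
            from .phantom import truth_templates

            tset = truth_templates(truth)
        else:
            tdir = config.get("templates")
            if not tdir:
                raise ConfigError("config key 'templates' (directory) is required")
            tset = load_templates(tdir, config.get("templates.tsv"))
        labels = label_components(
            dec, tset, tr_seconds=series.tr_seconds,
            gof_threshold=float(config.get("label.gof_threshold", 0.0)),
            hf_threshold=float(config.get("label.hf_threshold", 0.5)),
        )
        labels.to_frame().to_csv(tables_dir / "component_labels.tsv", sep="\t", index=False)
        stages.append(stage)

        stage = "activity"
        acfg = ActivityConfig(
            aggregation=str(config.get("activity.aggregation", "sum_sd")),
            sd_denominator=str(config.get("activity.sd_denominator", "n-1")),
            clip_negative_nc=bool(config.get("activity.clip_negative_nc", False)),
        )
        amap = activity_map(pre, dec, labels, acfg)
        write_volume(amap.values, maps_dir / "activity.nii.gz", grid=amap.grid)
        stages.append(stage)

        stage = "roi-stats"
        atlas = None
        if config.get("atlas"):
            atlas = load_label_atlas(config["atlas"], config["atlas.tsv"])
        elif truth is not None:
            from .phantom import truth_atlas

            atlas = truth_atlas(truth)
        summary = {
            "whole_brain_activity": whole_brain_activity(amap),
            "k_neuronal": int(labels.k),
        }
        if atlas is not None:
            roi_means(amap, atlas).to_csv(tables_dir / "roi_activity.tsv",
                                          sep="\t", index=False)
            roi_volume_fractions(atlas, amap.mask).to_csv(
                tables_dir / "roi_volume_fractions.tsv", sep="\t", index=False)
        pd.DataFrame([summary]).to_csv(tables_dir / "summary.tsv", sep="\t", index=False)
        stages.append(stage)

        if config.get("pet"):
            stage = "suvr"
            pet_vol = read_volume(config["pet"])
            _, ref = read_mask(config["pet.reference_mask"])
            smap = suvr_map(pet_vol, ref)
            write_volume(smap.values, maps_dir / "suvr.nii.gz", grid=smap.grid)
            stages.append(stage)

            stage = "correlate"
            _, gm = (read_mask(config["correlate.mask"])
                     if config.get("correlate.mask") else (None, amap.mask))
            result = voxelwise_correlation(amap.values, smap.values, gm)
            (tables_dir / "correlation.json").write_text(
                json.dumps(result.to_dict(), indent=2, sort_keys=True))
            stages.append(stage)
    except Exception as exc:
        try:
            wrapped = type(exc)(f"[stage: {stage}] {exc}")
        except Exception:
            wrapped = DataError(f"[stage: {stage}] {exc}")
        raise wrapped from exc

    manifest = {
        "version": __version__,
        "config_hash": config_hash(config),
        "config": {k: config[k] for k in sorted(config)},
        "stages": stages,
        "seeds": seeds,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
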