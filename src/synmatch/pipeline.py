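"""Manifest-driven batch execution of the analysis stages.

A run is described by a single config (YAML or dict): a list of stages,
their parameters, and an output directory.  Stages execute in the order
given; every run writes a JSON manifest recording the inputs, a hash of
the semantically meaningful parameters, the files each stage emitted, and
the package version, so a rerun with the same config and seeds reproduces
byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .factin import classify_and_compare, profile_axon
from .interactome import run_interactome, write_result
from .morpho import annotate_stem, branch_statistics, extract_primary_branches
from .simulate import (
    AxonSimConfig,
    TmtSimConfig,
    VolumeSimConfig,
    gen_axon_with_field,
    gen_glomerular_volumes,
    gen_tmt_dataset,
)
from .tmt import TmtDesign, default_design, read_quant_table
from .volumes import LabeledVolume, match_index, mismatch_index, segment_volume

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the run halts and partial outputs are flagged."""


def config_hash(params: dict) -> str:
    """Stable hash of the semantically meaningful parameters."""
    canon = json.dumps(params, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _resolve_design(params: dict) -> TmtDesign:
    if "design" in params and params["design"]:
        return TmtDesign.from_yaml(params["design"])
    return default_design()


# --- stage implementations -------------------------------------------------


def _stage_simulate_tmt(params: dict, out: Path, ctx: dict) -> list[Path]:
    cfg = TmtSimConfig(**params.get("config", {}))
    table, truth = gen_tmt_dataset(cfg)
    paths = [out / "quant.tsv", out / "truth.tsv"]
    table.to_csv(paths[0], sep="\t", index=False)
    truth.to_csv(paths[1], sep="\t", index=False)
    ctx["quant"] = table
    ctx["bait_id"] = cfg.bait_id
    return paths


def _stage_interactome(params: dict, out: Path, ctx: dict) -> list[Path]:
    design = _resolve_design(params)
    if "quant" in params and params["quant"]:
        table = read_quant_table(params["quant"], design, params.get("column_map"))
    elif "quant" in ctx:
        table = ctx["quant"]
    else:
        raise StageError("interactome: no quant table (path or upstream stage)")
    bait = params.get("bait") or ctx.get("bait_id")
    if not bait:
        raise StageError("interactome: bait id required")
    result = run_interactome(
        table,
        design,
        bait_id=bait,
        min_peptides=int(params.get("min_peptides", 2)),
        top_k=int(params.get("top_k", 37)),
        mode=params.get("mode", "precomputed"),
    )
    return list(write_result(result, out).values())


def _stage_simulate_volumes(params: dict, out: Path, ctx: dict) -> list[Path]:
    cfg = VolumeSimConfig(**params.get("config", {}))
    axon, dendrite, truth = gen_glomerular_volumes(cfg)
    axon.to_tiff(out / "axon.tif")
    dendrite.to_tiff(out / "dendrite.tif")
    truth_path = out / "volume_truth.json"
    truth_path.write_text(
        json.dumps(
            {k: v for k, v in truth.items() if not isinstance(v, np.ndarray)},
            indent=2,
        )
    )
    ctx["axon_vol"], ctx["dendrite_vol"] = axon, dendrite
    return [out / "axon.tif", out / "dendrite.tif", truth_path]


def _stage_match_index(params: dict, out: Path, ctx: dict) -> list[Path]:
    if "axon" in params and params["axon"]:
        axon = LabeledVolume.from_tiff(params["axon"], channel="axon")
        dendrite = LabeledVolume.from_tiff(params["dendrite"], channel="dendrite")
    elif "axon_vol" in ctx:
        axon, dendrite = ctx["axon_vol"], ctx["dendrite_vol"]
    else:
        raise StageError("match_index: no volumes (paths or upstream stage)")
    thr = params.get("threshold", "auto")
    min_size = int(params.get("min_size", 0))
    a = segment_volume(axon, thr, min_size)
    d = segment_volume(dendrite, thr, min_size)
    report = {
        "match_index": match_index(a, d),
        "mismatch_index": mismatch_index(a, d),
        "axon_voxels": a.n_voxels,
        "dendrite_voxels": d.n_voxels,
        "threshold_axon": a.threshold_used,
        "threshold_dendrite": d.threshold_used,
    }
    path = out / "match_report.json"
    path.write_text(json.dumps(report, indent=2))
    return [path]


def _stage_simulate_axon(params: dict, out: Path, ctx: dict) -> list[Path]:
    cfg = AxonSimConfig(**params.get("config", {}))
    sim = gen_axon_with_field(cfg)
    swc = out / "axon.swc"
    sim.tree.to_swc(swc)
    truth_path = out / "axon_truth.json"
    truth_path.write_text(json.dumps(sim.truth, indent=2))
    branches_path = out / "axon_truth_branches.tsv"
    sim.truth_branches.to_csv(branches_path, sep="\t", index=False)
    ctx["sim_axon"] = sim
    return [swc, truth_path, branches_path]


def _stage_axon_stats(params: dict, out: Path, ctx: dict) -> list[Path]:
    if "sim_axon" not in ctx:
        raise StageError("axon_stats: requires an upstream simulate_axon stage")
    sim = ctx["sim_axon"]
    ann = annotate_stem(sim.tree, sim.regions)
    records = extract_primary_branches(sim.tree, ann, sim.regions)
    summary = branch_statistics(records, ann, bins=int(params.get("bins", 20)))
    ctx["annotation"], ctx["records"] = ann, records
    path = out / "axon_summary.json"
    path.write_text(
        json.dumps(
            {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in summary.items()
            },
            indent=2,
        )
    )
    rec_path = out / "branch_records.tsv"
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
        rec_path, sep="\t", index=False
    )
    return [path, rec_path]


def _stage_factin(params: dict, out: Path, ctx: dict) -> list[Path]:
    for key in ("sim_axon", "annotation", "records"):
        if key not in ctx:
            raise StageError("factin: requires simulate_axon and axon_stats stages")
    sim = ctx["sim_axon"]
    profiles = profile_axon(
        sim.tree,
        ctx["annotation"],
        ctx["records"],
        sim.field,
        sim.regions,
        radius_vox=int(params.get("radius_vox", 1)),
        origin=sim.field_origin,
    )
    report = classify_and_compare(profiles)
    path = out / "factin_report.json"
    path.write_text(json.dumps(report, indent=2))
    return [path]


_STAGES: dict[str, Callable[[dict, Path, dict], list[Path]]] = {
    "simulate_tmt": _stage_simulate_tmt,
    "interactome": _stage_interactome,
    "simulate_volumes": _stage_simulate_volumes,
    "match_index": _stage_match_index,
    "simulate_axon": _stage_simulate_axon,
    "axon_stats": _stage_axon_stats,
    "factin": _stage_factin,
}


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages and write a run manifest.

    ``config`` is a dict or a YAML path with keys ``out_dir`` and
    ``stages`` (a list of ``{name: ..., params: {...}}``).  Returns the
    manifest, which is also written to ``manifest.json``.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out = Path(out_dir or config.get("out_dir", "synmatch_run"))
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", [])
    manifest: dict[str, Any] = {
        "version": __version__,
        "config_hash": config_hash({"stages": stages}),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
        "outputs": [],
    }
    ctx: dict = {}
    for entry in stages:
        name = entry["name"] if isinstance(entry, dict) else str(entry)
        params = entry.get("params", {}) if isinstance(entry, dict) else {}
        if name not in _STAGES:
            raise StageError(f"unknown stage {name!r}")
        stage_out = out / name
        stage_out.mkdir(parents=True, exist_ok=True)
        logger.info("running stage %s", name)
        try:
            emitted = _STAGES[name](params, stage_out, ctx)
        except StageError:
            raise
        except Exception as exc:  # halt with a stage-named error
            manifest["failed_stage"] = name
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        rel = [str(p.relative_to(out)) for p in emitted]
        manifest["stages"].append({"name": name, "params": params, "outputs": rel})
        manifest["outputs"].extend(rel)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
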