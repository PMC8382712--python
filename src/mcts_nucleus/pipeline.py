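"""End-to-end pipeline orchestration: simulate → segment → features →
cellcycle → spatial, driven by one YAML config with per-stage sections.

Every stage reads its inputs from and writes its outputs to the run
directory, records itself in the :class:`RunManifest` (written even when
a stage fails, so partial runs stay inspectable) and takes its
randomness from the single run seed — two runs with the same config
produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cellcycle as cc
from . import nucfeatures, spatial, stack_io
from .segment3d import SegmentationConfig, segment_nuclei
from .stack_io import read_stack, write_labels, write_stack
from .synthetic_mcts import PhantomSpec, generate_phantom

__all__ = ["RunManifest", "run_pipeline", "ALL_STAGES"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "segment", "features", "cellcycle", "spatial")


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    seed: int
    version: str = __version__
    stages: list[dict] = field(default_factory=list)
    started: float = field(default_factory=time.time)
    status: str = "running"
    error: str = ""

    def record(self, stage: str, inputs: list[str], outputs: list[str], counts: dict) -> None:
        self.stages.append(
            {
                "stage": stage,
                "inputs": [str(p) for p in inputs],
                "outputs": [str(p) for p in outputs],
                "counts": counts,
                "timestamp": time.time(),
            }
        )

    def write(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(d, indent=2, default=str))


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        cfg = yaml.safe_load(Path(config).read_text())
    else:
        cfg = dict(config)
    if not isinstance(cfg, dict):
        raise ValueError("malformed config: expected a mapping")
    return cfg


def _read_replacements(path) -> dict[int, list[tuple[int, int, int]]]:
    """Seed-replacement CSV: columns label, z, y, x (voxel coordinates)."""
    df = pd.read_csv(path)
    out: dict[int, list[tuple[int, int, int]]] = {}
    for _, row in df.iterrows():
        out.setdefault(int(row["label"]), []).append((int(row["z"]), int(row["y"]), int(row["x"])))
    return out


def run_pipeline(config, stages: list[str] | None = None) -> RunManifest:
    """Execute the requested pipeline stages in order.

    ``config`` is a YAML path or a dict with top-level keys ``out_dir``,
    ``seed``, ``stages`` and one optional section per stage. Fails fast
    with stage-named errors; the manifest is written in every case.
    """
    cfg = _load_config(config)
    out_dir = Path(cfg.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = list(stages or cfg.get("stages", ALL_STAGES))
    for s in stages:
        if s not in ALL_STAGES:
            raise ValueError(f"unknown stage {s!r}; choose from {ALL_STAGES}")
    manifest = RunManifest(config=cfg, seed=seed)
    manifest_path = out_dir / "manifest.json"
    try:
        _run_stages(cfg, stages, out_dir, seed, manifest)
        manifest.status = "ok"
    except Exception as exc:  # noqa: BLE001 - recorded, then re-raised
        manifest.status = "failed"
        manifest.error = f"{exc.__class__.__name__}: {exc}"
        raise
    finally:
        manifest.write(manifest_path)
    return manifest


def _spheroid_ids(cfg: dict, out_dir: Path) -> list[str]:
    n = int(cfg.get("simulate", {}).get("n_spheroids", 1))
    ids = [f"mcts{i:02d}" for i in range(n)]
    existing = sorted(p.name for p in out_dir.glob("mcts*") if p.is_dir())
    return ids if not existing else existing


def _run_stages(cfg: dict, stages: list[str], out_dir: Path, seed: int, manifest: RunManifest) -> None:
    if "simulate" in stages:
        sim = cfg.get("simulate", {})
        spec = PhantomSpec(**{**sim.get("phantom", {}), "seed": seed})
        n = int(sim.get("n_spheroids", 1))
        for i in range(n):
            sid = f"mcts{i:02d}"
            sdir = out_dir / sid
            sdir.mkdir(exist_ok=True)
            channels, labels, truth = generate_phantom(spec, seed=seed + i, spheroid_id=sid)
            outputs = []
            for name, grid in channels.items():
                p = sdir / f"{name}.ome.tif"
                write_stack(grid, p)
                outputs.append(p)
            write_labels(labels, sdir / "truth_labels.ome.tif")
            truth.to_csv(sdir / "truth.csv", index=False)
            spec.to_yaml(sdir / "phantom.yaml")
            manifest.record(
                "simulate", [], outputs + [sdir / "truth_labels.ome.tif", sdir / "truth.csv"],
                {"spheroid": sid, "n_nuclei": int(len(truth))},
            )
    ids = _spheroid_ids(cfg, out_dir)

    if "segment" in stages:
        seg = cfg.get("segment", {})
        seg_cfg = SegmentationConfig(**seg.get("config", {}))
        channel = seg.get("channel", "dapi")
        replacements = _read_replacements(seg["replacements"]) if seg.get("replacements") else None
        for sid in ids:
            sdir = out_dir / sid
            stack_path = Path(seg["input"]) if seg.get("input") else sdir / f"{channel}.ome.tif"
            if not stack_path.exists():
                raise FileNotFoundError(f"segment: input stack {stack_path} missing")
            grid = read_stack(stack_path, channel=channel)
            labels, seeds = segment_nuclei(grid, seg_cfg, replacements=replacements)
            write_labels(labels, sdir / "labels.ome.tif")
            pd.DataFrame(seeds.points, columns=["z", "y", "x"]).assign(source=seeds.source).to_csv(
                sdir / "seeds.csv", index=False
            )
            manifest.record(
                "segment", [stack_path], [sdir / "labels.ome.tif", sdir / "seeds.csv"],
                {"spheroid": sid, "n_labels": int(labels.ids().size), "n_seeds": len(seeds)},
            )

    if "features" in stages:
        feat = cfg.get("features", {})
        wanted = feat.get("channels", ["dapi", "rfp", "gfp"])
        gate = feat.get("volume_gate", [0.6, 1.8])
        from .segment3d import interpolate_isotropic
        from .stack_io import read_labels

        for sid in ids:
            sdir = out_dir / sid
            labels = read_labels(sdir / "labels.ome.tif")
            channels = {}
            for ch in wanted:
                p = sdir / f"{ch}.ome.tif"
                if not p.exists():
                    continue
                grid = read_stack(p, channel=ch)
                # measure intensities on the raw (unsmoothed) stack,
                # interpolated to the labels' isotropic grid if needed
                if grid.shape != labels.shape:
                    grid = interpolate_isotropic(grid)
                channels[ch] = grid
            records = nucfeatures.measure_nuclei(labels, channels, spheroid_id=sid)
            kept, discarded = nucfeatures.volume_gate(records, *gate)
            stack_io.write_records(kept, sdir / "nuclei.csv")
            if discarded:
                stack_io.write_records(discarded, sdir / "nuclei_discarded.csv")
            manifest.record(
                "features", [sdir / "labels.ome.tif"], [sdir / "nuclei.csv"],
                {"spheroid": sid, "n_measured": len(records), "n_gated": len(kept)},
            )

    if "cellcycle" in stages:
        ccfg = cfg.get("cellcycle", {})
        mode = ccfg.get("mode", "threshold")
        dna_channel = ccfg.get("dna_channel", "dapi")
        frames = []
        for sid in ids:
            df = stack_io.read_records(out_dir / sid / "nuclei.csv")
            frames.append(df)
        df = pd.concat(frames, ignore_index=True)
        has_fucci = {"ii_rfp", "ii_gfp"}.issubset(df.columns)
        if has_fucci:
            df["fucci_class"] = cc.classify_fucci(df)
        df, fits = cc.depth_correct(df, channel=dna_channel)
        df = cc.normalize_dna(df, channel=dna_channel)
        report: dict = {"mode": mode, "depth_fits": fits}
        if mode == "threshold":
            threshold = float(ccfg.get("threshold", 1.25))
            if has_fucci:
                try:
                    curve = cc.optimal_threshold(
                        df["dna_content"].to_numpy(), df["fucci_class"].to_numpy()
                    )
                    threshold = curve.optimum
                except ValueError:
                    logger.warning(
                        "single-class FUCCI cohort; keeping configured threshold %.3f", threshold
                    )
            df["predicted_class"] = cc.threshold_classify(df["dna_content"].to_numpy(), threshold)
            report["threshold"] = threshold
        elif mode == "svm":
            if not has_fucci:
                raise ValueError("cellcycle: svm mode needs FUCCI channels for training labels")
            features = cc.neighbor_normalize(df, k=int(ccfg.get("k_neighbors", 5)))
            model, eval_report = cc.train_svm(features, df["fucci_class"].to_numpy(), seed=seed)
            df["predicted_class"] = model.predict(features)
            report["svm"] = {**model.search_results, "test": eval_report.as_dict()}
        else:
            raise ValueError(f"cellcycle: unknown mode {mode!r}")
        if has_fucci:
            labelled = df[df["fucci_class"].isin(["G1", "SG2"])]
            rep = cc.evaluate(labelled["predicted_class"], labelled["fucci_class"])
            report["against_fucci"] = rep.as_dict()
        calls_path = out_dir / "calls.csv"
        df.to_csv(calls_path, index=False)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
        manifest.record(
            "cellcycle", [out_dir / sid / "nuclei.csv" for sid in ids],
            [calls_path, out_dir / "report.json"],
            {"n_nuclei": int(len(df)), "n_sg2": int((df["predicted_class"] == "SG2").sum())},
        )

    if "spatial" in stages:
        sp = cfg.get("spatial", {})
        layer_width = float(sp.get("layer_width", 10.0))
        max_depth = float(sp.get("max_depth", 60.0))
        closing_radius = float(sp.get("closing_radius", 10.0))
        from .stack_io import read_labels

        calls = pd.read_csv(out_dir / "calls.csv", dtype={"spheroid_id": str})
        pieces = []
        for sid in ids:
            sdir = out_dir / sid
            labels = read_labels(sdir / "labels.ome.tif")
            geom = spatial.approximate_surface(labels, closing_radius=closing_radius)
            sub = calls[calls["spheroid_id"] == sid].copy()
            kept, detached = spatial.filter_detached(sub, geom)
            kept["perimeter_distance"] = spatial.perimeter_distance(kept, geom)
            kept["layer"] = spatial.assign_layers(kept["perimeter_distance"], layer_width, max_depth)
            kept["alignment_angle"] = spatial.alignment_angles(kept, geom.center)
            kept["z_alignment_angle"] = spatial.z_alignment_angles(kept)
            pieces.append(kept)
            manifest.record(
                "spatial", [sdir / "labels.ome.tif"], [],
                {"spheroid": sid, "n_kept": len(kept), "n_detached": len(detached)},
            )
        merged = pd.concat(pieces, ignore_index=True)
        merged.to_csv(out_dir / "spatial.csv", index=False)
        cls_col = "predicted_class" if "predicted_class" in merged.columns else "fucci_class"
        per, agg = spatial.layer_stats(
            merged[cls_col], merged["layer"], merged["spheroid_id"],
            n_layers=int(np.ceil(max_depth / layer_width)),
        )
        per.to_csv(out_dir / "layers_per_spheroid.csv", index=False)
        agg.to_csv(out_dir / "layers_aggregate.csv", index=False)
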