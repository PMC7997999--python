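"""End-to-end orchestration: tracks → descriptors → MSD → classification →
spatial quantification → group statistics.

The pipeline is a pure function of (input files, config, root seed): the same
config reproduces every output bit-identically. Each population is either a
track file or a simulation spec; one Brownian-reference classifier is
calibrated once and applied unchanged to all populations. Exclusions are
config-declared (never hard-coded) and logged.

Config schema (YAML or dict)::

    seed: 1
    settings: {frame_interval: 0.5, n_frames: 601, pixel_size: 0.16}
    nucleus_center: [0.0, 0.0]          # optional; enables radial direction
    noise_sigma: 0.0                    # applied to simulated populations
    quantize: false                     # pixel-quantize simulated populations
    populations:
      - label: control
        tracks: control.csv             # OR a simulation spec:
      - label: knockdown
        simulate:
          - {process: brownian_drift, D: 2.5e-4, V: 0.06, count: 45}
          - {process: brownian, D: 2.5e-4, count: 30}
    msd: {max_lag_fraction: 0.25, n_lags: 10, weights: null}
    classification: {tau_S: 5.0, tau_L: 40.0, q_low: 0.5, q_high: 0.95,
                     n_reference: 2000, D_reference: 0.01}
    spatial:                            # optional section
      geometry: {nucleus_radius: 5.0, cell_radius: 15.0, nucleus_offset: 0.0,
                 band_width: 2.0}
      particles: particles.csv
      min_size_nm: 150
    compare: [[control, knockdown]]     # pairs for rank-sum comparisons
    exclude: {control: [track-0001]}    # optional declared exclusions
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import yaml

from . import __version__
from .classify import MotionClassifier
from .core import AcquisitionSettings
from .descriptors import aggregate_descriptors, summarize_population
from .errors import PipelineError
from .io import read_tracks
from .msd import alpha_distribution, compare_alpha
from .simulate import SimulationParams, generate_cell_geometry, generate_population
from .spatial import filter_particles, perinuclear_density, read_particles
from .stats import compare_groups

log = logging.getLogger("melanotrack.pipeline")


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _pop_seed(root_seed: int, index: int) -> int:
    return int((root_seed * 1_000_003 + 7919 * (index + 1)) % (2**31))


def _build_population(pop: dict, settings, config, index: int):
    label = pop["label"]
    if "tracks" in pop:
        trajs = read_tracks(pop["tracks"], settings=settings,
                            allow_gaps=bool(pop.get("allow_gaps", False)))
    elif "simulate" in pop:
        spec = []
        for entry in pop["simulate"]:
            entry = dict(entry)
            count = int(entry.pop("count"))
            spec.append((SimulationParams(**entry), count))
        trajs = generate_population(
            spec,
            settings,
            seed=_pop_seed(int(config.get("seed", 0)), index),
            noise_sigma=config.get("noise_sigma"),
            quantize=bool(config.get("quantize", False)),
            id_prefix=label,
        )
    else:
        raise PipelineError(f"population {label!r}: needs 'tracks' or 'simulate'")
    excluded = set(config.get("exclude", {}).get(label, []))
    if excluded:
        before = len(trajs)
        trajs = [t for t in trajs if t.track_id not in excluded]
        log.info("population %s: excluded %d of %d tracks (declared in config)",
                 label, before - len(trajs), before)
    if not trajs:
        raise PipelineError(f"population {label!r}: no trajectories")
    return trajs


def run_pipeline(config: dict, output_dir: Optional[str] = None) -> Dict:
    """Run the full analysis described by ``config``; optionally write tables.

    Returns a dict with per-population descriptor tables, α distributions,
    classification tables and counts, spatial results (when configured),
    pairwise comparisons, and a manifest of every setting used.
    """
    settings = AcquisitionSettings(**config.get("settings", {}))
    seed = int(config.get("seed", 0))
    nucleus_center = config.get("nucleus_center")
    if nucleus_center is not None:
        nucleus_center = tuple(float(v) for v in nucleus_center)
    msd_cfg = dict(config.get("msd", {}))
    cls_cfg = dict(config.get("classification", {}))

    results: Dict = {"populations": {}, "comparisons": []}
    populations = config.get("populations", [])
    if not populations:
        raise PipelineError("config lists no populations")

    try:
        classifier = MotionClassifier.calibrate(
            settings,
            tau_S=float(cls_cfg.get("tau_S", 5.0)),
            tau_L=float(cls_cfg.get("tau_L", 40.0)),
            q_low=float(cls_cfg.get("q_low", 0.50)),
            q_high=float(cls_cfg.get("q_high", 0.95)),
            n_reference=int(cls_cfg.get("n_reference", 2000)),
            D_reference=float(cls_cfg.get("D_reference", 0.01)),
            noise_sigma=float(config.get("noise_sigma") or 0.0),
            quantize=bool(config.get("quantize", False)),
            seed=_pop_seed(seed, 10_000),
        )
    except Exception as exc:  # stage-labelled diagnostics
        raise PipelineError(f"calibration stage failed: {exc}") from exc
    results["frontiers"] = classifier.frontiers

    for i, pop in enumerate(populations):
        label = pop["label"]
        try:
            trajs = _build_population(pop, settings, config, i)
            log.info("population %s: %d trajectories", label, len(trajs))
            desc = summarize_population(trajs, nucleus_center=nucleus_center)
            alphas = alpha_distribution(
                trajs,
                label=label,
                max_lag_fraction=float(msd_cfg.get("max_lag_fraction", 0.25)),
                n_lags=msd_cfg.get("n_lags", 10),
                weights=msd_cfg.get("weights"),
            )
            cls_table = classifier.classify_population(trajs)
            counts = classifier.count_directional(trajs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"population {label!r} stage failed: {exc}") from exc
        results["populations"][label] = {
            "trajectories": trajs,
            "descriptors": desc,
            "descriptor_aggregates": aggregate_descriptors(desc),
            "alpha": alphas,
            "classification": cls_table,
            "directional_count": counts,
        }

    if "spatial" in config and config["spatial"]:
        sp = config["spatial"]
        try:
            geom = generate_cell_geometry(
                nucleus_radius=float(sp["geometry"]["nucleus_radius"]),
                cell_radius=float(sp["geometry"]["cell_radius"]),
                nucleus_offset=float(sp["geometry"].get("nucleus_offset", 0.0)),
                band_width=float(sp["geometry"].get("band_width", 2.0)),
            )
            particles = filter_particles(
                read_particles(sp["particles"]),
                min_size_nm=float(sp.get("min_size_nm", 150.0)),
            )
            results["spatial"] = perinuclear_density(particles, geom)
        except Exception as exc:
            raise PipelineError(f"spatial stage failed: {exc}") from exc

    for pair in config.get("compare", []):
        la, lb = pair
        pa = results["populations"][la]
        pb = results["populations"][lb]
        comp = {
            "pair": (la, lb),
            "alpha": compare_alpha(pa["alpha"], pb["alpha"]),
        }
        for col in ("total_distance_um", "euclidean_distance_um", "pause_fraction"):
            comp[col] = compare_groups(
                pa["descriptors"][col], pb["descriptors"][col],
                test="mann_whitney", labels=(la, lb),
            )
        results["comparisons"].append(comp)

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "settings": {
            "frame_interval": settings.frame_interval,
            "n_frames": settings.n_frames,
            "pixel_size": settings.pixel_size,
        },
        "msd": msd_cfg,
        "classification": cls_cfg,
        "noise_sigma": config.get("noise_sigma"),
        "quantize": bool(config.get("quantize", False)),
        "populations": [
            {"label": p["label"], "n": len(results["populations"][p["label"]]["trajectories"])}
            for p in populations
        ],
    }
    results["manifest"] = manifest

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        classifier.frontiers.to_json(out / "frontiers.json")
        for label, res in results["populations"].items():
            res["descriptors"].to_csv(out / f"descriptors_{label}.csv", index=False)
            res["classification"].to_csv(out / f"classification_{label}.csv", index=False)
            np.savetxt(out / f"alphas_{label}.csv", res["alpha"].alphas,
                       header="alpha", comments="")
        comp_json = []
        for comp in results["comparisons"]:
            entry = {"pair": list(comp["pair"])}
            for key, gc in comp.items():
                if key == "pair":
                    continue
                entry[key] = {"statistic": gc.statistic, "p_value": gc.p_value,
                              "direction": gc.direction}
            comp_json.append(entry)
        with open(out / "comparisons.json", "w") as fh:
            json.dump(comp_json, fh, indent=2)
        counts_json = {
            label: {
                "n_D": res["directional_count"].n_D,
                "n_intermediate": res["directional_count"].n_intermediate,
                "n_ND": res["directional_count"].n_ND,
                "directional_range": list(res["directional_count"].directional_range),
            }
            for label, res in results["populations"].items()
        }
        with open(out / "directional_counts.json", "w") as fh:
            json.dump(counts_json, fh, indent=2)
        if "spatial" in results:
            spr = results["spatial"]
            with open(out / "spatial.json", "w") as fh:
                json.dump({"count": spr.count, "band_area_um2": spr.band_area_um2,
                           "density_per_um2": spr.density_per_um2}, fh, indent=2)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return results
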