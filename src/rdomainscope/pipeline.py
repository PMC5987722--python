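"""End-to-end orchestration: simulate -> QC -> cluster -> spacing -> coupling.

A single YAML config drives every stage; the run report echoes the
parameters as executed together with the headline summaries (median
stretches/RD, intra-RD NND, Feret, Δt = 60 min spacing median, coupling
transition point) so an identical re-run is fully specified by the report.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import yaml

from . import __version__
from . import clustering, coupling, spacing, storm_qc, synthetic
from .io import atomic_write_yaml

log = logging.getLogger(__name__)

_SECTION_TYPES = {
    "scene": synthetic.SceneConfig,
    "imaging": synthetic.ImagingConfig,
    "motion": synthetic.MotionModel,
    "clustering": clustering.ClusteringConfig,
}

_RUN_DEFAULTS: Dict[str, Any] = {
    "mode": "synthetic",
    "seed": 0,
    "min_photons": 500.0,
    "drift_block_frames": 500,
    "max_resolution_nm": 50.0,
    "frc_threshold": "3sigma",
    "n_scenes": 3,
    "spacing_delta_t": 60.0,
    "spacing_n_scenes": 2,
    "coupling_n_pairs": 1500,
    "coupling_n_frames": 41,
    "coupling_max_distance": 1500.0,
    "out": None,
}


@dataclass
class PipelineConfig:
    scene: synthetic.SceneConfig = field(default_factory=synthetic.SceneConfig)
    imaging: synthetic.ImagingConfig = field(default_factory=synthetic.ImagingConfig)
    motion: synthetic.MotionModel = field(default_factory=synthetic.MotionModel)
    clustering: clustering.ClusteringConfig = field(
        default_factory=clustering.ClusteringConfig)
    run: Dict[str, Any] = field(default_factory=lambda: dict(_RUN_DEFAULTS))


def validate_config(source) -> PipelineConfig:
    """Build a validated config from a YAML path or a nested dict.

    Unknown sections or keys, type mismatches and infeasible values are
    collected and reported together.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source or {})
    errors: List[str] = []
    kwargs: Dict[str, Any] = {}
    for section, content in raw.items():
        if section == "run":
            run = dict(_RUN_DEFAULTS)
            for k, v in (content or {}).items():
                if k not in _RUN_DEFAULTS:
                    errors.append(f"run: unknown key {k!r}")
                else:
                    run[k] = v
            if run.get("mode") not in ("synthetic", "real"):
                errors.append(f"run.mode must be 'synthetic' or 'real', got {run.get('mode')!r}")
            kwargs["run"] = run
            continue
        cls = _SECTION_TYPES.get(section)
        if cls is None:
            errors.append(f"unknown section {section!r}")
            continue
        names = {f.name for f in dataclasses.fields(cls)}
        bad = set(content or {}) - names
        if bad:
            errors.append(f"{section}: unknown keys {sorted(bad)}")
            continue
        content = {k: (tuple(v) if isinstance(v, list) else v)
                   for k, v in (content or {}).items()}
        try:
            kwargs[section] = cls(**content)
        except (TypeError, ValueError) as exc:
            errors.append(f"{section}: {exc}")
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    cfg = PipelineConfig(**kwargs)
    if "run" not in kwargs:
        cfg.run = dict(_RUN_DEFAULTS)
    return cfg


def _qc_and_cluster(cfg: PipelineConfig, rng: np.random.Generator) -> Dict[str, Any]:
    """One scene through the STORM chain; returns summary + QC flags."""
    scene = synthetic.sample_scene(cfg.scene, rng)
    events = synthetic.simulate_event_list(scene, cfg.imaging, rng)
    events = storm_qc.filter_by_photons(events, cfg.run["min_photons"])
    drift_est = None
    if cfg.imaging.drift_model is not None:
        events, drift_est = storm_qc.estimate_and_correct_drift(
            events, cfg.run["drift_block_frames"], cfg.imaging.storm_pixel)
        if drift_est.residual_nm >= 10.0:
            return {"qc": {"drift_residual_nm": drift_est.residual_nm,
                           "passed": False, "reason": "drift"}}
    frc = storm_qc.frc_resolution(events, cfg.imaging.storm_pixel,
                                  cfg.run["frc_threshold"],
                                  cfg.run["max_resolution_nm"])
    qc = {"frc_resolution_nm": frc.resolution_nm, "frc_passed": frc.passed,
          "n_events": len(events), "passed": frc.passed}
    if drift_est is not None:
        qc["drift_residual_nm"] = drift_est.residual_nm
    if not frc.passed:
        qc["reason"] = "frc"
        return {"qc": qc}
    image = storm_qc.render(events, cfg.imaging.storm_pixel)
    _, table, summary = clustering.analyze_image(image, cfg.clustering)
    return {"qc": qc, "summary": summary}


def run_pipeline(cfg: PipelineConfig, out_path=None) -> Dict[str, Any]:
    """Run every stage on synthetic scenes and emit the structured report.

    FRC- or drift-rejected images are recorded and skipped downstream; a
    report is written atomically when ``out_path`` (or run.out) is set.
    """
    if cfg.run.get("mode") != "synthetic":
        raise NotImplementedError("real-data mode expects per-stage CLI invocation")
    seed = int(cfg.run["seed"])
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(3)]
    report: Dict[str, Any] = {
        "software": {"name": "rdomainscope", "version": __version__},
        "parameters": {
            "scene": dataclasses.asdict(cfg.scene),
            "imaging": dataclasses.asdict(cfg.imaging),
            "motion": dataclasses.asdict(cfg.motion),
            "clustering": dataclasses.asdict(cfg.clustering),
            "run": dict(cfg.run),
        },
        "stages": {},
    }
    try:
        # --- STORM QC + clustering -------------------------------------
        per_scene = [_qc_and_cluster(cfg, rngs[0]) for _ in range(cfg.run["n_scenes"])]
        summaries = [s["summary"] for s in per_scene if "summary" in s]
        cl: Dict[str, Any] = {"qc": [s["qc"] for s in per_scene],
                              "n_accepted": len(summaries)}
        if summaries:
            cl["median_stretches_per_rd"] = float(np.median(
                [s["median_stretches_per_rd"] for s in summaries]))
            cl["median_intra_nnd_nm"] = float(np.median(
                [s["median_intra_nnd_nm"] for s in summaries]))
            cl["median_feret_nm"] = float(np.median(
                [s["median_feret_nm"] for s in summaries]))
            cl["solitary_fraction"] = float(np.mean(
                [s["solitary_fraction"] for s in summaries]))
        report["stages"]["clustering"] = cl

        # --- dual-color spacing ----------------------------------------
        dt = float(cfg.run["spacing_delta_t"])
        # solitary stretches are too dim to register as diffraction-limited
        # foci in confocal data; the dual-color scenes omit them
        sc = dataclasses.replace(
            cfg.scene, delta_t=dt, n_rds=max(6, cfg.scene.n_rds // 3),
            field_size=(8000.0, 8000.0, 4000.0), min_center_separation=2500.0,
            solitary_fraction=0.0)
        nnds = []
        for _ in range(cfg.run["spacing_n_scenes"]):
            scene = synthetic.sample_scene(sc, rngs[1])
            stack = synthetic.simulate_confocal_stack(scene, cfg.imaging, rngs[1])
            d1 = spacing.detect_particles_3d(stack, "ch1")
            d2 = spacing.detect_particles_3d(stack, "ch2")
            nnds.append(spacing.cross_channel_nnd(d1, d2, delta_t=dt).nnd)
        pooled = spacing.NNDTable(dt, np.concatenate(nnds),
                                  n_cells=cfg.run["spacing_n_scenes"])
        dt_summary = spacing.summarize_by_dt([pooled])
        report["stages"]["spacing"] = {
            "delta_t_min": dt,
            "median_nnd_nm": float(dt_summary["median_nnd_nm"].iloc[0]),
            "n_pairs": int(dt_summary["n_pairs"].iloc[0]),
        }

        # --- motion coupling -------------------------------------------
        n_pairs = int(cfg.run["coupling_n_pairs"])
        dists = rngs[2].uniform(50.0, cfg.run["coupling_max_distance"], size=n_pairs)
        tracks, _ = synthetic.simulate_trajectory_pairs(
            n_pairs, dists, cfg.motion, int(cfg.run["coupling_n_frames"]), rngs[2])
        pairs = coupling.pair_trajectories(
            tracks, max_pair_distance=4.0 * cfg.run["coupling_max_distance"])
        profile = coupling.coupling_profile(pairs)
        fit = coupling.fit_transition(profile)
        report["stages"]["coupling"] = {
            "n_pairs": profile.n_pairs,
            "transition_distance_nm": fit.d_star_nm,
            "transition_alpha_deg": fit.alpha_star_deg,
            "found": fit.found,
        }
    except Exception as exc:
        report["error"] = f"{type(exc).__name__}: {exc}"
        out = out_path or cfg.run.get("out")
        if out:
            atomic_write_yaml(report, out)
        raise
    out = out_path or cfg.run.get("out")
    if out:
        atomic_write_yaml(report, out)
    return report
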