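"""Pipeline configuration, replica training, orchestration and round trips.

Binds the stages end to end: simulate -> binarize -> features -> mutual
information -> replica fits (full and null, per condition) -> in-silico
efficiency suites.  A single master seed fans out deterministically to every
stage, so two runs with the same configuration are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arena import HexArena, build_arena, place_food
from .colony import (SimConfig, events_from_csv, events_to_csv, simulate_series,
                     tracks_from_csv, tracks_to_csv)
from .efficiency import scenario_suite
from .features import (OccupancyMatrix, activity_series, binarize_tracks,
                       transition_points)
from .maxent import PairwiseModel, calibrate_beta, fit_independent, fit_pairwise, \
    polish_fields, sample_equilibrium
from .mutualinfo import lag_times, windowed_average_mi

__all__ = ["PipelineConfig", "train_replicas", "run_pipeline", "round_trip"]

log = logging.getLogger("antforage")


def _plain(obj):
    """Recursively convert numpy scalars/containers to plain Python types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return type(obj)(_plain(v) for v in obj)
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class PipelineConfig:
    arena_width_mm: float = 2000.0
    arena_height_mm: float = 1000.0
    edge_mm: float = 50.0
    sim: SimConfig = field(default_factory=SimConfig)
    n_trials: int = 3
    conditions: tuple[str, ...] = ("deterministic", "stochastic")
    snap_radius_mm: float = 25.0
    body_length_mm: float = 10.0
    mi_window_s: float = 900.0
    mi_step_s: float = 150.0
    mi_base: float = 2.0
    fit_lambda: float = 0.01
    fit_tol: float = 1e-6
    null_beta: float | None = None  # None: calibrate to the full replica's occupancy
    n_realizations: int = 500
    max_sweeps: int = 10_000
    p_grid: tuple[float, ...] = (0.0, 0.5, 1.0)
    R_grid_mm: tuple[float, ...] = (250.0, 550.0, 750.0)
    master_seed: int = 0
    out_dir: str = "antforage_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        cfg = cls(sim=sim, **{k: tuple(v) if isinstance(v, list) else v
                              for k, v in raw.items()})
        return cfg

    def to_yaml(self, path) -> None:
        obj = _plain(asdict(self))
        with open(path, "w") as fh:
            yaml.safe_dump(obj, fh)

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.master_seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2 ** 31)


def pooled_exploitation_occupancy(
    arena: HexArena, series, config: SimConfig, snap_radius_mm: float = 25.0
) -> OccupancyMatrix:
    """Exploitation-phase frames (TP1..TP2) pooled across a condition's trials."""
    fr = config.frame_rate_hz
    pools = []
    for tracks, events, _scen in series:
        occ = binarize_tracks(tracks, arena, snap_radius_mm,
                              n_frames=config.n_frames, frame_rate_hz=fr)
        ph = transition_points(events, config.duration_s)
        if ph.TP1_s is None or ph.TP2_s is None:
            continue
        f0, f1 = int(ph.TP1_s * fr), int(np.ceil(ph.TP2_s * fr))
        if f1 > f0 + 1:
            pools.append(occ.values[f0:f1])
    if not pools:
        raise ValueError("no trial with an exploitation phase to train on")
    return OccupancyMatrix(np.vstack(pools), fr, list(arena.active_nodes))


def train_replicas(
    arena: HexArena,
    condition: str,
    n_trials: int,
    config: SimConfig,
    seed: int,
    lam: float = 0.01,
    tol: float = 1e-6,
    null_beta: float | None = None,
    calibration_seed: int = 0,
) -> tuple[PairwiseModel, PairwiseModel, OccupancyMatrix]:
    """Simulate a condition's trial series and fit its full and null replicas.

    The null replica's beta is either given or calibrated by bisection so its
    overall occupancy matches the full replica's at beta = 1, mirroring the
    beta=1 vs beta=0.9 pairing used for a fair correlated-vs-independent
    comparison.
    """
    series = simulate_series(arena, condition, n_trials, config, seed)
    occ = pooled_exploitation_occupancy(arena, series, config)
    full = fit_pairwise(occ, lam=lam, tol=tol)
    # pin the replica's per-node mean occupancies back onto the data (the
    # pseudolikelihood optimum alone can drift at equilibrium)
    full = polish_fields(full, occ, seed=calibration_seed + 13)
    null = fit_independent(occ)
    if null_beta is not None:
        null = null.with_beta(null_beta)
    else:
        target = float(sample_equilibrium(full, 2000, seed=calibration_seed).mean())
        try:
            b = calibrate_beta(null, target, tol=0.005, seed=calibration_seed + 1)
            null = null.with_beta(b)
        except ValueError:
            log.warning("null-beta calibration failed; keeping beta=1")
    return full, null, occ


def round_trip(obj, path):
    """Write ``obj`` to ``path`` and read it back (exact for ids/integers,
    <=1e-12 relative for reals); returns the re-read object."""
    path = Path(path)
    if isinstance(obj, HexArena):
        obj.to_json(path)
        return HexArena.from_json(path)
    if isinstance(obj, PairwiseModel):
        obj.to_json(path)
        return PairwiseModel.from_json(path)
    if isinstance(obj, OccupancyMatrix):
        obj.to_csv(path)
        return OccupancyMatrix.from_csv(path)
    if isinstance(obj, pd.DataFrame):
        if "kind" in obj.columns:
            events_to_csv(obj, path)
            return events_from_csv(path)
        tracks_to_csv(obj, path)
        return tracks_from_csv(path)
    if isinstance(obj, (PipelineConfig, SimConfig)):
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(obj)), fh)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if isinstance(obj, SimConfig):
            for k in ("recruit_count_range", "relax_floor"):
                raw[k] = tuple(raw[k])
            return SimConfig(**raw)
        sim = SimConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in raw.pop("sim").items()})
        return PipelineConfig(sim=sim, **{k: tuple(v) if isinstance(v, list) else v
                                          for k, v in raw.items()})
    raise TypeError(f"don't know how to round-trip {type(obj).__name__}")


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline and write all artifacts plus a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stage = "arena"
    manifest: dict = {"seeds": {}, "files": {}, "stages": []}
    try:
        log.info("[arena] building %gx%g mm lattice", config.arena_width_mm,
                 config.arena_height_mm)
        arena = build_arena(config.arena_width_mm, config.arena_height_mm,
                            config.edge_mm)
        arena.to_json(out / "arena.json")
        manifest["stages"].append("arena")

        replicas: dict[str, tuple[PairwiseModel, PairwiseModel]] = {}
        for condition in config.conditions:
            stage = f"simulate:{condition}"
            seed = config.stage_seed(stage)
            manifest["seeds"][stage] = seed
            log.info("[%s] %d trials", stage, config.n_trials)
            series = simulate_series(arena, condition, config.n_trials,
                                     config.sim, seed)
            for t, (tracks, events, scen) in enumerate(series):
                tracks_to_csv(tracks, out / f"tracks_{condition}_{t}.csv")
                events_to_csv(events, out / f"events_{condition}_{t}.csv")

            stage = f"features:{condition}"
            tracks, events, _ = series[0]
            occ0 = binarize_tracks(tracks, arena, config.snap_radius_mm,
                                   n_frames=config.sim.n_frames,
                                   frame_rate_hz=config.sim.frame_rate_hz)
            occ0.to_csv(out / f"occupancy_{condition}_0.csv")
            phases = transition_points(events, config.sim.duration_s)

            stage = f"mi:{condition}"
            log.info("[%s] windowed <MI>", stage)
            series_mi = windowed_average_mi(occ0, config.mi_window_s,
                                            config.mi_step_s, config.mi_base)
            pd.DataFrame({"center_s": series_mi.centers_s,
                          "avg_mi_bits": series_mi.values}
                         ).to_csv(out / f"avg_mi_{condition}_0.csv", index=False)
            lags = lag_times(series_mi, phases)
            (out / f"lags_{condition}_0.json").write_text(
                json.dumps({"T1_s": lags.T1_s, "T2_s": lags.T2_s,
                            "TP1_s": phases.TP1_s, "TP2_s": phases.TP2_s}))

            if condition == "no_food":
                continue
            stage = f"fit:{condition}"
            seed = config.stage_seed(stage)
            manifest["seeds"][stage] = seed
            log.info("[%s] replica fits", stage)
            full, null, _ = train_replicas(
                arena, condition, config.n_trials, config.sim, seed,
                lam=config.fit_lambda, tol=config.fit_tol,
                null_beta=config.null_beta,
                calibration_seed=config.stage_seed(f"calib:{condition}"))
            full.to_json(out / f"replica_{condition}.json")
            null.to_json(out / f"replica_{condition}_null.json")
            replicas[condition] = (full, null)

        if {"deterministic", "stochastic"} <= set(replicas):
            for suite in ("trained", "p_grid", "radial_grid"):
                stage = f"efficiency:{suite}"
                seed = config.stage_seed(stage)
                manifest["seeds"][stage] = seed
                log.info("[%s] %d realizations/cell", stage, config.n_realizations)
                rep = scenario_suite(
                    arena, replicas["deterministic"][0], replicas["stochastic"][0],
                    replicas["deterministic"][1], replicas["stochastic"][1],
                    suite, config.n_realizations, config.max_sweeps, seed,
                    p_grid=config.p_grid, R_grid_mm=config.R_grid_mm)
                payload = [
                    {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                     for k, v in row.items()}
                    for row in rep.to_dict("records")]
                (out / f"efficiency_{suite}.json").write_text(json.dumps(payload))
        else:
            log.info("[efficiency] skipped: needs deterministic and stochastic replicas")
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    config.to_yaml(out / "config.yaml")
    manifest["files"] = {p.name: _sha(p) for p in sorted(out.iterdir())
                         if p.name != "manifest.json"}
    manifest["elapsed_s"] = round(time.time() - t_start, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
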