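"""In-silico food-detection experiments on colony replicas.

A detection run evolves a replica under Glauber dynamics from the all-empty
arena and records the first sweep at which the food nodes i^F have all been
occupied at least once (default) or at which the first one is reached (the
``first_node`` metric).  Efficiency is summarized by survival curves
S(t) = P(detection time > t) and nearest-rank percentiles of the finite
times, with explicit censoring at a sweep cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _glauber
from .arena import FoodScenario, HexArena, place_food
from .maxent import PairwiseModel

__all__ = [
    "DetectionResult",
    "detection_time",
    "run_experiment",
    "survival_curve",
    "percentile_time",
    "scenario_suite",
]


@dataclass
class DetectionResult:
    """Per-realization first-passage detection times in sweeps (-1 censored)."""

    times: np.ndarray
    max_sweeps: int
    scenario: str = ""
    model: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=np.int64)
        finite = t[t > 0]
        if len(finite) and finite.max() > self.max_sweeps:
            raise ValueError("detection time exceeds max_sweeps")
        self.times = t

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def censored_fraction(self) -> float:
        return float((self.times < 0).mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "realization": np.arange(self.n),
            "model": self.model,
            "scenario": self.scenario,
            "time_sweeps": np.where(self.times > 0, self.times, self.max_sweeps),
            "censored": self.times < 0,
        })


def detection_time(
    model: PairwiseModel,
    food_nodes,
    max_sweeps: int = 10_000,
    seed: int = 0,
    metric: str = "all_nodes",
) -> int:
    """Sweeps until the food nodes are detected, or -1 if censored.

    ``all_nodes``: every food node must have been occupied at least once;
    ``first_node``: the first occupancy of any food node suffices.
    """
    food = sorted(food_nodes)
    if not food:
        raise ValueError("empty food node set")
    pos = {n: k for k, n in enumerate(model.node_ids)}
    try:
        idx = np.array([pos[n] for n in food], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"food node {e} not in the model") from e
    kern = (_glauber.detection_kernel if metric == "all_nodes"
            else _glauber.first_detection_kernel)
    return int(kern(np.ascontiguousarray(model.h), np.ascontiguousarray(model.J),
                    float(model.beta), idx, int(max_sweeps), int(seed) % (2 ** 31)))


def run_experiment(
    model: PairwiseModel,
    scenario_sampler,
    n_realizations: int,
    max_sweeps: int = 10_000,
    seed: int = 0,
    metric: str = "all_nodes",
    label: str = "",
) -> DetectionResult:
    """Repeated detection runs; each realization draws a fresh scenario from
    ``scenario_sampler(seed)`` and a fresh dynamics seed."""
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    times = np.empty(n_realizations, dtype=np.int64)
    scen_name = ""
    for r in range(n_realizations):
        sub = np.random.default_rng([seed, r])
        scen = scenario_sampler(int(sub.integers(2 ** 31)))
        scen_name = scen.condition
        times[r] = detection_time(model, scen.food_nodes, max_sweeps,
                                  seed=int(sub.integers(2 ** 31)), metric=metric)
    return DetectionResult(times, max_sweeps, scenario=scen_name, model=label)


def survival_curve(result: DetectionResult) -> tuple[np.ndarray, np.ndarray]:
    """S(t) = fraction of realizations with detection time > t, censored
    counted as beyond the cap; returned on t = 0..max_sweeps."""
    if result.n < 1:
        raise ValueError("empty detection result")
    t = np.arange(result.max_sweeps + 1)
    finite = result.times[result.times > 0]
    exceed = np.searchsorted(np.sort(finite), t, side="right")
    s = 1.0 - exceed / result.n
    return t, s


def percentile_time(result: DetectionResult, q: float = 90.0) -> float:
    """Nearest-rank percentile of the detection times.

    Censored runs sit above every finite time; if the rank falls among them
    the percentile is undefined and an error is raised.
    """
    if not 0 < q <= 100:
        raise ValueError("q must be in (0, 100]")
    n = result.n
    rank = int(np.ceil(q / 100.0 * n))  # 1-based nearest-rank
    finite = np.sort(result.times[result.times > 0])
    if rank > len(finite):
        raise ValueError(
            f"percentile {q} undefined: rank {rank} exceeds the "
            f"{len(finite)} uncensored realizations of {n}")
    return float(finite[rank - 1])


def _sampler(arena: HexArena, condition: str, **kw):
    def draw(seed: int) -> FoodScenario:
        return place_food(arena, condition, seed=seed, **kw)
    return draw


def scenario_suite(
    arena: HexArena,
    det_model: PairwiseModel,
    sto_model: PairwiseModel,
    null_det: PairwiseModel,
    null_sto: PairwiseModel,
    suite: str,
    n_realizations: int = 500,
    max_sweeps: int = 10_000,
    seed: int = 0,
    p_grid=(0.0, 0.5, 1.0),
    R_grid_mm=(250.0, 550.0, 750.0),
    metric: str = "all_nodes",
    percentile: float = 90.0,
) -> pd.DataFrame:
    """Run one of the comparison suites over the four replicas.

    ``trained``: each replica under its own trained food condition;
    ``p_grid``: all replicas across the deterministic-probability mixture;
    ``radial_grid``: all replicas with food restricted to radius R of the
    nest.  Returns one row per (model, scenario) cell with the percentile
    and the survival curve.
    """
    models = {"DET_J": det_model, "STO_J": sto_model,
              "DET_J0": null_det, "STO_J0": null_sto}
    cells = []
    if suite == "trained":
        cells = [(name, "deterministic" if name.startswith("DET") else "stochastic", {})
                 for name in models]
    elif suite == "p_grid":
        cells = [(name, "p_mixture", {"p": float(p)})
                 for p in p_grid for name in models]
    elif suite == "radial_grid":
        cells = [(name, "radial", {"R_mm": float(R)})
                 for R in R_grid_mm for name in models]
    else:
        raise ValueError(f"unknown suite {suite!r}")

    rows = []
    for k, (name, condition, kw) in enumerate(cells):
        res = run_experiment(models[name], _sampler(arena, condition, **kw),
                             n_realizations, max_sweeps,
                             seed=seed, metric=metric,
                             label=name)
        t, s = survival_curve(res)
        try:
            p90 = percentile_time(res, percentile)
        except ValueError:
            p90 = float("nan")
        rows.append({"model": name, "condition": condition, **kw,
                     "n": n_realizations,
                     "censored_fraction": res.censored_fraction,
                     f"p{int(percentile)}_sweeps": p90,
                     "median_sweeps": (percentile_time(res, 50.0)
                                       if res.censored_fraction < 0.5 else float("nan")),
                     "survival_t": t, "survival_s": s,
                     "times": res.times})
    return pd.DataFrame(rows)
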