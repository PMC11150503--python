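"""Pairwise mutual information of binary node occupancies.

MI(I_i, I_j) = sum_{a,b} P_ij(a,b) log[ P_ij(a,b) / (P_i(a) P_j(b)) ]
with plug-in (empirical frequency) probabilities, and its system average
<MI> = 2/(N(N-1)) * sum_{i<j} MI(I_i, I_j), i.e. the mean over unordered
pairs.  Logarithms are base 2 (bits) by default; nats are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arena import HexArena
from .features import OccupancyMatrix, PhaseBounds

__all__ = [
    "MIMatrix",
    "MISeries",
    "LagTimes",
    "pairwise_mi",
    "average_mi",
    "neighbor_mi_map",
    "windowed_average_mi",
    "lag_times",
]


@dataclass
class MIMatrix:
    values: np.ndarray              # N x N symmetric, zero diagonal
    node_ids: list[int]
    window: tuple[float, float]     # (start_s, end_s) of the frames used
    base: float = 2.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("MI matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("MI matrix must be symmetric")
        if (v < -1e-12).any():
            raise ValueError("MI must be non-negative")
        self.values = v

    @property
    def N(self) -> int:
        return self.values.shape[0]


@dataclass
class MISeries:
    centers_s: np.ndarray
    values: np.ndarray              # <MI> per window
    window_s: float
    step_s: float

    def __post_init__(self) -> None:
        if (np.diff(self.centers_s) <= 0).any():
            raise ValueError("window centers must be strictly increasing")


@dataclass(frozen=True)
class LagTimes:
    """Signed lags between <MI> turning points and the transition points.

    T1 = (time <MI> begins to rise) - TP1; T2 = (time <MI> starts to fall)
    - TP2.  Negative values are responses anticipating the transition.
    """

    T1_s: float | None
    T2_s: float | None


def _entropy(p: np.ndarray, base: float) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log(p), 0.0)
    return -t / np.log(base)


def pairwise_mi(
    occupancy: OccupancyMatrix,
    frame_window: tuple[int, int] | None = None,
    base: float = 2.0,
    miller_madow: bool = False,
) -> MIMatrix:
    """Plug-in pairwise MI over the window's frames for every node pair.

    Cells of the empirical 2x2 joint with zero count contribute zero.  The
    optional Miller-Madow correction subtracts the first-order plug-in bias.
    """
    f0, f1 = frame_window if frame_window is not None else (0, occupancy.n_frames)
    X = occupancy.values[f0:f1].astype(np.float64)
    T = X.shape[0]
    if T < 2:
        raise ValueError("need at least 2 frames to estimate MI")
    n1 = X.sum(axis=0)
    n11 = X.T @ X
    n10 = n1[:, None] - n11
    n01 = n1[None, :] - n11
    n00 = T - n11 - n10 - n01
    logb = np.log(base)

    def term(nab, na, nb):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (nab / T) * np.log(nab * T / (na * nb))
        return np.where(nab > 0, t, 0.0)

    mi = (term(n11, n1[:, None], n1[None, :])
          + term(n10, n1[:, None], (T - n1)[None, :])
          + term(n01, (T - n1)[:, None], n1[None, :])
          + term(n00, (T - n1)[:, None], (T - n1)[None, :])) / logb
    if miller_madow:
        # (K_joint - K_i - K_j + 1) / (2T ln base): first-order bias of the
        # plug-in estimator, with K the number of non-empty cells
        kj = ((n11 > 0).astype(int) + (n10 > 0) + (n01 > 0) + (n00 > 0))
        ki = ((n1 > 0).astype(int) + (n1 < T))
        mi -= (kj - ki[:, None] - ki[None, :] + 1) / (2 * T * logb)
    mi = np.maximum(mi, 0.0)
    np.fill_diagonal(mi, 0.0)
    mi = (mi + mi.T) / 2.0
    fr = occupancy.frame_rate_hz
    return MIMatrix(mi, list(occupancy.node_ids), (f0 / fr, f1 / fr), base)


def average_mi(mi_matrix: MIMatrix) -> float:
    """Mean MI over the N(N-1)/2 unordered node pairs."""
    N = mi_matrix.N
    if N < 2:
        raise ValueError("average MI needs at least 2 nodes")
    iu = np.triu_indices(N, k=1)
    return float(mi_matrix.values[iu].mean())


def neighbor_mi_map(mi_matrix: MIMatrix, arena: HexArena) -> dict[int, float]:
    """Per node, the mean MI with its channel-adjacent neighbors (the local
    nearest-neighbor MI used for spatial heat maps); NaN if isolated."""
    col = {n: k for k, n in enumerate(mi_matrix.node_ids)}
    if not set(col) <= set(range(arena.n_nodes)):
        raise ValueError("MI matrix nodes not in arena")
    out: dict[int, float] = {}
    for n, k in col.items():
        nbrs = [col[m] for m in arena.neighbors(n) if m in col]
        out[n] = float(np.mean(mi_matrix.values[k, nbrs])) if nbrs else float("nan")
    return out


def windowed_average_mi(
    occupancy: OccupancyMatrix,
    window_s: float = 900.0,
    step_s: float = 150.0,
    base: float = 2.0,
) -> MISeries:
    """<MI> on a moving window; values reported at window centers."""
    fr = occupancy.frame_rate_hz
    T = occupancy.n_frames
    wf = int(round(window_s * fr))
    sf = max(1, int(round(step_s * fr)))
    if wf > T:
        raise ValueError("window longer than the trial")
    starts = np.arange(0, T - wf + 1, sf)
    vals = np.empty(len(starts))
    for k, s in enumerate(starts):
        vals[k] = average_mi(pairwise_mi(occupancy, (int(s), int(s + wf)), base))
    centers = (starts + wf / 2.0) / fr
    return MISeries(centers, vals, window_s, step_s)


def lag_times(mi_series: MISeries, phases: PhaseBounds,
              smooth: int = 3) -> LagTimes:
    """Signed lags of the <MI> turning points relative to TP1/TP2.

    The series is smoothed with a short moving mean; the rise onset is the
    series minimum before the global maximum, the fall onset is the global
    maximum after TP1.  A monotone series has no turning points and yields
    undefined markers.
    """
    if phases.TP1_s is None or phases.TP2_s is None:
        return LagTimes(None, None)
    v = np.asarray(mi_series.values, float)
    if smooth > 1 and len(v) >= smooth:
        half = smooth // 2
        v = np.array([v[max(0, i - half): i + half + 1].mean()
                      for i in range(len(v))])
    t = np.asarray(mi_series.centers_s)
    dv = np.diff(v)
    if (dv >= 0).all() or (dv <= 0).all():
        return LagTimes(None, None)
    after_tp1 = np.where(t >= phases.TP1_s)[0]
    if len(after_tp1) == 0:
        return LagTimes(None, None)
    i_max = int(after_tp1[np.argmax(v[after_tp1])])
    i_min = int(np.argmin(v[: i_max + 1]))
    return LagTimes(float(t[i_min] - phases.TP1_s), float(t[i_max] - phases.TP2_s))
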