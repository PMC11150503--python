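"""Pairwise maximum-entropy (inverse-Ising) replicas of colony occupancy.

The replica is the distribution

    P(sigma) = exp[ beta ( sum_i h_i sigma_i + sum_{i<j} J_ij sigma_i sigma_j ) ] / Z

over spins sigma_i = 2 I_i - 1 in {-1, +1}, the maximum-entropy model
consistent with the observed node occupancies and pairwise correlations.
Fields h and couplings J are inferred at beta = 1 by node-wise logistic
pseudolikelihood maximization; beta is kept as a post-fit temperature knob
used to tune the replica's overall occupancy.  The null model forces J = 0,
reproducing mean occupancies but no spatial correlations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _glauber
from .features import OccupancyMatrix

__all__ = [
    "PairwiseModel",
    "ExactDistribution",
    "score",
    "exact_distribution",
    "fit_independent",
    "fit_pairwise",
    "polish_fields",
    "sample_equilibrium",
    "goodness_of_fit",
    "occupancy_vs_beta",
    "calibrate_beta",
    "pairwise_fraction",
]


@dataclass
class PairwiseModel:
    h: np.ndarray
    J: np.ndarray
    beta: float = 1.0
    node_ids: list[int] | None = None
    is_null: bool = False
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, float)
        self.J = np.asarray(self.J, float)
        n = self.h.shape[0]
        if self.J.shape != (n, n):
            raise ValueError("J must be N x N")
        if not np.allclose(self.J, self.J.T, atol=1e-12):
            raise ValueError("J must be symmetric")
        if np.abs(np.diag(self.J)).max(initial=0.0) > 1e-12:
            raise ValueError("J must have a zero diagonal")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.is_null and np.abs(self.J).max(initial=0.0) > 0:
            raise ValueError("null model requires J = 0")
        if self.node_ids is None:
            self.node_ids = list(range(n))

    @property
    def N(self) -> int:
        return self.h.shape[0]

    def with_beta(self, beta: float) -> "PairwiseModel":
        return PairwiseModel(self.h, self.J, beta, list(self.node_ids),
                             self.is_null, dict(self.fit_meta))

    # JSON round trip (sparse J triplets), exact to double precision
    def to_json(self, path) -> None:
        iu = np.triu_indices(self.N, k=1)
        nz = np.nonzero(self.J[iu])[0]
        triplets = [[int(iu[0][k]), int(iu[1][k]), float(self.J[iu][k])] for k in nz]
        obj = {"beta": self.beta, "node_ids": [int(n) for n in self.node_ids],
               "h": [float(x) for x in self.h], "J": triplets,
               "is_null": self.is_null, "fit_meta": self.fit_meta}
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "PairwiseModel":
        with open(path) as fh:
            obj = json.load(fh)
        n = len(obj["h"])
        J = np.zeros((n, n))
        for i, j, v in obj["J"]:
            J[i, j] = J[j, i] = v
        return cls(np.array(obj["h"]), J, obj["beta"], obj["node_ids"],
                   obj["is_null"], obj.get("fit_meta", {}))


@dataclass
class ExactDistribution:
    states: np.ndarray       # (2^N, N) spins +-1
    probs: np.ndarray
    Z: float
    log_Z: float


def _as_spins(configuration: np.ndarray) -> np.ndarray:
    c = np.asarray(configuration)
    if np.isin(c, (-1, 1)).all() and (c == -1).any():
        return c.astype(np.int8)
    if np.isin(c, (0, 1)).all():
        return (2 * c - 1).astype(np.int8)
    if np.isin(c, (-1, 1)).all():
        return c.astype(np.int8)
    raise ValueError("configuration must be binary {0,1} or spins {-1,+1}")


def score(model: PairwiseModel, configuration: np.ndarray) -> float:
    """beta (h . sigma + sum_{i<j} J_ij sigma_i sigma_j) for one configuration."""
    s = _as_spins(configuration).astype(float)
    if s.shape[-1] != model.N:
        raise ValueError("configuration dimension does not match the model")
    return float(model.beta * (model.h @ s + 0.5 * s @ model.J @ s))


def _enumerate_spins(n: int) -> np.ndarray:
    return ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(np.int8) * 2 - 1


def exact_distribution(model: PairwiseModel) -> ExactDistribution:
    """Full enumeration of the 2^N configurations (guarded to N <= 20)."""
    if model.N > 20:
        raise ValueError("exact enumeration is limited to N <= 20")
    S = _enumerate_spins(model.N).astype(float)
    scores = model.beta * (S @ model.h + 0.5 * np.einsum("si,ij,sj->s", S, model.J, S))
    m = scores.max()
    w = np.exp(scores - m)
    Z = float(w.sum() * np.exp(m))
    probs = w / w.sum()
    return ExactDistribution(S.astype(np.int8), probs, Z, float(np.log(w.sum()) + m))


def fit_independent(
    occupancy: OccupancyMatrix, beta: float = 1.0, pseudocount: float = 1.0
) -> PairwiseModel:
    """Closed-form independent (J = 0) null model.

    With p_i the Laplace-smoothed mean occupancy of node i, the field is
    h_i = atanh(2 p_i - 1) / beta, so sampled occupancies reproduce the
    per-node means but no collective structure.
    """
    X = occupancy.values
    T = X.shape[0]
    if T == 0:
        raise ValueError("empty occupancy matrix")
    p = (X.sum(axis=0) + pseudocount) / (T + 2 * pseudocount)
    h = np.arctanh(2 * p - 1) / beta
    return PairwiseModel(h, np.zeros((len(h), len(h))), beta,
                         list(occupancy.node_ids), is_null=True,
                         fit_meta={"method": "independent-closed-form",
                                   "pseudocount": pseudocount,
                                   "converged": True,
                                   "training_frames": T})


def fit_pairwise(
    occupancy: OccupancyMatrix,
    lam: float = 0.01,
    tol: float = 1e-6,
    max_iter: int = 500,
    beta: float = 1.0,
    pseudocount: float = 1.0,
    penalize_h: bool = False,
) -> PairwiseModel:
    """Infer (h, J) by node-wise logistic pseudolikelihood maximization.

    The conditional of spin i given the rest is logistic with intercept
    2 h_i and coefficients 2 J_ij, so each node is an L2-penalized logistic
    regression of I_i on the other spins.  The penalty lam multiplies the
    squared parameters against the per-frame mean conditional log-likelihood
    (so its strength does not vanish as the number of training frames grows)
    and by default applies to the couplings only; ``penalize_h`` extends it
    to the fields, which keeps rarely-occupied nodes at moderate h at the
    price of bias in the per-node occupancies.  The two directed estimates of each
    coupling are averaged (symmetrized).  Constant columns get the
    closed-form independent field and zero couplings.
    """
    import warnings as _warnings

    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import LogisticRegression

    X = occupancy.values
    T, N = X.shape
    if T < 2:
        raise ValueError("need at least 2 frames to fit")
    S = (2 * X.astype(np.float64) - 1)
    h = np.zeros(N)
    Jdir = np.zeros((N, N))
    converged = True
    p = (X.sum(axis=0) + pseudocount) / (T + 2 * pseudocount)
    variable = (X.min(axis=0) != X.max(axis=0))
    # sklearn's objective is sum-logloss + ||w||^2/(2C); with w = 2J and the
    # per-frame penalty lam ||J||^2 this maps to C = 2/(lam T)
    ones = np.ones((T, 1))
    for i in range(N):
        if not variable[i]:
            h[i] = np.arctanh(2 * p[i] - 1)
            continue
        others = np.delete(np.arange(N), i)
        if lam > 0:
            clf = LogisticRegression(C=2.0 / (lam * T), solver="lbfgs",
                                     tol=tol, max_iter=max_iter,
                                     fit_intercept=not penalize_h)
        else:
            clf = LogisticRegression(penalty=None, solver="lbfgs",
                                     tol=tol, max_iter=max_iter)
        design = np.hstack([ones, S[:, others]]) if penalize_h and lam > 0 \
            else S[:, others]
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(design, X[:, i])
        if clf.n_iter_[0] >= max_iter:
            converged = False
        if penalize_h and lam > 0:
            h[i] = 0.5 * float(clf.coef_[0][0])
            Jdir[i, others] = 0.5 * clf.coef_[0][1:]
        else:
            h[i] = 0.5 * float(clf.intercept_[0])
            Jdir[i, others] = 0.5 * clf.coef_[0]
    J = 0.5 * (Jdir + Jdir.T)
    np.fill_diagonal(J, 0.0)
    meta = {"method": "pseudolikelihood-logistic", "lambda": lam,
            "converged": bool(converged), "training_frames": T,
            "objective": float(_pseudolikelihood(S, h, J))}
    return PairwiseModel(h, J, beta, list(occupancy.node_ids),
                         is_null=False, fit_meta=meta)


def _pseudolikelihood(S: np.ndarray, h: np.ndarray, J: np.ndarray) -> float:
    f = 2.0 * (h[None, :] + S @ J)            # 2(h_i + sum_j J_ij s_j)
    return float(-np.logaddexp(0.0, -S * f).sum())


def polish_fields(
    model: PairwiseModel,
    occupancy: OccupancyMatrix,
    n_rounds: int = 15,
    n_samples: int = 500,
    learning_rate: float = 0.4,
    seed: int = 0,
) -> PairwiseModel:
    """Boltzmann-learning refinement of the fields h at fixed couplings J.

    Pseudolikelihood estimates the conditionals well but its Glauber
    equilibrium can drift away from the observed per-node occupancies; this
    gradient step h_i <- h_i - eta (<sigma_i>_model - <sigma_i>_data) pins the
    first moments back onto the data, so the replica reproduces the observed
    mean occupancy at every node.
    """
    X = occupancy.values.astype(float)
    target = 2 * X.mean(axis=0) - 1
    h = model.h.copy()
    for r in range(n_rounds):
        m = PairwiseModel(h, model.J, model.beta, list(model.node_ids),
                          model.is_null, model.fit_meta)
        S = 2 * sample_equilibrium(m, n_samples, burn_in_sweeps=100,
                                   thin_sweeps=2, seed=seed + r).astype(float) - 1
        h -= learning_rate * (S.mean(axis=0) - target)
    meta = dict(model.fit_meta)
    meta["field_polish_rounds"] = n_rounds
    return PairwiseModel(h, model.J, model.beta, list(model.node_ids),
                         model.is_null, meta)


def sample_equilibrium(
    model: PairwiseModel,
    n_samples: int,
    burn_in_sweeps: int = 200,
    thin_sweeps: int = 5,
    init: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Glauber equilibrium samples; returns (n_samples, N) binary occupancies."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if init is None:
        init_state = np.where(np.random.default_rng(seed).random(model.N) < 0.5,
                              1, -1).astype(np.int8)
    else:
        init_state = _as_spins(init)
    spins = _glauber.sample_kernel(
        np.ascontiguousarray(model.h), np.ascontiguousarray(model.J),
        float(model.beta), int(n_samples), int(burn_in_sweeps),
        int(max(1, thin_sweeps)), int(seed) % (2 ** 31), init_state)
    return ((spins + 1) // 2).astype(np.uint8)


def goodness_of_fit(
    model: PairwiseModel,
    occupancy: OccupancyMatrix,
    n_samples: int = 2000,
    seed: int = 0,
) -> dict:
    """Data-vs-model comparison of per-node mean occupancies and per-pair
    connected spin correlations, with RMSE and Pearson r summaries."""
    if list(model.node_ids) != list(occupancy.node_ids):
        raise ValueError("model and occupancy node sets differ")
    Xd = occupancy.values.astype(float)
    Xm = sample_equilibrium(model, n_samples, seed=seed).astype(float)
    iu = np.triu_indices(model.N, k=1)

    def stats(X):
        S = 2 * X - 1
        m = X.mean(axis=0)
        C = (S.T @ S) / len(S) - np.outer(S.mean(0), S.mean(0))
        return m, C[iu]

    md, cd = stats(Xd)
    mm, cm = stats(Xm)
    occ_r = float(np.corrcoef(md, mm)[0, 1]) if md.std() > 0 and mm.std() > 0 else float("nan")
    cor_r = float(np.corrcoef(cd, cm)[0, 1]) if cd.std() > 0 and cm.std() > 0 else float("nan")
    return {
        "occupancy_data": md, "occupancy_model": mm,
        "pair_corr_data": cd, "pair_corr_model": cm,
        "occupancy_rmse": float(np.sqrt(np.mean((md - mm) ** 2))),
        "occupancy_r": occ_r,
        "pair_corr_rmse": float(np.sqrt(np.mean((cd - cm) ** 2))),
        "pair_corr_r": cor_r,
        "n_samples": n_samples,
    }


def occupancy_vs_beta(
    model: PairwiseModel,
    beta_grid,
    n_samples: int = 2000,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Equilibrium mean fraction of occupied nodes at each beta."""
    out = []
    for k, b in enumerate(beta_grid):
        if b <= 0:
            raise ValueError("beta must be positive")
        X = sample_equilibrium(model.with_beta(float(b)), n_samples,
                               seed=seed + 7919 * k)
        out.append((float(b), float(X.mean())))
    return out


def calibrate_beta(
    model: PairwiseModel,
    target_occupancy: float,
    tol: float = 0.005,
    seed: int = 0,
    bracket: tuple[float, float] = (0.05, 4.0),
    n_samples: int = 2000,
    max_iter: int = 25,
) -> float:
    """Bisection on beta until the equilibrium occupancy is within ``tol``
    of ``target_occupancy`` (occupancy is monotone in beta on the bracket)."""
    if not 0 < target_occupancy < 1:
        raise ValueError("target occupancy must be in (0, 1)")

    def occ(b, k):
        X = sample_equilibrium(model.with_beta(b), n_samples, seed=seed + k)
        return float(X.mean())

    lo, hi = bracket
    f_lo, f_hi = occ(lo, 0), occ(hi, 1)
    if not (min(f_lo, f_hi) - tol <= target_occupancy <= max(f_lo, f_hi) + tol):
        raise ValueError(
            f"target occupancy {target_occupancy} outside achievable "
            f"range [{min(f_lo, f_hi):.4f}, {max(f_lo, f_hi):.4f}]")
    above_lo = f_lo > target_occupancy
    for k in range(2, max_iter + 2):
        mid = 0.5 * (lo + hi)
        f_mid = occ(mid, k)
        if abs(f_mid - target_occupancy) <= tol:
            return mid
        # keep the sub-bracket whose ends still straddle the target
        if (f_mid > target_occupancy) == above_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# -- pairwise fraction of total correlations ----------------------------

def _subset_joint(X: np.ndarray) -> np.ndarray:
    """Empirical joint over the 2^k states of the subset columns."""
    T, k = X.shape
    idx = X.astype(np.int64) @ (1 << np.arange(k))
    counts = np.bincount(idx, minlength=2 ** k).astype(float)
    return counts / T


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _ipf_pairwise(p_emp: np.ndarray, k: int, max_iter: int = 200,
                  tol: float = 1e-8) -> np.ndarray:
    """Max-ent distribution matching all pairwise (hence single) marginals
    of ``p_emp``, by iterative proportional fitting over 2^k states."""
    states = ((np.arange(2 ** k)[:, None] >> np.arange(k)) & 1)
    q = np.full(2 ** k, 1.0 / 2 ** k)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    targets = {}
    for i, j in pairs:
        t = np.zeros((2, 2))
        np.add.at(t, (states[:, i], states[:, j]), p_emp)
        targets[(i, j)] = t
    for _ in range(max_iter):
        err = 0.0
        for i, j in pairs:
            cur = np.zeros((2, 2))
            np.add.at(cur, (states[:, i], states[:, j]), q)
            ratio = np.where(cur > 0, targets[(i, j)] / np.where(cur > 0, cur, 1.0), 0.0)
            q = q * ratio[states[:, i], states[:, j]]
            s = q.sum()
            if s > 0:
                q /= s
            err = max(err, float(np.abs(cur - targets[(i, j)]).max()))
        if err < tol:
            break
    return q


def pairwise_fraction(occupancy: OccupancyMatrix, node_subset) -> float:
    """Share I2/IN of the subset's total multi-information captured by the
    best pairwise maximum-entropy fit (connected-information decomposition).

    IN = sum_i H(I_i) - H(joint); I2 = sum_i H(I_i) - H(P2) with P2 the
    iterative-scaling fit to all pair marginals.  Exact enumeration limits
    the subset to at most 10 nodes.
    """
    cols = [occupancy.node_ids.index(n) for n in node_subset]
    k = len(cols)
    if k < 2:
        raise ValueError("need at least 2 nodes")
    if k > 10:
        raise ValueError("subset too large for exact enumeration (max 10)")
    X = occupancy.values[:, cols]
    p_emp = _subset_joint(X)
    h_ind = sum(_entropy(np.array([1 - m, m])) for m in X.mean(axis=0))
    i_n = h_ind - _entropy(p_emp)
    if i_n <= 1e-12:
        return 1.0  # no correlations at all: pairwise trivially captures them
    p2 = _ipf_pairwise(p_emp, k)
    i_2 = h_ind - _entropy(p2)
    return float(np.clip(i_2 / i_n, 0.0, 1.0))
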