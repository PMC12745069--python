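"""Close/Distant fixation split via 1-D quantile-based (k-quantiles) clustering.

The distance-to-ship values (degrees) are clustered with k = 2 using a
quantile-based loss: each cluster k has a skewness parameter θ_k and a
center q_k (its θ_k-quantile), and a point x assigned to cluster k costs

    −log(θ_k (1 − θ_k)) + ρ_{θ_k}(x − q_k),

where ρ_θ is the check (pinball) function.  Variables are scaled by their
standard deviation before clustering and θ is estimated per cluster
("variable-wise θ, scaled variables").  The fit keeps the best of ``b``
random initializations of an assign/update iteration and finishes with a
contiguous-split polish; for 1-D data the optimal 2-cluster partition is a
single split of the sorted values, and the exhaustive search over all such
splits (``exhaustive_split``) is the normative definition of the optimum
in this package — the iterative fit is required to agree with it.

The decision threshold reported for a fitted split lies strictly between
the two clusters; a distance exactly at the threshold is labeled distant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = ["ClusterParams", "ClassSplit", "DegenerateDataError",
           "kquantiles_fit", "exhaustive_split", "apply_split",
           "segment_cost"]


class DegenerateDataError(ValueError):
    """All distances identical; no two-cluster split exists."""


@dataclass(frozen=True)
class ClusterParams:
    k: int = 2
    b: int = 50                  # random initialization repeats
    method: str = "VS"           # variable-wise theta, scaled variables
    seed: int = 0
    max_iter: int = 60

    def __post_init__(self):
        if self.k != 2:
            raise ValueError("only k = 2 is supported for this analysis")
        if self.b < 1:
            raise ValueError("b must be >= 1")


@dataclass
class ClassSplit:
    threshold_deg: float
    labels: np.ndarray           # "close" | "distant", input order
    objective: float             # final loss, scaled space
    centers_deg: tuple[float, float]
    thetas: tuple[float, float]
    n_close: int
    n_distant: int


_EPS = 1e-4


def _cluster_cost(arr: np.ndarray, prefix: np.ndarray) -> tuple[float, float, float]:
    """Optimal (cost, theta, center) for one sorted cluster.

    ``prefix`` is the length-(m+1) cumulative sum of ``arr``.
    """
    m = len(arr)
    if m == 0:
        return 0.0, 0.5, np.nan

    def cost_at(theta: float) -> float:
        q = np.quantile(arr, theta)
        k1 = np.searchsorted(arr, q, side="left")
        k2 = np.searchsorted(arr, q, side="right")
        below = k1 * q - prefix[k1]
        above = (prefix[m] - prefix[k2]) - (m - k2) * q
        return -m * np.log(theta * (1 - theta)) + theta * above + (1 - theta) * below

    res = minimize_scalar(cost_at, bounds=(_EPS, 1 - _EPS), method="bounded",
                          options={"xatol": 1e-6})
    theta = float(res.x)
    return float(res.fun), theta, float(np.quantile(arr, theta))


def segment_cost(xs: np.ndarray, i: int, j: int) -> float:
    """Cluster cost of the sorted slice xs[i:j]."""
    arr = xs[i:j]
    prefix = np.concatenate([[0.0], np.cumsum(arr)])
    return _cluster_cost(arr, prefix)[0]


def exhaustive_split(xs_sorted: np.ndarray) -> tuple[int, float]:
    """Globally best contiguous split of sorted 1-D data into two clusters.

    Returns (split index i, loss); the low cluster is xs[:i].  Only splits
    between distinct values are admissible so that the induced labeling is
    a monotone step function of the distance.
    """
    n = len(xs_sorted)
    best_i, best_loss = -1, np.inf
    for i in range(1, n):
        if xs_sorted[i] == xs_sorted[i - 1]:
            continue
        loss = segment_cost(xs_sorted, 0, i) + segment_cost(xs_sorted, i, n)
        if loss < best_loss:
            best_i, best_loss = i, loss
    return best_i, best_loss


def _point_cost(x: np.ndarray, theta: float, q: float) -> np.ndarray:
    u = x - q
    rho = np.where(u >= 0, theta * u, (theta - 1) * u)
    return -np.log(theta * (1 - theta)) + rho


def kquantiles_fit(distances_deg: np.ndarray,
                   params: ClusterParams = ClusterParams()) -> ClassSplit:
    """Fit the two-cluster quantile split of 1-D distances (degrees)."""
    d = np.asarray(distances_deg, dtype=float)
    if d.ndim != 1 or len(d) < 2:
        raise ValueError("need a 1-D array of at least two distances")
    if np.ptp(d) == 0:
        raise DegenerateDataError("all distances identical")
    scale = float(np.std(d))
    xs = d / scale
    order = np.argsort(xs, kind="stable")
    xs_sorted = xs[order]
    n = len(xs_sorted)
    rng = np.random.default_rng(params.seed)

    best_assign, best_loss = None, np.inf
    for _ in range(params.b):
        centers = rng.choice(xs_sorted, size=2, replace=False)
        thetas = [0.5, 0.5]
        qs = sorted(centers)
        assign = None
        for _ in range(params.max_iter):
            costs = np.vstack([_point_cost(xs_sorted, thetas[k], qs[k])
                               for k in range(2)])
            new_assign = np.argmin(costs, axis=0)
            if assign is not None and np.array_equal(new_assign, assign):
                break
            assign = new_assign
            loss = 0.0
            ok = True
            for k in range(2):
                arr = xs_sorted[assign == k]
                if len(arr) == 0:
                    ok = False
                    break
                prefix = np.concatenate([[0.0], np.cumsum(arr)])
                c, thetas[k], qs[k] = _cluster_cost(arr, prefix)
                loss += c
            if not ok:
                break
        if assign is None or len(np.unique(assign)) < 2:
            continue
        if loss < best_loss:
            best_loss, best_assign = loss, assign.copy()

    # contiguous polish: reduce the converged solution to a split of the
    # sorted values and hill-climb over admissible split positions
    if best_assign is None:
        split_i = n // 2
    else:
        lo_cluster = int(np.argmin([xs_sorted[best_assign == k].mean()
                                    for k in range(2)]))
        split_i = int(np.sum(best_assign == lo_cluster))
        split_i = min(max(split_i, 1), n - 1)
    admissible = [i for i in range(1, n) if xs_sorted[i] > xs_sorted[i - 1]]
    if split_i not in admissible:
        split_i = min(admissible, key=lambda i: abs(i - split_i))

    def loss_at(p: int) -> float:
        i = admissible[p]
        return segment_cost(xs_sorted, 0, i) + segment_cost(xs_sorted, i, n)

    if n <= 2000:
        # small inputs: scan every admissible split (the global optimum of
        # the 1-D two-cluster problem is a single split of the sorted data)
        losses = [loss_at(p) for p in range(len(admissible))]
        pos = int(np.argmin(losses))
        cur = losses[pos]
    else:
        # large inputs: local hill-climb from the iterative solution
        pos = admissible.index(split_i)
        cur = loss_at(pos)
        improved = True
        while improved:
            improved = False
            for q in (pos - 1, pos + 1):
                if 0 <= q < len(admissible):
                    l = loss_at(q)
                    if l < cur - 1e-12:
                        pos, cur, improved = q, l, True
                        break
    split_i = admissible[pos]

    thr_scaled = (xs_sorted[split_i - 1] + xs_sorted[split_i]) / 2
    threshold = float(thr_scaled * scale)
    labels = np.where(d >= threshold, "distant", "close")
    _, th_lo, q_lo = _cluster_cost(
        xs_sorted[:split_i],
        np.concatenate([[0.0], np.cumsum(xs_sorted[:split_i])]))
    _, th_hi, q_hi = _cluster_cost(
        xs_sorted[split_i:],
        np.concatenate([[0.0], np.cumsum(xs_sorted[split_i:])]))
    return ClassSplit(threshold_deg=threshold, labels=labels,
                      objective=float(cur),
                      centers_deg=(float(q_lo * scale), float(q_hi * scale)),
                      thetas=(th_lo, th_hi),
                      n_close=int((labels == "close").sum()),
                      n_distant=int((labels == "distant").sum()))


def apply_split(fixations: pd.DataFrame, split: ClassSplit,
                col: str = "dist_to_ship_deg"
                ) -> tuple[pd.DataFrame, list[int]]:
    """Label a fixation table with the fitted split.

    Returns the labeled table and the index list of rows whose distance was
    missing (left unlabeled).
    """
    out = fixations.copy()
    if len(out) == 0:
        out["cls"] = pd.Series(dtype=object)
        return out, []
    dist = out[col].to_numpy(float)
    missing = list(np.flatnonzero(~np.isfinite(dist)))
    labels = np.where(dist >= split.threshold_deg, "distant", "close")
    labels = labels.astype(object)
    for i in missing:
        labels[i] = None
    out["cls"] = labels
    return out, missing
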