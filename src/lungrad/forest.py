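"""Random survival forest and the 0-100 composite radiomic score.

An ensemble of binary survival trees grown on bootstrap samples.  Each split
maximizes the standardized two-sample log-rank statistic over the best
threshold of ``mtry`` randomly chosen features; terminal nodes store the
Nelson-Aalen cumulative hazard of their in-bag subjects.  A subject's risk is
the ensemble mortality: the leaf cumulative hazard summed over the training
event-time grid, averaged over trees.  Risks are rescaled to a 0-100 score
using the training min/max (clipped for out-of-range external subjects).

Default hyperparameters: 50 trees, minimum terminal-node size 10, maximum
depth 4, mtry = ceil(sqrt(p)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class RSFHyperParams:
    ntree: int = 50
    nodesize: int = 10          # min subjects per terminal node
    nodedepth: int = 4          # max depth (0 = root-only trees)
    mtry: int | None = None     # default ceil(sqrt(p))
    seed: int = 0

    def __post_init__(self):
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.nodesize < 1:
            raise ValueError("nodesize must be >= 1")
        if self.nodedepth < 0:
            raise ValueError("nodedepth must be >= 0")


def split_cohort(records: pd.DataFrame, seed: int = 0,
                 train_fraction: float = 2 / 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random train/test partition; train size = round(frac * n), half-up.

    Disjoint and exhaustive; deterministic given the seed.
    """
    n = len(records)
    if n < 3:
        raise ValueError("need at least 3 records to split")
    n_train = int(math.floor(train_fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return records.iloc[train_idx].copy(), records.iloc[test_idx].copy()


def logrank_split_stat(times, events, left: np.ndarray) -> float:
    """Standardized two-sample log-rank statistic |U| / sqrt(V).

    ``left`` is a boolean membership array for the first group.  Larger
    values indicate better separation of the survival experience.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    left = np.asarray(left, dtype=bool)
    if left.all() or not left.any():
        raise ValueError("both sides of the split must be nonempty")
    if events.sum() == 0:
        raise ValueError("no events: log-rank statistic undefined")
    et = np.unique(times[events == 1])
    at_risk = times[:, None] >= et[None, :]
    event_at = (times[:, None] == et[None, :]) & (events[:, None] == 1)
    n_j = at_risk.sum(axis=0).astype(float)
    d_j = event_at.sum(axis=0).astype(float)
    n1_j = at_risk[left].sum(axis=0).astype(float)
    d1_j = event_at[left].sum(axis=0).astype(float)
    u = float(np.sum(d1_j - d_j * n1_j / n_j))
    with np.errstate(invalid="ignore", divide="ignore"):
        v_terms = d_j * (n1_j / n_j) * (1 - n1_j / n_j) * (n_j - d_j) / (n_j - 1)
    v = float(np.nansum(np.where(n_j > 1, v_terms, 0.0)))
    if v <= 0:
        return 0.0
    return abs(u) / math.sqrt(v)


def _best_threshold(x, times, events, nodesize):
    """Best log-rank threshold for one feature, vectorized over candidates.

    Returns (stat, threshold) or (0.0, None) when no admissible split exists.
    Candidate thresholds are midpoints between consecutive distinct sorted
    values; both children must keep >= nodesize subjects.
    """
    order = np.argsort(x, kind="stable")
    xs, ts, es = x[order], times[order], events[order]
    m = xs.size
    et = np.unique(ts[es == 1])
    if et.size == 0:
        return 0.0, None
    at_risk = ts[:, None] >= et[None, :]
    event_at = (ts[:, None] == et[None, :]) & (es[:, None] == 1)
    n1 = np.cumsum(at_risk, axis=0).astype(float)       # (m, d): left group = first k+1
    d1 = np.cumsum(event_at, axis=0).astype(float)
    n_j = at_risk.sum(axis=0).astype(float)
    d_j = event_at.sum(axis=0).astype(float)

    k = np.arange(m - 1)                                 # split after position k
    valid = (xs[:-1] < xs[1:]) & (k + 1 >= nodesize) & (m - k - 1 >= nodesize)
    if not valid.any():
        return 0.0, None
    u = np.sum(d1[:-1] - d_j[None, :] * n1[:-1] / n_j[None, :], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = n1[:-1] / n_j[None, :]
        v_terms = d_j[None, :] * frac * (1 - frac) * (n_j[None, :] - d_j[None, :]) / (
            n_j[None, :] - 1
        )
        v_terms = np.where(n_j[None, :] > 1, v_terms, 0.0)
    v = np.nansum(v_terms, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where((v > 0) & valid, np.abs(u) / np.sqrt(v), 0.0)
    best = int(np.argmax(stat))
    if stat[best] <= 0:
        return 0.0, None
    threshold = (xs[best] + xs[best + 1]) / 2.0
    return float(stat[best]), threshold


@dataclass
class _Node:
    feature: int | None = None
    threshold: float | None = None
    left: "_Node | None" = None
    right: "_Node | None" = None
    mortality: float | None = None        # leaves only
    chf_times: np.ndarray | None = None
    chf_values: np.ndarray | None = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


def _nelson_aalen(times, events):
    """Step function (times, cumulative hazard) of the Nelson-Aalen estimator."""
    et = np.unique(times[events == 1])
    if et.size == 0:
        return et, np.zeros(0)
    n_j = (times[:, None] >= et[None, :]).sum(axis=0).astype(float)
    d_j = ((times[:, None] == et[None, :]) & (events[:, None] == 1)).sum(axis=0)
    return et, np.cumsum(d_j / n_j)


def _chf_at(chf_times, chf_values, grid):
    """Evaluate a right-continuous CHF step function on a time grid."""
    if chf_times.size == 0:
        return np.zeros(grid.size)
    idx = np.searchsorted(chf_times, grid, side="right") - 1
    out = np.where(idx >= 0, chf_values[np.clip(idx, 0, None)], 0.0)
    return out


@dataclass
class SurvivalForest:
    """Fitted ensemble; see module docstring for the model."""

    trees: list[_Node]
    feature_names: list[str]
    event_grid: np.ndarray
    hyper: RSFHyperParams
    train_risk_min: float = field(default=np.nan)
    train_risk_max: float = field(default=np.nan)


def fit_rsf(features: pd.DataFrame, times, events,
            hyper: RSFHyperParams = RSFHyperParams()) -> SurvivalForest:
    """Grow the forest on training data.

    ``features`` holds one column per predictor (non-numeric columns such as
    subject_id are ignored).  Raises when the training data carry no event or
    fewer than ``2 * nodesize`` subjects.
    """
    num = features.select_dtypes(include=[np.number])
    names = list(num.columns)
    X = num.to_numpy(dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n, p = X.shape
    if n < 2 * hyper.nodesize:
        raise ValueError(f"need >= {2 * hyper.nodesize} subjects, got {n}")
    if events.sum() == 0:
        raise ValueError("all-censored training data: cannot grow survival trees")
    mtry = hyper.mtry if hyper.mtry is not None else int(math.ceil(math.sqrt(p)))
    mtry = min(max(mtry, 1), p)
    rng = np.random.default_rng(hyper.seed)
    event_grid = np.unique(times[events == 1])

    def make_leaf(idx):
        ct, cv = _nelson_aalen(times[idx], events[idx])
        mortality = float(_chf_at(ct, cv, event_grid).sum())
        return _Node(mortality=mortality, chf_times=ct, chf_values=cv)

    def build(idx, depth):
        if (depth >= hyper.nodedepth or idx.size < 2 * hyper.nodesize
                or events[idx].sum() == 0):
            return make_leaf(idx)
        cand = rng.choice(p, size=mtry, replace=False)
        best_stat, best_feat, best_thr = 0.0, None, None
        for f in cand:
            stat, thr = _best_threshold(X[idx, f], times[idx], events[idx],
                                        hyper.nodesize)
            if thr is not None and stat > best_stat:
                best_stat, best_feat, best_thr = stat, int(f), thr
        if best_feat is None:
            return make_leaf(idx)
        go_left = X[idx, best_feat] <= best_thr
        node = _Node(feature=best_feat, threshold=best_thr)
        node.left = build(idx[go_left], depth + 1)
        node.right = build(idx[~go_left], depth + 1)
        return node

    trees = []
    for _ in range(hyper.ntree):
        boot = rng.integers(0, n, size=n)
        trees.append(build(np.asarray(boot), 0))

    forest = SurvivalForest(trees, names, event_grid, hyper)
    train_risk = predict_mortality(forest, features)
    forest.train_risk_min = float(train_risk.min())
    forest.train_risk_max = float(train_risk.max())
    return forest


def _traverse(node: _Node, x: np.ndarray) -> _Node:
    while not node.is_leaf:
        node = node.left if x[node.feature] <= node.threshold else node.right
    return node


def predict_mortality(forest: SurvivalForest, features: pd.DataFrame) -> np.ndarray:
    """Ensemble mortality (dimensionless risk), higher = higher death risk."""
    missing = [f for f in forest.feature_names if f not in features.columns]
    if missing:
        raise KeyError(f"missing feature column(s): {missing}")
    X = features[forest.feature_names].to_numpy(dtype=float)
    out = np.empty(X.shape[0])
    for i, x in enumerate(X):
        out[i] = float(np.mean([_traverse(t, x).mortality for t in forest.trees]))
    return out


def normalize_score(forest: SurvivalForest, risks) -> np.ndarray:
    """Rescale risks to the 0-100 score using training min/max; clip outside."""
    lo, hi = forest.train_risk_min, forest.train_risk_max
    if not np.isfinite(lo) or not np.isfinite(hi) or hi <= lo:
        raise ValueError("degenerate training risk range; cannot normalize")
    return np.clip(100.0 * (np.asarray(risks, dtype=float) - lo) / (hi - lo), 0.0, 100.0)


def forest_to_dict(forest: SurvivalForest) -> dict:
    """JSON-serializable representation of a fitted forest."""

    def node_dict(n: _Node):
        if n.is_leaf:
            return {
                "mortality": n.mortality,
                "chf_times": n.chf_times.tolist(),
                "chf_values": n.chf_values.tolist(),
            }
        return {
            "feature": forest.feature_names[n.feature],
            "threshold": n.threshold,
            "left": node_dict(n.left),
            "right": node_dict(n.right),
        }

    return {
        "feature_names": forest.feature_names,
        "event_grid": forest.event_grid.tolist(),
        "hyper": {
            "ntree": forest.hyper.ntree, "nodesize": forest.hyper.nodesize,
            "nodedepth": forest.hyper.nodedepth, "mtry": forest.hyper.mtry,
            "seed": forest.hyper.seed,
        },
        "train_risk_min": forest.train_risk_min,
        "train_risk_max": forest.train_risk_max,
        "trees": [node_dict(t) for t in forest.trees],
    }


def forest_from_dict(data: dict) -> SurvivalForest:
    names = data["feature_names"]

    def build(d):
        if "feature" in d:
            return _Node(feature=names.index(d["feature"]), threshold=d["threshold"],
                         left=build(d["left"]), right=build(d["right"]))
        return _Node(mortality=d["mortality"],
                     chf_times=np.asarray(d["chf_times"], dtype=float),
                     chf_values=np.asarray(d["chf_values"], dtype=float))

    forest = SurvivalForest(
        trees=[build(t) for t in data["trees"]],
        feature_names=list(names),
        event_grid=np.asarray(data["event_grid"], dtype=float),
        hyper=RSFHyperParams(**data["hyper"]),
        train_risk_min=data["train_risk_min"],
        train_risk_max=data["train_risk_max"],
    )
    return forest
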