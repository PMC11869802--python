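"""Gradient-boosted regression trees for a binary outcome, from scratch.

The ensemble is fit by stagewise gradient boosting on the Bernoulli deviance:
starting from the log-odds of the training prevalence, each iteration fits a
small regression tree to the gradient residuals ``y - p`` and adds a
learning-rate-scaled one-step Newton update per leaf to the additive log-odds
model. The defaults mirror the analysis this package reimplements: 1000
trees, learning rate 0.01, up to 10 splits per tree (permitting 10-way
interactions), a fresh random 50% predictor subset per tree, and a single
random 75% training subsample drawn before boosting.

Trees are grown best-first: among all current leaves, the split with the
maximal reduction in squared error of the residuals is taken, until the
split budget is exhausted or no split improves. Missing predictor values are
routed to the child that maximizes the split's improvement, and each split
stores that direction, so counterfactual prediction requires no imputation.

Relative influence (RI) of a predictor is its share of the total squared-error
improvement over all splits of all trees, scaled to sum to 100%. With p
predictors, a predictor whose influence were uniform noise would score
100/p %, the "randomness threshold" used to flag influential predictors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "BRTParams",
    "BRTModel",
    "RelativeInfluence",
    "fit_brt",
    "predict_raw",
    "predict_prob",
    "relative_influence",
]


class FitError(ValueError):
    """Raised when the data cannot support a fit (e.g. single-class outcome)."""


@dataclass(frozen=True)
class BRTParams:
    """Hyperparameters of the boosted ensemble.

    ``tree_complexity`` is the maximum number of splits per tree.
    ``predictor_fraction`` is the share of predictors available to each tree
    (drawn without replacement, fresh per tree); ``train_fraction`` is the
    share of respondents trained on, drawn without replacement. Following
    stochastic-gradient-boosting practice (the semantics of the R ``gbm``
    bag fraction, the reference BRT implementation), the training sample is
    redrawn per tree by default; ``bag_per_tree=False`` instead fixes a
    single subsample before boosting. ``min_samples_leaf`` (default 10, as
    in ``gbm``) stabilizes the Newton leaf updates on small leaves and
    ``leaf_clamp`` bounds |leaf value| to avoid divergence on near-pure
    leaves (set ``None`` to disable either).
    """

    n_trees: int = 1000
    learning_rate: float = 0.01
    tree_complexity: int = 10
    predictor_fraction: float = 0.5
    train_fraction: float = 0.75
    min_samples_leaf: int = 10
    leaf_clamp: float | None = 4.0
    seed: int = 0
    #: redraw the training sample per tree (stochastic gradient boosting);
    #: False fixes one subsample up front and leaves a 25% holdout
    bag_per_tree: bool = True
    #: redraw the predictor subset at every split instead of once per tree
    features_per_split: bool = False

    def __post_init__(self):
        if not (0.0 < self.predictor_fraction <= 1.0):
            raise ValueError("predictor_fraction must be in (0, 1]")
        if not (0.0 < self.train_fraction <= 1.0):
            raise ValueError("train_fraction must be in (0, 1]")
        if self.n_trees < 0 or self.tree_complexity < 1:
            raise ValueError("n_trees must be >= 0 and tree_complexity >= 1")


@dataclass
class BRTModel:
    """A fitted additive ensemble of regression trees on the log-odds scale."""

    intercept: float
    trees: list
    params: BRTParams
    predictor_names: list
    train_index: np.ndarray
    train_deviance: np.ndarray
    holdout_index: np.ndarray
    holdout_deviance: float | None
    split_gains: dict  # predictor name -> summed squared-error improvement

    @property
    def n_predictors(self) -> int:
        return len(self.predictor_names)

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "intercept": self.intercept,
            "trees": self.trees,
            "params": asdict(self.params),
            "predictor_names": list(self.predictor_names),
            "train_index": np.asarray(self.train_index).tolist(),
            "train_deviance": np.asarray(self.train_deviance).tolist(),
            "holdout_index": np.asarray(self.holdout_index).tolist(),
            "holdout_deviance": self.holdout_deviance,
            "split_gains": self.split_gains,
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "BRTModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            intercept=payload["intercept"],
            trees=payload["trees"],
            params=BRTParams(**payload["params"]),
            predictor_names=list(payload["predictor_names"]),
            train_index=np.asarray(payload["train_index"], dtype=int),
            train_deviance=np.asarray(payload["train_deviance"], dtype=float),
            holdout_index=np.asarray(payload["holdout_index"], dtype=int),
            holdout_deviance=payload["holdout_deviance"],
            split_gains={k: float(v) for k, v in payload["split_gains"].items()},
        )


@dataclass
class RelativeInfluence:
    """Per-predictor relative influence, in percent (sums to 100)."""

    per_predictor: pd.Series
    threshold: float

    def summary_frame(self) -> pd.DataFrame:
        out = self.per_predictor.sort_values(ascending=False).to_frame("relative_influence_pct")
        out["above_threshold"] = out["relative_influence_pct"] > self.threshold
        return out


def _as_matrix(X, predictor_names=None):
    if isinstance(X, pd.DataFrame):
        if predictor_names is not None:
            missing = [c for c in predictor_names if c not in X.columns]
            extra = [c for c in X.columns if c not in predictor_names]
            if missing or extra:
                raise ValueError(
                    f"predictor columns mismatch; missing={missing}, extra={extra}"
                )
            X = X[list(predictor_names)]
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be two-dimensional")
    names = (
        list(predictor_names)
        if predictor_names is not None
        else [f"x{j}" for j in range(arr.shape[1])]
    )
    return arr, names


def _mean_bernoulli_deviance(y, F):
    # -2/n * sum(y*F - log(1 + e^F)), computed stably
    return float(2.0 * np.mean(np.logaddexp(0.0, F) - y * F))


def _candidate_splits(Xtr):
    """Per-feature candidate thresholds (midpoints of observed unique values)."""
    feat_of, thr = [], []
    for j in range(Xtr.shape[1]):
        v = Xtr[:, j]
        u = np.unique(v[~np.isnan(v)])
        if u.size < 2:
            continue
        mids = (u[:-1] + u[1:]) / 2.0
        feat_of.extend([j] * mids.size)
        thr.extend(mids.tolist())
    return np.asarray(feat_of, dtype=int), np.asarray(thr, dtype=float)


class _LeafCandidate:
    __slots__ = ("rows", "gain", "cand", "miss_left", "order")

    def __init__(self, rows, gain, cand, miss_left, order):
        self.rows = rows
        self.gain = gain
        self.cand = cand
        self.miss_left = miss_left
        self.order = order


def fit_brt(X, y, params: BRTParams | None = None, predictor_names=None) -> BRTModel:
    """Fit the boosted ensemble.

    ``X`` is an (n, p) table of coded predictors (NaN marks missing);
    ``y`` is the binary outcome. Deterministic given ``params.seed``
    (Philox counter-based generator: the training subsample is drawn first,
    then one predictor subset per tree).
    """
    if params is None:
        params = BRTParams()
    Xa, names = _as_matrix(X, predictor_names)
    ya = np.asarray(y, dtype=float)
    if Xa.shape[0] != ya.shape[0]:
        raise ValueError("X and y have different lengths")
    if np.isnan(ya).any():
        raise FitError("outcome contains missing values; drop those rows first")
    if not np.isin(ya, (0.0, 1.0)).all():
        raise FitError("outcome must be binary 0/1")
    if np.isinf(Xa).any():
        raise FitError("predictors contain non-finite values")

    n, p = Xa.shape
    rng = np.random.Generator(np.random.Philox(key=params.seed))

    n_tr = max(1, int(round(params.train_fraction * n)))
    if params.train_fraction < 1.0 and not params.bag_per_tree:
        train_idx = np.sort(rng.choice(n, size=n_tr, replace=False))
    else:
        train_idx = np.arange(n)
    holdout_idx = np.setdiff1d(np.arange(n), train_idx)

    ytr_full = ya[train_idx]
    if ytr_full.min() == ytr_full.max():
        raise FitError("outcome is single-class on the training split")

    pbar = ytr_full.mean()
    intercept = float(np.log(pbar / (1.0 - pbar)))

    Xtr = Xa[train_idx]
    feat_of, thr = _candidate_splits(Xtr)
    # Left-indicator (x <= thr, missing excluded) and missing-indicator
    # matrices over the training rows; split statistics come from matmuls.
    with np.errstate(invalid="ignore"):
        L = (Xtr[:, feat_of] <= thr[None, :]).astype(np.float32)
    M = np.isnan(Xtr)
    L[M[:, feat_of]] = 0.0
    Mf = M.astype(np.float32)

    n_sub = max(1, int(np.floor(params.predictor_fraction * p + 0.5)))
    min_leaf = max(1, int(params.min_samples_leaf))

    F_tr = np.full(len(train_idx), intercept)
    trees = []
    dev_trace = np.empty(params.n_trees)
    split_gains = {nm: 0.0 for nm in names}

    def best_split(rows, r, cand_cols):
        """Best candidate split of a leaf: squared-error reduction on residuals."""
        n_node = rows.size
        if n_node < 2 * min_leaf:
            return None
        if params.features_per_split:
            sub = np.sort(rng.choice(p, size=n_sub, replace=False))
            cand_cols = np.flatnonzero(np.isin(feat_of, sub))
            if cand_cols.size == 0:
                return None
        rr = r[rows]
        S = rr.sum()
        A = L[rows][:, cand_cols]
        B = Mf[rows]
        s_l = rr @ A
        n_l = A.sum(axis=0)
        s_mf = rr @ B
        n_mf = B.sum(axis=0)
        fsel = feat_of[cand_cols]
        s_m = s_mf[fsel]
        n_m = n_mf[fsel]
        s_r = (S - s_m) - s_l
        n_r = (n_node - n_m) - n_l
        base = S * S / n_node

        def gain_of(sl, nl, sr, nr):
            with np.errstate(divide="ignore", invalid="ignore"):
                g = np.where(
                    (nl >= min_leaf) & (nr >= min_leaf),
                    np.where(nl > 0, sl * sl / np.maximum(nl, 1e-12), 0.0)
                    + np.where(nr > 0, sr * sr / np.maximum(nr, 1e-12), 0.0)
                    - base,
                    -np.inf,
                )
            return g

        g_left = gain_of(s_l + s_m, n_l + n_m, s_r, n_r)  # missing -> left
        g_right = gain_of(s_l, n_l, s_r + s_m, n_r + n_m)  # missing -> right
        miss_left = g_left >= g_right
        g = np.where(miss_left, g_left, g_right)
        k = int(np.argmax(g))
        if not np.isfinite(g[k]) or g[k] <= 1e-12:
            return None
        return float(g[k]), int(cand_cols[k]), bool(miss_left[k])

    order_counter = 0
    for m in range(params.n_trees):
        if params.bag_per_tree and params.train_fraction < 1.0:
            root_rows = np.sort(rng.choice(n, size=n_tr, replace=False))
        else:
            root_rows = np.arange(len(train_idx))
        if params.features_per_split:
            cand_cols = None
        else:
            sub = np.sort(rng.choice(p, size=n_sub, replace=False))
            cand_cols = np.flatnonzero(np.isin(feat_of, sub))
            if cand_cols.size == 0:
                trees.append({"value": 0.0})
                dev_trace[m] = _mean_bernoulli_deviance(ytr_full, F_tr)
                continue

        prob = 1.0 / (1.0 + np.exp(-F_tr))
        r = ytr_full - prob
        h = prob * (1.0 - prob)

        leaves = []
        found = best_split(root_rows, r, cand_cols)
        # Each leaf candidate carries its precomputed best split; best-first
        # growth repeatedly splits the leaf with the largest improvement.
        root = _LeafCandidate(root_rows, *(found if found else (-np.inf, -1, True)), order_counter)
        order_counter += 1
        leaves.append(root)
        node_of = {id(root): {}}
        tree = node_of[id(root)]

        for _ in range(params.tree_complexity):
            best = None
            for lf in leaves:
                if lf.gain > 0 and (best is None or lf.gain > best.gain):
                    best = lf
            if best is None:
                break
            leaves.remove(best)
            j = int(feat_of[best.cand])
            t = float(thr[best.cand])
            split_gains[names[j]] += best.gain

            xv = Xtr[best.rows, j]
            isna = np.isnan(xv)
            go_left = (xv <= t) & ~isna
            if best.miss_left:
                go_left = go_left | isna
            rows_l = best.rows[go_left]
            rows_r = best.rows[~go_left]

            node = node_of[id(best)]
            node["feature"] = j
            node["threshold"] = t
            node["missing_left"] = best.miss_left
            for key, rows_c in (("left", rows_l), ("right", rows_r)):
                child_found = best_split(rows_c, r, cand_cols)
                child = _LeafCandidate(
                    rows_c, *(child_found if child_found else (-np.inf, -1, True)), order_counter
                )
                order_counter += 1
                node[key] = {}
                node_of[id(child)] = node[key]
                leaves.append(child)

        # Newton leaf values on the Bernoulli loss: sum(r) / sum(p(1-p)).
        for lf in leaves:
            denom = h[lf.rows].sum()
            gamma = 0.0 if denom <= 0 else float(r[lf.rows].sum() / denom)
            if params.leaf_clamp is not None:
                gamma = float(np.clip(gamma, -params.leaf_clamp, params.leaf_clamp))
            node_of[id(lf)]["value"] = gamma
            if not params.bag_per_tree:
                F_tr[lf.rows] += params.learning_rate * gamma
        if params.bag_per_tree:
            # out-of-bag training rows also move: apply the tree everywhere
            F_tr += _ensemble_raw([tree], Xtr, params.learning_rate)

        trees.append(tree)
        dev_trace[m] = _mean_bernoulli_deviance(ytr_full, F_tr)

    holdout_dev = None
    if holdout_idx.size:
        F_hold = intercept + _ensemble_raw(trees, Xa[holdout_idx], params.learning_rate)
        holdout_dev = _mean_bernoulli_deviance(ya[holdout_idx], F_hold)

    return BRTModel(
        intercept=intercept,
        trees=trees,
        params=params,
        predictor_names=names,
        train_index=train_idx,
        train_deviance=dev_trace,
        holdout_index=holdout_idx,
        holdout_deviance=holdout_dev,
        split_gains=split_gains,
    )


def _tree_raw(node, Xa, out, rows):
    if "value" in node and "feature" not in node:
        out[rows] += node["value"]
        return
    xv = Xa[rows, node["feature"]]
    isna = np.isnan(xv)
    go_left = (xv <= node["threshold"]) & ~isna
    if node["missing_left"]:
        go_left = go_left | isna
    _tree_raw(node["left"], Xa, out, rows[go_left])
    _tree_raw(node["right"], Xa, out, rows[~go_left])


def _ensemble_raw(trees, Xa, learning_rate):
    out = np.zeros(Xa.shape[0])
    rows = np.arange(Xa.shape[0])
    for tree in trees:
        _tree_raw(tree, Xa, out, rows)
    return learning_rate * out


def predict_raw(model: BRTModel, X) -> np.ndarray:
    """Additive log-odds predictions."""
    Xa, _ = _as_matrix(X, model.predictor_names)
    return model.intercept + _ensemble_raw(trees=model.trees, Xa=Xa,
                                           learning_rate=model.params.learning_rate)


def predict_prob(model: BRTModel, X) -> np.ndarray:
    """Predicted probabilities of the outcome, in (0, 1)."""
    return 1.0 / (1.0 + np.exp(-predict_raw(model, X)))


def relative_influence(model: BRTModel) -> RelativeInfluence:
    """Relative influence of each predictor, scaled to sum to 100%.

    A predictor's influence is the sum of squared-error improvements of all
    splits made on it across all trees; the randomness threshold is 100/p.
    """
    if not model.trees:
        raise ValueError("model has no trees; fit it first")
    gains = pd.Series(model.split_gains, dtype=float).reindex(model.predictor_names)
    total = gains.sum()
    if total <= 0:
        ri = pd.Series(0.0, index=gains.index)
    else:
        ri = 100.0 * gains / total
    return RelativeInfluence(per_predictor=ri, threshold=100.0 / model.n_predictors)
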