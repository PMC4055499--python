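"""Representative learners and evaluation protocols.

Two models cover the classification and regression arms of the analysis:

* a randomized decision tree for two-group classification — at each node a
  random subset of ceil(sqrt(d)) features is considered and the best
  information-gain split over midpoints of sorted unique values is taken;
  the tree grows until pure (or fewer than 2 samples), so full-dataset
  accuracy on consistent data is 1;
* an entropic instance-based (memory-based) regressor for phenotype
  prediction — a Gaussian-kernel weighted average over stored training
  instances on variance-normalized features, with a per-query bandwidth set
  so the effective number of neighbors sum(w)/max(w) matches a blend
  parameter (default 5).

Evaluation protocols: full-dataset (train = test), stratified shuffled
k-fold (k in 2..10), and percentage split (10%..90% training); all are
seed-deterministic. Margin curves summarize classifier confidence: the
margin of an instance is the probability of its true class minus the
largest other-class probability, and the curve is the cumulative instance
count over sorted margins.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# random tree classifier

@dataclass
class _Node:
    feature: int = -1
    threshold: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None
    counts: np.ndarray | None = None   # leaf class counts


def _entropy(counts: np.ndarray) -> float:
    tot = counts.sum()
    if tot == 0:
        return 0.0
    p = counts[counts > 0] / tot
    return float(-(p * np.log2(p)).sum())


class RandomTreeClassifier:
    """Single decision tree with random feature subsets at each node."""

    def __init__(self, seed: int = 0):
        self.seed = seed
        self.root: _Node | None = None
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RandomTreeClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, yi = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("training data contains a single class")
        rng = np.random.default_rng(self.seed)
        self._k = max(1, math.ceil(math.sqrt(X.shape[1])))
        self.root = self._grow(X, yi, rng)
        return self

    def _grow(self, X: np.ndarray, yi: np.ndarray, rng: np.random.Generator) -> _Node:
        counts = np.bincount(yi, minlength=self.classes_.size).astype(float)
        if len(yi) < 2 or np.count_nonzero(counts) == 1:
            return _Node(counts=counts)
        parent_h = _entropy(counts)
        feats = rng.choice(X.shape[1], size=min(self._k, X.shape[1]), replace=False)
        # prefer the best information gain; a zero-gain split is still taken
        # when the node is impure (XOR-like interactions need it), and any
        # candidate split leaves both children non-empty so growth terminates
        best_gain, best_feat, best_thr = -1.0, -1, 0.0
        for f in feats:
            vals = np.unique(X[:, f])
            if vals.size < 2:
                continue
            for thr in (vals[:-1] + vals[1:]) / 2.0:
                mask = X[:, f] <= thr
                lc = np.bincount(yi[mask], minlength=self.classes_.size).astype(float)
                rc = counts - lc
                nl, nr = lc.sum(), rc.sum()
                gain = parent_h - (nl * _entropy(lc) + nr * _entropy(rc)) / len(yi)
                if gain > best_gain + 1e-12:
                    best_gain, best_feat, best_thr = gain, int(f), float(thr)
        if best_feat < 0:   # no candidate split at all (all-duplicate x)
            return _Node(counts=counts)
        mask = X[:, best_feat] <= best_thr
        return _Node(feature=best_feat, threshold=best_thr,
                     left=self._grow(X[mask], yi[mask], rng),
                     right=self._grow(X[~mask], yi[~mask], rng))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], self.classes_.size))
        for i, x in enumerate(X):
            node = self.root
            while node.counts is None:
                node = node.left if x[node.feature] <= node.threshold else node.right
            out[i] = node.counts / node.counts.sum()
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


def fit_random_tree(X: np.ndarray, y: np.ndarray, seed: int = 0) -> RandomTreeClassifier:
    return RandomTreeClassifier(seed=seed).fit(X, y)


# ---------------------------------------------------------------------------
# evaluation protocols

@dataclass
class EvalReport:
    protocol: str
    param: float | int | None
    accuracy: float
    fold_accuracies: list[float]
    predictions: pd.DataFrame       # columns: true, predicted, proba per class
    seed: int


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Round-robin assignment of shuffled within-class indices to k folds."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.array(sorted(f)) for f in folds]


def evaluate(X: np.ndarray, y: np.ndarray, protocol: str,
             param: float | int | None = None, seed: int = 0,
             fit=fit_random_tree) -> EvalReport:
    """Run a classifier under one of the three evaluation protocols."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    classes = np.unique(y)
    rng = np.random.default_rng(seed)

    def _proba_frame(true, pred, proba, index) -> pd.DataFrame:
        df = pd.DataFrame({"true": true, "predicted": pred}, index=index)
        for j, c in enumerate(classes):
            df[f"p_{c}"] = proba[:, j]
        return df

    if protocol == "full_dataset":
        model = fit(X, y, seed=int(rng.integers(2**31)))
        proba = model.predict_proba(X)
        pred = model.classes_[proba.argmax(axis=1)]
        acc = float((pred == y).mean())
        return EvalReport("full_dataset", None, acc, [acc],
                          _proba_frame(y, pred, proba, np.arange(n)), seed)

    if protocol == "kfold":
        k = int(param)
        if not 2 <= k <= 10:
            raise ValueError("fold count must lie in [2, 10]")
        if min(np.bincount(np.unique(y, return_inverse=True)[1])) < k:
            # one reshuffle cannot fix a class smaller than k
            raise ValueError("a fold would miss a class: too few per-class samples")
        folds = _stratified_folds(y, k, rng)
        accs, parts = [], []
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            model = fit(X[train_idx], y[train_idx], seed=int(rng.integers(2**31)))
            proba = model.predict_proba(X[test_idx])
            pred = model.classes_[proba.argmax(axis=1)]
            accs.append(float((pred == y[test_idx]).mean()))
            parts.append(_proba_frame(y[test_idx], pred, proba, test_idx))
        preds = pd.concat(parts).sort_index()
        acc = float((preds["predicted"] == preds["true"]).mean())
        return EvalReport("kfold", k, acc, accs, preds, seed)

    if protocol == "percentage_split":
        frac = float(param)
        if not 0.1 <= frac <= 0.9:
            raise ValueError("split fraction must lie in [0.1, 0.9]")
        for attempt in range(2):
            perm = rng.permutation(n)
            n_train = int(np.floor(frac * n))
            train_idx, test_idx = perm[:n_train], perm[n_train:]
            ok = (np.unique(y[train_idx]).size == classes.size
                  and test_idx.size > 0)
            if ok:
                break
        if not ok:
            raise ValueError("train split misses a class after one reshuffle")
        model = fit(X[train_idx], y[train_idx], seed=int(rng.integers(2**31)))
        proba = model.predict_proba(X[test_idx])
        pred = model.classes_[proba.argmax(axis=1)]
        acc = float((pred == y[test_idx]).mean())
        return EvalReport("percentage_split", frac, acc, [acc],
                          _proba_frame(y[test_idx], pred, proba, test_idx), seed)

    raise ValueError(f"unknown protocol {protocol!r}")


@dataclass
class MarginCurve:
    margins: np.ndarray            # sorted ascending, in [-1, 1]
    cumulative: np.ndarray         # instances with margin <= value

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"margin": self.margins, "cumulative": self.cumulative})


def margin_curve(model, X: np.ndarray, y: np.ndarray) -> MarginCurve:
    """Cumulative distribution of per-instance classification margins."""
    proba = model.predict_proba(np.asarray(X, dtype=float))
    y = np.asarray(y)
    cls_index = {c: j for j, c in enumerate(model.classes_)}
    p_true = proba[np.arange(len(y)), [cls_index[c] for c in y]]
    masked = proba.copy()
    masked[np.arange(len(y)), [cls_index[c] for c in y]] = -np.inf
    p_other = masked.max(axis=1)
    p_other[np.isinf(p_other)] = 0.0   # single-class edge
    margins = np.sort(p_true - p_other)
    return MarginCurve(margins=margins, cumulative=np.arange(1, len(y) + 1))


# ---------------------------------------------------------------------------
# instance-based (K*-style) regressor

class InstanceRegressor:
    """Gaussian-kernel memory-based regressor with effective-neighbor bandwidth.

    Prediction at x is sum(w_i y_i)/sum(w_i) with
    w_i = exp(-||x - x_i||^2 / (2 h^2)) on variance-normalized features;
    h is solved per query so that sum(w)/max(w) is approximately ``blend``.
    """

    def __init__(self, blend: float = 5.0):
        if blend < 1:
            raise ValueError("blend must be >= 1")
        self.blend = blend

    def fit(self, X: np.ndarray, y: np.ndarray) -> "InstanceRegressor":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if len(y) == 0:
            raise ValueError("empty training set")
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        self._sd = sd
        self._X = (X - self._mu) / self._sd
        self._y = y
        return self

    def _weights(self, d2: np.ndarray) -> np.ndarray:
        target = min(self.blend, len(self._y))
        pos = d2[d2 > 0]
        if pos.size == 0 or target <= np.count_nonzero(d2 == 0):
            w = np.zeros_like(d2)
            w[d2 == 0] = 1.0
            return w if w.any() else np.ones_like(d2)

        # weights shifted by the minimum distance: w/max(w) analytically,
        # immune to exp underflow; the shift cancels in the weighted mean
        shifted = d2 - d2.min()

        def weights_at(log_h: float) -> np.ndarray:
            return np.exp(-shifted / (2.0 * np.exp(2 * log_h)))

        scale = float(np.sqrt(np.median(pos)))
        lo, hi = np.log(scale) - 20.0, np.log(scale) + 20.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if float(weights_at(mid).sum()) < target:
                lo = mid
            else:
                hi = mid
        return weights_at(hi)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xn = (X - self._mu) / self._sd
        out = np.empty(len(Xn))
        for i, x in enumerate(Xn):
            d2 = ((self._X - x) ** 2).sum(axis=1)
            w = self._weights(d2)
            tot = w.sum()
            out[i] = float((w * self._y).sum() / tot) if tot > 0 else float(self._y.mean())
        return out


def fit_instance_regressor(X: np.ndarray, y: np.ndarray, blend: float = 5.0) -> InstanceRegressor:
    return InstanceRegressor(blend=blend).fit(X, y)


def predict_phenotype(table, selection, score: "pd.Series | np.ndarray",
                      protocol: str = "full_dataset", seed: int = 0,
                      blend: float = 5.0):
    """Instance-based regression of a clinical score on selected features.

    Returns (fitted values, Pearson r, least-squares slope of observed on
    fitted). Subjects with a missing score are dropped.
    """
    feats = table.data[selection.selected]
    y = pd.Series(np.asarray(score, dtype=float), index=feats.index)
    ok = y.notna()
    if int(ok.sum()) < 2:
        raise ValueError("need at least 2 scored subjects")
    X = feats.loc[ok].to_numpy(dtype=float)
    yy = y[ok].to_numpy(dtype=float)
    if np.ptp(yy) == 0:
        raise ValueError("score is constant")

    if protocol == "full_dataset":
        fitted = fit_instance_regressor(X, yy, blend=blend).predict(X)
    elif protocol == "kfold":
        rng = np.random.default_rng(seed)
        k = 10
        perm = rng.permutation(len(yy))
        fitted = np.empty(len(yy))
        for f in range(k):
            test = perm[f::k]
            train = np.setdiff1d(np.arange(len(yy)), test)
            model = fit_instance_regressor(X[train], yy[train], blend=blend)
            fitted[test] = model.predict(X[test])
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    if np.ptp(fitted) == 0:
        r, slope = float("nan"), float("nan")
    else:
        r = float(np.corrcoef(fitted, yy)[0, 1])
        slope = float(np.cov(fitted, yy, ddof=0)[0, 1] / np.var(fitted))
    return fitted, r, slope
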