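"""Feature integration: the canonical 22-feature table, PCA component
counting, and mRMR feature selection.

The table holds, per subject: 9 supratentorially normalized subcortical
volumes (bilateral caudate, thalamus, pallidum, hippocampus, cerebellum),
8 seed-connectivity summaries (N and Z for caudate, IFG pars opercularis,
IFG pars triangularis and DMN seeds), 3 seed-set fALFF means, and the 2
global VMHC summaries (N, mean Z).

The number of features to select is chosen by singular value decomposition
of the covariance matrix after variance normalization (equivalently,
correlation-matrix PCA): the minimal component count containing 95% or 99%
of the variance. Selection itself is greedy mRMR on three-bin discretized
features, maximizing plug-in mutual information with the class label minus
the mean mutual information with already-selected features (the difference
criterion; a quotient variant is available).
"""
from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import (DEFAULT_Z_THRESHOLD, SeedSummary, falff,
                       seed_connectivity_map, summarize_seed_map, vmhc)
from .stats import normalize_volume

SEED_FEATURES = ("caudate", "ifg_opercularis", "ifg_triangularis", "dmn")
FALFF_SEEDS = ("caudate", "ifg_opercularis", "ifg_triangularis")

CANONICAL_FEATURES: tuple[str, ...] = (
    "vol_caudate_L", "vol_caudate_R",
    "vol_thalamus_L", "vol_thalamus_R",
    "vol_pallidum_L", "vol_pallidum_R",
    "vol_hippocampus_L", "vol_hippocampus_R",
    "vol_cerebellum",
    "fc_caudate_N", "fc_caudate_Z",
    "fc_ifg_opercularis_N", "fc_ifg_opercularis_Z",
    "fc_ifg_triangularis_N", "fc_ifg_triangularis_Z",
    "fc_dmn_N", "fc_dmn_Z",
    "falff_caudate", "falff_ifg_opercularis", "falff_ifg_triangularis",
    "vmhc_N", "vmhc_Z",
)


@dataclass
class FeatureTable:
    """Subjects x 22 named quantitative imaging features."""

    data: pd.DataFrame                  # index: subject ids
    groups: pd.Series                   # subject id -> group label

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise ValueError(f"missing values in feature column(s) {bad}")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate feature columns")

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def write(self, path: str | Path) -> Path:
        out = self.data.copy()
        out.insert(0, "group", self.groups)
        out.to_csv(Path(path), sep="\t")
        return Path(path)

    @classmethod
    def read(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        groups = df.pop("group")
        return cls(df, groups)


@dataclass
class SelectionResult:
    selected: list[str]
    relevance: list[float]
    redundancy: list[float]
    criterion_values: list[float]
    k: int
    criterion: str = "difference"
    variance_threshold: float | None = None

    def to_json(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps({
            "selected": self.selected, "relevance": self.relevance,
            "redundancy": self.redundancy,
            "criterion_values": self.criterion_values, "k": self.k,
            "criterion": self.criterion,
            "variance_threshold": self.variance_threshold}, indent=1))
        return Path(path)

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# assembly

def assemble_features(cohort, seed_summaries: dict, falff_means: dict,
                      vmhc_summaries: dict, volumes: dict) -> FeatureTable:
    """Build the canonical table from per-subject feature sources.

    ``seed_summaries``: subject id -> {seed name -> SeedSummary};
    ``falff_means``: subject id -> {seed name -> float};
    ``vmhc_summaries``: subject id -> SeedSummary;
    ``volumes``: subject id -> {canonical volume name -> normalized volume}.
    """
    ids = [s.id for s in cohort.subjects]
    for name, src in (("seed summaries", seed_summaries), ("fALFF", falff_means),
                      ("VMHC", vmhc_summaries), ("volumes", volumes)):
        missing = [i for i in ids if i not in src]
        if missing:
            raise KeyError(f"{name} missing for subject(s) {missing[:5]}")

    rows = []
    for sid in ids:
        row: dict[str, float] = {}
        for vn in ("caudate_L", "caudate_R", "thalamus_L", "thalamus_R",
                   "pallidum_L", "pallidum_R", "hippocampus_L",
                   "hippocampus_R", "cerebellum"):
            if vn in volumes[sid]:
                row[f"vol_{vn}"] = float(volumes[sid][vn])
        for seed in SEED_FEATURES:
            if seed in seed_summaries[sid]:
                summ = seed_summaries[sid][seed]
                row[f"fc_{seed}_N"] = float(summ.n_suprathreshold)
                row[f"fc_{seed}_Z"] = float(summ.mean_z)
        for seed in FALFF_SEEDS:
            if seed in falff_means[sid]:
                row[f"falff_{seed}"] = float(falff_means[sid][seed])
        row["vmhc_N"] = float(vmhc_summaries[sid].n_suprathreshold)
        row["vmhc_Z"] = float(vmhc_summaries[sid].mean_z)
        rows.append(row)

    df = pd.DataFrame(rows, index=ids)
    missing_cols = [c for c in CANONICAL_FEATURES if c not in df.columns]
    if missing_cols:
        raise KeyError(f"feature source(s) incomplete; missing columns: {missing_cols}")
    df = df[list(CANONICAL_FEATURES)]
    groups = pd.Series({s.id: s.group for s in cohort.subjects}, name="group")[ids]
    return FeatureTable(df, groups)


def compute_feature_table(cohort, z_threshold: float = DEFAULT_Z_THRESHOLD) -> FeatureTable:
    """Extract every feature source from a simulated cohort and assemble."""
    tr = cohort.config.tr_seconds
    seed_summaries: dict[str, dict[str, SeedSummary]] = {}
    falff_means: dict[str, dict[str, float]] = {}
    vmhc_summaries: dict[str, SeedSummary] = {}
    volumes: dict[str, dict[str, float]] = {}
    for s in cohort.subjects:
        if s.timeseries is None:
            raise ValueError(f"subject {s.id} has no time series")
        ts = s.timeseries
        seed_summaries[s.id] = {
            name: summarize_seed_map(seed_connectivity_map(ts, idxs),
                                     z_threshold, seed_name=name)
            for name, idxs in cohort.seed_sets.items()}
        fa = falff(ts, tr=tr).values
        falff_means[s.id] = {name: float(fa[list(cohort.seed_sets[name])].mean())
                             for name in FALFF_SEEDS}
        vmhc_summaries[s.id] = vmhc(ts, cohort.homotopic_pairs, z_threshold)
        volumes[s.id] = {name: normalize_volume(s.volumes[name], s.supratentorial)
                         for name in s.volumes}
    return assemble_features(cohort, seed_summaries, falff_means,
                             vmhc_summaries, volumes)


# ---------------------------------------------------------------------------
# normalization and component counting

def variance_normalize(t: FeatureTable) -> FeatureTable:
    """Column-wise mean 0 / variance 1 (population n denominator)."""
    sd = t.data.std(axis=0, ddof=0)
    dead = sd[sd == 0].index.tolist()
    if dead:
        raise ValueError(f"zero-variance feature column(s): {dead}")
    return FeatureTable((t.data - t.data.mean(axis=0)) / sd, t.groups)


def component_count(t: FeatureTable, threshold: float) -> int:
    """Minimal k with the top-k covariance eigenvalues holding >= threshold
    of the total variance (eigenvalues sorted descending)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if t.data.shape[0] == 0:
        raise ValueError("empty feature table")
    cov = np.cov(t.data.to_numpy(dtype=float), rowvar=False, ddof=0)
    lam = np.linalg.eigvalsh(np.atleast_2d(cov))[::-1]
    lam = np.clip(lam, 0.0, None)
    frac = np.cumsum(lam) / lam.sum()
    return int(np.searchsorted(frac, threshold - 1e-12) + 1)


# ---------------------------------------------------------------------------
# mutual information and mRMR

def discretize(x: np.ndarray) -> np.ndarray:
    """Three-bin discretization at mu +/- sigma (the vector's own moments)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values cannot be discretized")
    mu, sd = x.mean(), x.std(ddof=0)
    if sd == 0:
        raise ValueError("constant vector cannot be discretized")
    out = np.ones(x.shape, dtype=int)
    out[x <= mu - sd] = 0
    out[x >= mu + sd] = 2
    return out


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in MI (nats) from the joint contingency table of two discrete vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    n = x.size
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (px @ py)[nz])))


def mrmr_select(t: FeatureTable, labels: "pd.Series | np.ndarray", k: int,
                criterion: str = "difference",
                variance_threshold: float | None = None) -> SelectionResult:
    """Greedy minimum-redundancy maximum-relevance selection.

    Step 1 takes the feature with maximal MI against the binary labels;
    step j maximizes relevance minus (difference) or divided by (quotient)
    the mean MI with already-selected features. Ties break toward the lower
    canonical column index.
    """
    if criterion not in ("difference", "quotient"):
        raise ValueError(f"unknown criterion {criterion!r}")
    cols = t.feature_names
    if k > len(cols):
        raise ValueError(f"k={k} exceeds {len(cols)} features")
    y = np.asarray(labels)
    if np.unique(y).size != 2:
        raise ValueError("labels must be binary")
    disc = {c: discretize(t.data[c].to_numpy()) for c in cols}
    rel = {c: mutual_information(disc[c], y) for c in cols}

    selected: list[str] = []
    relevance, redundancy, crit_vals = [], [], []
    pair_mi: dict[tuple[str, str], float] = {}

    def red(c: str) -> float:
        if not selected:
            return 0.0
        tot = 0.0
        for s in selected:
            key = (min(c, s), max(c, s))
            if key not in pair_mi:
                pair_mi[key] = mutual_information(disc[c], disc[s])
            tot += pair_mi[key]
        return tot / len(selected)

    for _ in range(k):
        best, best_val, best_red = None, -np.inf, 0.0
        for c in cols:                     # canonical order = tie-break order
            if c in selected:
                continue
            r = red(c)
            if criterion == "difference":
                val = rel[c] - r
            else:
                val = rel[c] / (r + 1e-12)
            if val > best_val:
                best, best_val, best_red = c, val, r
        selected.append(best)
        relevance.append(rel[best])
        redundancy.append(best_red)
        crit_vals.append(best_val)
    return SelectionResult(selected, relevance, redundancy, crit_vals, k,
                           criterion=criterion,
                           variance_threshold=variance_threshold)


def select_by_variance(t: FeatureTable, labels, threshold: float = 0.95,
                       criterion: str = "difference") -> SelectionResult:
    """PCA-counted mRMR: k from :func:`component_count` of the normalized
    table, then greedy selection of that many features."""
    norm = variance_normalize(t)
    k = component_count(norm, threshold)
    return mrmr_select(t, labels, k, criterion=criterion,
                       variance_threshold=threshold)
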