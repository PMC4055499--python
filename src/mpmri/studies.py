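"""Replication studies: the package's end-to-end property checks.

Each function runs one self-contained study on synthetic cohorts or
closed-form fixtures and returns plain numbers: worked percentage-change
examples, graph-metric oracle agreement, planted small-world group
differences with type-I calibration, mRMR recovery of planted informative
features, classifier/regressor calibration, and fALFF/VMHC analytics.

Study sizes are scaled for desk-time execution (region counts, replicate
counts and permutation counts are stated per study); every random element
derives from the single ``seed`` argument.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortConfig, generate_cohort, generate_phenotypes
from .efficiency import global_efficiency, local_efficiency, structural_group_comparison
from .features import falff, vmhc
from .integration import compute_feature_table, mrmr_select, variance_normalize, component_count
from .models import evaluate, fit_instance_regressor, predict_phenotype
from .networks import BinaryGraph
from .stats import load_reference_table, percent_change, two_sample_t

#: worked percentage-change cells: (key, table, region)
WORKED_CELLS = (
    ("pct_change_volume_left_inferior_frontal_gm", "volume", "frontal_gm_left_inferior"),
    ("pct_change_volume_left_superior_frontal_gm", "volume", "frontal_gm_left_superior"),
    ("pct_change_volume_right_superior_occipital_gm", "volume", "occipital_gm_right_superior"),
    ("pct_change_volume_left_postcentral_wm", "volume", "parietal_wm_left_postcentral"),
    ("pct_change_thickness_left_anterior_cingulum", "thickness", "frontal_left_anterior_cingulum"),
    ("pct_change_thickness_left_transverse_pole", "thickness", "frontal_left_transverse_pole"),
    ("pct_change_thickness_right_postcentral", "thickness", "parietal_right_postcentral"),
    ("pct_change_thickness_right_superior_temporal", "thickness", "temporal_right_superior"),
)

STRONG_SIGNAL_FEATURES = frozenset({
    "vol_caudate_L", "vol_caudate_R",
    "fc_caudate_Z", "fc_caudate_N",
    "fc_ifg_opercularis_Z", "fc_ifg_opercularis_N",
    "fc_ifg_triangularis_Z", "fc_ifg_triangularis_N",
})


def worked_percent_changes() -> dict[str, float]:
    """Recompute the reference percentage-change cells from the tabulated group means."""
    tables = {w: load_reference_table(w).set_index("region") for w in ("volume", "thickness")}
    out = {}
    for key, which, region in WORKED_CELLS:
        row = tables[which].loc[region]
        out[key] = percent_change(float(row["v1"]), float(row["v2"]))
    return out


# ---------------------------------------------------------------------------
# graph-metric oracle agreement

def _floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[adj > 0] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d


def _oracle_global(adj: np.ndarray) -> float:
    n = adj.shape[0]
    d = _floyd_warshall(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def _oracle_local(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nb = np.nonzero(adj[i])[0]
        if nb.size < 2:
            continue
        total += _oracle_global(adj[np.ix_(nb, nb)])
    return total / n


def _all_graphs(n: int):
    """Every labeled simple graph on n nodes (n <= 5)."""
    iu, ju = np.triu_indices(n, 1)
    m = len(iu)
    for bits in range(2 ** m):
        adj = np.zeros((n, n), dtype=np.uint8)
        mask = (bits >> np.arange(m)) & 1
        adj[iu, ju] = mask
        yield BinaryGraph(adj | adj.T)


def graph_oracle_agreement(seed: int, n_random_small: int = 300,
                           n_random_large: int = 200) -> dict[str, float]:
    """Exhaustive 2-5-node sweep plus random graphs up to 40 nodes, all
    checked against an independent Floyd-Warshall brute-force oracle."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    count = 0
    for n in range(2, 6):
        for g in _all_graphs(n):
            max_err = max(max_err,
                          abs(global_efficiency(g) - _oracle_global(g.adjacency)),
                          abs(local_efficiency(g) - _oracle_local(g.adjacency)))
            count += 1
    for n_nodes, reps in ((tuple(range(6, 13)), n_random_small),
                          (tuple(range(13, 41)), n_random_large)):
        for _ in range(reps):
            n = int(rng.choice(n_nodes))
            p = float(rng.uniform(0.05, 0.8))
            a = (rng.random((n, n)) < p).astype(np.uint8)
            a = np.triu(a, 1)
            g = BinaryGraph(a | a.T)
            max_err = max(max_err,
                          abs(global_efficiency(g) - _oracle_global(g.adjacency)),
                          abs(local_efficiency(g) - _oracle_local(g.adjacency)))
            count += 1
    k4 = BinaryGraph(np.ones((4, 4), dtype=np.uint8) - np.eye(4, dtype=np.uint8))
    p3 = BinaryGraph(np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.uint8))
    return {"max_abs_error": max_err, "n_graphs": count,
            "e_global_complete_k4": global_efficiency(k4),
            "e_global_path_p3": global_efficiency(p3)}


# ---------------------------------------------------------------------------
# small-world group differences on thickness covariance

def _thickness_tables(cfg: CohortConfig):
    coh = generate_cohort(cfg, timeseries=False)
    td = pd.DataFrame(coh.thickness_matrix("TD"), columns=coh.cortical_regions)
    asd = pd.DataFrame(coh.thickness_matrix("ASD"), columns=coh.cortical_regions)
    return td, asd


def smallworld_power_study(seed: int, n_per_group: int = 50,
                           n_regions: int = 60, n_perm: int = 79,
                           n_random: int = 6, n_reps: int = 3) -> dict[str, float]:
    """Planted covariance difference: fraction of mid-sparsity grid points
    where relative global efficiency is significantly LOWER in the ASD
    group, averaged over replicate cohorts."""
    grid = (0.10, 0.15, 0.20, 0.25, 0.30, 0.35)
    fracs = []
    for r in range(n_reps):
        cfg = CohortConfig(n_per_group=n_per_group, n_cortical=n_regions,
                           seed=seed + 7907 * r)
        td, asd = _thickness_tables(cfg)
        table = structural_group_comparison(td, asd, grid=grid,
                                            n_random=n_random, n_boot=0,
                                            n_perm=n_perm, seed=seed + r + 1)
        sub = table[table.metric == "e_global_rel"]
        fracs.append(float(((sub["p"] < 0.05) & (sub["point_diff"] < 0)).mean()))
    return {"sig_fraction": float(np.mean(fracs)), "n": n_per_group * 2}


def smallworld_type1_study(seed: int, n_reps: int = 200, n_per_group: int = 25,
                           n_regions: int = 40, n_perm: int = 59,
                           n_random: int = 3) -> dict[str, float]:
    """No planted difference: rejection rate of the permutation test at a
    mid sparsity across seeded replicates (nominal 5%)."""
    null_cov = {"TD": {"global": 0.25, "block": 0.2},
                "ASD": {"global": 0.25, "block": 0.2}}
    rejections = 0
    for r in range(n_reps):
        cfg = CohortConfig(n_per_group=n_per_group, n_cortical=n_regions,
                           covariance_strength=null_cov, seed=seed + 7919 * (r + 1))
        td, asd = _thickness_tables(cfg)
        table = structural_group_comparison(td, asd, grid=(0.2,),
                                            n_random=n_random, n_boot=0,
                                            n_perm=n_perm, seed=seed + r)
        rejections += float(table[table.metric == "e_global_rel"]["p"].iloc[0]) < 0.05
    return {"type1_rate": rejections / n_reps, "n": n_reps}


# ---------------------------------------------------------------------------
# mRMR recovery of planted informative features

INFORMATIVE_FEATURES = STRONG_SIGNAL_FEATURES | frozenset(
    {"fc_dmn_Z", "fc_dmn_N", "vmhc_Z", "vmhc_N"})


def mrmr_recovery_study(seed: int, n_reps: int = 20,
                        n_per_group: int = 50) -> dict[str, float]:
    """Fraction of seeded cohorts whose top-6 mRMR slots are all occupied by
    planted-informative features (group-dependent generator parameters),
    including the three strongly affected seed-Z features."""
    hits = 0
    for r in range(n_reps):
        cfg = CohortConfig(n_per_group=n_per_group, seed=seed + 104729 * (r + 1))
        coh = generate_cohort(cfg)
        table = compute_feature_table(coh)
        labels = (table.groups == "ASD").astype(int).to_numpy()
        sel = mrmr_select(table, labels, 6)
        top = set(sel.selected)
        ok = ({"fc_caudate_Z", "fc_ifg_opercularis_Z", "fc_ifg_triangularis_Z"} <= top
              and top <= INFORMATIVE_FEATURES)
        hits += int(ok)
    return {"recovery_rate": hits / n_reps, "n": n_reps}


# ---------------------------------------------------------------------------
# model calibration and recovery

def classifier_calibration_study(seed: int) -> dict[str, float]:
    rng = np.random.default_rng(seed)
    n = 200
    X = np.vstack([rng.standard_normal((n // 2, 5)),
                   rng.standard_normal((n // 2, 5)) + 3.0])
    y = np.repeat([0, 1], n // 2)
    separated = evaluate(X, y, "kfold", 10, seed=seed).accuracy
    full = evaluate(X, y, "full_dataset", seed=seed).accuracy
    perm_accs = []
    keep = np.r_[0:40, n // 2:n // 2 + 40]       # stratified subset
    Xs, ys = X[keep], y[keep]
    for k in range(25):
        perm_accs.append(evaluate(Xs, rng.permutation(ys), "kfold", 10,
                                  seed=seed + k).accuracy)
    return {"separated_kfold_accuracy": separated,
            "full_dataset_accuracy": full,
            "permuted_mean_accuracy": float(np.mean(perm_accs)), "n": n}


def regressor_recovery_study(seed: int) -> dict[str, float]:
    rng = np.random.default_rng(seed)
    n = 300
    X = rng.standard_normal((n, 4))
    signal = X @ np.full(4, 0.5)
    noise_sd = float(np.sqrt(np.var(signal) / 9.0))   # theoretical R^2 = 0.9
    y = signal + noise_sd * rng.standard_normal(n)
    model = fit_instance_regressor(X[:250], y[:250])
    pred = model.predict(X[250:])
    held_out_r = float(np.corrcoef(pred, y[250:])[0, 1])

    y0 = 2.0 * X[:, 0] - X[:, 1]                      # noise-free limit
    fitted = fit_instance_regressor(X[:, :2], y0, blend=1.5).predict(X[:, :2])
    slope = float(np.cov(fitted, y0, ddof=0)[0, 1] / np.var(fitted))
    return {"held_out_r": held_out_r, "noise_free_slope": slope, "n": n}


# ---------------------------------------------------------------------------
# fALFF / VMHC analytics

def falff_vmhc_analytics(seed: int) -> dict[str, float]:
    rng = np.random.default_rng(seed)
    t = np.arange(180) * 2.0
    in_band = falff(np.sin(2 * np.pi * 0.05 * t), tr=2.0).values[0]
    out_band = falff(np.sin(2 * np.pi * 0.2 * t), tr=2.0).values[0]
    white = float(falff(rng.standard_normal((40, 20000)), tr=2.0).values.mean())
    left = rng.standard_normal((6, 150))
    dup = vmhc(np.vstack([left, left]), [(k, k + 6) for k in range(6)])
    return {"falff_in_band": float(in_band), "falff_out_of_band": float(out_band),
            "falff_white_noise": white,
            "vmhc_duplicated_fraction": dup.n_suprathreshold / 6, "n": 180}


# ---------------------------------------------------------------------------
# end-to-end cohort analysis (feature table, classification, prediction)

def cohort_pipeline_study(seed: int, n_per_group: int = 70) -> dict[str, float]:
    """Full chain on one default-condition cohort: 22-feature table, PCA
    component counts, full-dataset classification and ADOS prediction."""
    cfg = CohortConfig(n_per_group=n_per_group, seed=seed)
    coh = generate_cohort(cfg)
    table = compute_feature_table(coh)
    coh = generate_phenotypes(coh, cfg, features=table.data)
    labels = (table.groups == "ASD").astype(int).to_numpy()
    norm = variance_normalize(table)
    sel = mrmr_select(table, labels, 4)
    X = table.data[sel.selected].to_numpy(dtype=float)
    full_acc = evaluate(X, labels, "full_dataset", seed=seed).accuracy
    phen = coh.phenotype_frame()
    _, r_ados, slope_ados = predict_phenotype(table, sel, phen["ados_module"],
                                              protocol="full_dataset", seed=seed)
    iq = phen["iq_full"]
    t_iq, _ = two_sample_t(iq[(table.groups == "ASD").to_numpy()],
                           iq[(table.groups == "TD").to_numpy()], variant="welch")
    return {"n_features": table.data.shape[1],
            "k_components_95": component_count(norm, 0.95),
            "k_components_99": component_count(norm, 0.99),
            "full_dataset_accuracy": full_acc,
            "ados_prediction_r": r_ados,
            "ados_prediction_slope": slope_ados,
            "n": 2 * n_per_group}


def welch_t_worked_example() -> dict[str, float]:
    """Group IQ difference from summary-equivalent samples
    (means 104.3/111.7, SDs 18.9/14.4, n 127/153)."""
    def sample(mean, sd, n, seed):
        v = np.random.default_rng(seed).standard_normal(n)
        v = (v - v.mean()) / v.std(ddof=1)
        return mean + sd * v
    t, p = two_sample_t(sample(104.3, 18.9, 127, 0),
                        sample(111.7, 14.4, 153, 1), variant="welch")
    return {"t": abs(t), "p": p, "n": 280}
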