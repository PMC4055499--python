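"""Feature table assembly, PCA component counting, MI and mRMR selection."""
import numpy as np
import pandas as pd
import pytest

from mpmri.integration import (CANONICAL_FEATURES, FeatureTable,
                               assemble_features, component_count,
                               compute_feature_table, discretize,
                               mrmr_select, mutual_information,
                               select_by_variance, variance_normalize)


def _table(X, labels=None):
    X = np.atleast_2d(X)
    cols = [f"f{k}" for k in range(X.shape[1])]
    groups = pd.Series(labels if labels is not None else ["a"] * X.shape[0])
    return FeatureTable(pd.DataFrame(X, columns=cols), groups)


class TestAssembly:
    def test_canonical_table_has_22_columns(self, small_features):
        assert list(small_features.data.columns) == list(CANONICAL_FEATURES)
        assert small_features.data.shape[1] == 22
        assert not small_features.data.isna().any().any()

    def test_single_subject_table(self, small_cohort):
        import copy
        coh = copy.copy(small_cohort)
        coh.subjects = small_cohort.subjects[:1]
        t = compute_feature_table(coh)
        assert t.data.shape == (1, 22)

    def test_missing_vmhc_source_lists_columns(self, small_cohort):
        from mpmri.features import falff, seed_connectivity_map, summarize_seed_map
        from mpmri.stats import normalize_volume
        seed_summaries, falff_means, volumes = {}, {}, {}
        for s in small_cohort.subjects:
            seed_summaries[s.id] = {
                name: summarize_seed_map(seed_connectivity_map(s.timeseries, idx), 2.3, name)
                for name, idx in small_cohort.seed_sets.items()}
            fa = falff(s.timeseries, tr=2.0).values
            falff_means[s.id] = {n: float(fa[small_cohort.seed_sets[n]].mean())
                                 for n in ("caudate", "ifg_opercularis", "ifg_triangularis")}
            volumes[s.id] = {k: normalize_volume(v, s.supratentorial)
                             for k, v in s.volumes.items()}
        with pytest.raises(KeyError, match="VMHC missing"):
            assemble_features(small_cohort, seed_summaries, falff_means, {}, volumes)

    def test_volumes_are_supratentorial_normalized(self, small_cohort, small_features):
        s = small_cohort.subjects[0]
        expect = s.volumes["caudate_L"] / s.supratentorial * 1000.0
        assert small_features.data.loc[s.id, "vol_caudate_L"] == pytest.approx(expect)


class TestVarianceNormalize:
    def test_population_moments(self, small_features):
        norm = variance_normalize(small_features)
        assert np.allclose(norm.data.mean(), 0, atol=1e-12)
        assert np.allclose(norm.data.var(ddof=0), 1, atol=1e-12)

    def test_idempotent(self, small_features):
        once = variance_normalize(small_features)
        twice = variance_normalize(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_hand_computed_column(self):
        t = _table(np.array([[1.0], [2.0], [3.0]]))
        norm = variance_normalize(t)
        np.testing.assert_allclose(norm.data["f0"],
                                   [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_zero_variance_named(self):
        t = _table(np.column_stack([np.arange(4.0), np.ones(4)]))
        with pytest.raises(ValueError, match="f1"):
            variance_normalize(t)


class TestComponentCount:
    def test_rank_one_table(self):
        base = np.arange(10.0)
        t = _table(np.column_stack([base, 2 * base, -base]))
        assert component_count(t, 0.95) == 1

    def test_isotropic_covariance_ceil_rule(self):
        # exactly whitened 22-feature data: all eigenvalues equal,
        # so k = ceil(threshold * 22)
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.standard_normal((100, 22)))
        t = _table(q - q.mean(axis=0))
        t = variance_normalize(t)
        assert component_count(t, 0.95) == 21
        assert component_count(t, 0.99) == 22

    def test_monotone_in_threshold(self, small_features):
        norm = variance_normalize(small_features)
        assert component_count(norm, 0.95) <= component_count(norm, 0.99)

    def test_empty_table_rejected(self):
        t = FeatureTable(pd.DataFrame(columns=["a"], dtype=float), pd.Series(dtype=object))
        with pytest.raises(ValueError):
            component_count(t, 0.95)


class TestDiscretize:
    def test_standard_normal_middle_bin_mass(self):
        x = np.random.default_rng(1).standard_normal(100_000)
        d = discretize(x)
        assert np.mean(d == 1) == pytest.approx(0.6827, abs=0.01)

    def test_symmetric_outer_bins(self):
        x = np.concatenate([np.random.default_rng(2).standard_normal(50_000)])
        d = discretize(x)
        assert abs(np.mean(d == 0) - np.mean(d == 2)) < 0.01

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            discretize(np.ones(10))

    def test_affine_invariance(self):
        x = np.random.default_rng(3).standard_normal(500)
        np.testing.assert_array_equal(discretize(x), discretize(7.0 * x - 3.0))


class TestMutualInformation:
    def test_identical_binary_vectors_give_ln2(self):
        x = np.array([0, 1] * 500)
        assert mutual_information(x, x) == pytest.approx(np.log(2), abs=1e-12)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 3, 60_000)
        y = rng.integers(0, 3, 60_000)
        assert mutual_information(x, y) < 0.01

    def test_constant_vector_zero(self):
        x = np.array([0, 1, 2, 0, 1, 2])
        assert mutual_information(x, np.zeros(6, dtype=int)) == 0.0

    def test_matches_sklearn_oracle(self):
        from sklearn.metrics import mutual_info_score
        rng = np.random.default_rng(5)
        x = rng.integers(0, 3, 400)
        y = (x + rng.integers(0, 2, 400)) % 3
        assert mutual_information(x, y) == pytest.approx(mutual_info_score(x, y), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mutual_information(np.zeros(3), np.zeros(4))


def _brute_force_mrmr(table, labels, k):
    """Independent step-by-step re-evaluation of the greedy criterion."""
    disc = {c: discretize(table.data[c].to_numpy()) for c in table.feature_names}
    rel = {c: mutual_information(disc[c], labels) for c in table.feature_names}
    selected = []
    for _ in range(k):
        scores = {}
        for c in table.feature_names:
            if c in selected:
                continue
            red = (np.mean([mutual_information(disc[c], disc[s]) for s in selected])
                   if selected else 0.0)
            scores[c] = rel[c] - red
        best = max(table.feature_names,
                   key=lambda c: (c not in selected, scores.get(c, -np.inf),
                                  -table.feature_names.index(c)))
        selected.append(best)
    return selected


class TestMrmr:
    def test_k1_is_max_relevance(self):
        rng = np.random.default_rng(6)
        labels = np.repeat([0, 1], 200)
        X = rng.standard_normal((400, 5))
        X[:, 3] += labels * 2.0
        sel = mrmr_select(_table(X), labels, 1)
        assert sel.selected == ["f3"]

    def test_informative_feature_found_among_noise(self):
        rng = np.random.default_rng(7)
        labels = np.repeat([0, 1], 200)
        X = rng.standard_normal((400, 22))
        X[:, 10] += labels * 1.5
        sel = mrmr_select(_table(X), labels, 3)
        assert sel.selected[0] == "f10"

    def test_duplicate_deferred_by_redundancy(self):
        rng = np.random.default_rng(8)
        labels = np.repeat([0, 1], 300)
        strong = rng.standard_normal(600) + labels * 2.0
        moderate = rng.standard_normal(600) + labels * 1.0
        X = np.column_stack([strong, strong.copy(), moderate,
                             rng.standard_normal(600)])
        sel = mrmr_select(_table(X), labels, 3)
        assert sel.selected[0] == "f0"
        # the exact duplicate is penalized behind the independent feature
        assert sel.selected[1] == "f2"

    def test_matches_brute_force_re_evaluation(self, small_features):
        labels = (small_features.groups == "ASD").astype(int).to_numpy()
        for k in (1, 4, 6):
            sel = mrmr_select(small_features, labels, k)
            assert sel.selected == _brute_force_mrmr(small_features, labels, k)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(9)
        labels = np.repeat([0, 1], 100)
        X = rng.standard_normal((200, 6))
        X[:, 2] += labels
        a = mrmr_select(_table(X), labels, 4).selected
        X2 = X * np.array([3.0, 0.1, 7.0, 2.0, 5.0, 0.5]) + 11.0
        b = mrmr_select(_table(X2), labels, 4).selected
        assert a == b

    def test_k_too_large_rejected(self, small_features):
        labels = (small_features.groups == "ASD").astype(int).to_numpy()
        with pytest.raises(ValueError):
            mrmr_select(small_features, labels, 23)

    def test_select_by_variance_pipeline(self, small_features):
        labels = (small_features.groups == "ASD").astype(int).to_numpy()
        sel = select_by_variance(small_features, labels, threshold=0.95)
        assert sel.k == component_count(variance_normalize(small_features), 0.95)
        assert len(sel.selected) == sel.k
        assert len(set(sel.selected)) == sel.k


def test_feature_table_io_roundtrip(tmp_path, small_features):
    small_features.write(tmp_path / "f.tsv")
    back = FeatureTable.read(tmp_path / "f.tsv")
    pd.testing.assert_frame_equal(back.data, small_features.data)
    assert (back.groups == small_features.groups).all()
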