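"""Synthetic cohort generator: determinism, planted effects, signal structure."""
import numpy as np
import pandas as pd
import pytest

from mpmri.cohort import (CohortConfig, PhenotypeSpec, generate_cohort,
                          generate_phenotypes, generate_timeseries,
                          read_cohort, write_cohort, default_seed_sets,
                          default_target_sets, band_limited_noise)


def _flat_connectivity(c, h=0.0):
    return dict(
        seed_connectivity={g: {s: c for s in ("caudate", "ifg_opercularis",
                                              "ifg_triangularis", "dmn")}
                           for g in ("TD", "ASD")},
        homotopic_strength={"TD": h, "ASD": h},
        coupling_sd=0.0, homotopic_sd=0.0,
    )


class TestGenerateCohort:
    def test_subject_count_and_groups(self):
        coh = generate_cohort(CohortConfig(n_per_group=20, seed=0), timeseries=False)
        assert len(coh.subjects) == 40
        assert len(coh.group("ASD")) == len(coh.group("TD")) == 20

    def test_seeded_determinism(self):
        cfg = CohortConfig(n_per_group=5, seed=42)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert np.array_equal(a.thickness_matrix(), b.thickness_matrix())
        assert np.array_equal(a.subjects[3].timeseries, b.subjects[3].timeseries)
        assert a.subjects[0].phenotypes == b.subjects[0].phenotypes

    def test_different_seeds_differ(self):
        a = generate_cohort(CohortConfig(n_per_group=5, seed=1), timeseries=False)
        b = generate_cohort(CohortConfig(n_per_group=5, seed=2), timeseries=False)
        assert not np.array_equal(a.thickness_matrix(), b.thickness_matrix())

    def test_planted_volume_effect_recovered(self):
        cfg = CohortConfig(n_per_group=500, seed=3, volume_noise_sd=0.02,
                           volume_effects={"caudate_R": 0.10})
        coh = generate_cohort(cfg, timeseries=False)
        td = coh.volume_matrix("TD")["caudate_R"].mean()
        asd = coh.volume_matrix("ASD")["caudate_R"].mean()
        assert 1.08 <= asd / td <= 1.12

    def test_thickness_positive_and_supratentorial_dominates(self, small_cohort):
        for s in small_cohort.subjects:
            assert (s.thickness > 0).all()
            assert s.supratentorial > max(s.volumes.values())

    def test_default_dimensions(self, small_cohort):
        cfg = small_cohort.config
        assert (cfg.n_cortical, cfg.n_roi, cfg.n_timepoints) == (148, 112, 180)
        assert (cfg.n_subcortical, cfg.n_wm, cfg.tr_seconds) == (45, 70, 2.0)
        assert len(small_cohort.cortical_regions) == 148
        assert small_cohort.subjects[0].timeseries.shape == (112, 180)

    @pytest.mark.parametrize("kwargs", [
        {"n_per_group": 0}, {"n_timepoints": -1}, {"tr_seconds": 0},
        {"volume_effects": {"caudate_L": -1.5}},
        {"seed_connectivity": {"TD": {"caudate": 1.2}}},
        {"homotopic_strength": {"TD": 0.7}, "seed_connectivity":
            {"TD": {"caudate": 0.5}}},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortConfig(**kwargs)

    def test_homotopic_pairs_disjoint(self, small_cohort):
        seen = set()
        for a, b in small_cohort.homotopic_pairs:
            assert a != b and a not in seen and b not in seen
            seen.update((a, b))

    def test_seed_sets_nonempty_roi_subsets(self, small_cohort):
        n = small_cohort.config.n_roi
        for name, idxs in small_cohort.seed_sets.items():
            assert idxs and all(0 <= i < n for i in idxs)


class TestTimeseries:
    def test_shape(self, small_cohort):
        assert small_cohort.subjects[0].timeseries.shape == (112, 180)

    def test_no_constant_rows(self, small_cohort):
        for s in small_cohort.subjects[:5]:
            assert (s.timeseries.std(axis=1) > 0).all()

    def test_zero_coupling_gives_near_zero_correlations(self):
        cfg = CohortConfig(n_per_group=2, seed=5, **_flat_connectivity(0.0))
        coh = generate_cohort(cfg)
        ts = coh.subjects[0].timeseries
        r = np.corrcoef(ts)
        off = np.abs(r[np.triu_indices_from(r, 1)])
        assert off.mean() < 0.1

    def test_planted_coupling_recovered(self):
        # long series: within-network correlation concentrates near c
        cfg = CohortConfig(n_per_group=1, n_timepoints=2000, seed=6,
                           **_flat_connectivity(0.8))
        coh = generate_cohort(cfg)
        ts = coh.subjects[0].timeseries
        idx = coh.seed_sets["dmn"]
        r = np.corrcoef(ts[idx])
        off = r[np.triu_indices(len(idx), 1)]
        assert 0.7 <= off.mean() <= 0.9

    def test_target_sets_disjoint_from_seeds(self):
        seeds = default_seed_sets(112)
        targets = default_target_sets(112)
        seed_all = {i for v in seeds.values() for i in v}
        targ_all = {i for v in targets.values() for i in v}
        assert not (seed_all & targ_all)

    def test_band_limited_noise_spectrum(self):
        rng = np.random.default_rng(0)
        x = band_limited_noise(rng, 2000, 2.0, size=4)
        freqs = np.fft.rfftfreq(2000, d=2.0)
        amp = np.abs(np.fft.rfft(x, axis=-1))
        out_band = (freqs < 0.005) | (freqs > 0.1)
        assert amp[:, out_band].max() < 1e-8 * amp.max()


class TestPhenotypes:
    def test_null_model_gives_no_correlation(self):
        model = {"score": PhenotypeSpec(10.0, {}, noise_sd=2.0)}
        cfg = CohortConfig(n_per_group=140, seed=8, phenotype_model=model)
        coh = generate_cohort(cfg)
        from mpmri.integration import compute_feature_table
        table = compute_feature_table(coh)
        coh = generate_phenotypes(coh, cfg, features=table.data)
        y = coh.phenotype_frame()["score"]
        for col in table.data.columns:
            r = np.corrcoef(table.data[col], y)[0, 1]
            assert abs(r) < 0.15

    def test_noise_free_coupling_is_deterministic(self, small_cohort, small_features):
        model = {"score": PhenotypeSpec(0.0, {"fc_caudate_Z": 2.0}, noise_sd=1e-9)}
        cfg = CohortConfig(n_per_group=20, seed=7, phenotype_model=model)
        coh = generate_phenotypes(small_cohort, cfg, features=small_features.data)
        y = coh.phenotype_frame()["score"]
        r = np.corrcoef(small_features.data["fc_caudate_Z"], y)[0, 1]
        assert r > 0.999

    def test_planted_correlation_recovered(self):
        # beta=-1, noise sd=sqrt(3) on a z-scored feature: theoretical r=-0.5
        model = {"score": PhenotypeSpec(0.0, {"vol_caudate_L": -1.0},
                                        noise_sd=float(np.sqrt(3.0)))}
        cfg = CohortConfig(n_per_group=250, seed=9, phenotype_model=model)
        coh = generate_cohort(cfg, timeseries=False)
        vols = coh.volume_matrix(normalized=True)["caudate_L"]
        feats = pd.DataFrame({"vol_caudate_L": vols})
        # complete the betas' feature space with just the referenced column
        coh = generate_phenotypes(coh, cfg, features=feats)
        y = coh.phenotype_frame()["score"]
        r = np.corrcoef(vols, y)[0, 1]
        assert -0.6 <= r <= -0.4

    def test_unknown_feature_rejected(self, small_cohort, small_features):
        model = {"score": PhenotypeSpec(0.0, {"no_such_feature": 1.0})}
        cfg = CohortConfig(n_per_group=20, seed=7, phenotype_model=model)
        with pytest.raises(KeyError, match="no_such_feature"):
            generate_phenotypes(small_cohort, cfg, features=small_features.data)

    def test_scores_in_declared_ranges(self, small_cohort_with_phenotypes):
        phen = small_cohort_with_phenotypes.phenotype_frame()
        assert phen["ados_total"].between(0, 22).all()
        assert phen["iq_full"].between(40, 160).all()
        assert (phen["iq_full"] == phen["iq_full"].round()).all()


class TestCohortIO:
    def test_roundtrip(self, tmp_path, small_cohort_with_phenotypes):
        coh = small_cohort_with_phenotypes
        write_cohort(coh, tmp_path / "cohort")
        back = read_cohort(tmp_path / "cohort")
        assert [s.id for s in back.subjects] == [s.id for s in coh.subjects]
        np.testing.assert_allclose(back.thickness_matrix(), coh.thickness_matrix())
        np.testing.assert_allclose(back.subjects[2].timeseries,
                                   coh.subjects[2].timeseries, rtol=0, atol=1e-12)
        assert back.seed_sets == coh.seed_sets
        assert back.subjects[0].phenotypes == pytest.approx(coh.subjects[0].phenotypes)
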