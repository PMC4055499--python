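"""Synthetic two-group cohort generator.

Emulates the statistical structure of a post-preprocessing multiparametric
MRI study of autism spectrum disorder (ASD) versus typically developing (TD)
children: regional cortical thickness (148 regions by default), regional
subcortical/white-matter volumes, band-limited resting-state ROI time series
(112 ROIs x 180 time points at TR = 2 s), and clinical phenotype scores
(ADOS, ADI-R, IQ, SRS, VABS) linearly coupled to latent imaging features.

Group effects are planted as

* multiplicative mean shifts on configured volume/thickness regions
  (a few percent, the magnitude reported for real ASD cohorts),
* group-dependent covariance structure for cortical thickness, via a
  cohort-wide latent factor (long-range integration) plus one latent factor
  per hemisphere-lobe block (local covariance),
* group-dependent seed-network coupling and homotopic coupling for the
  ROI time series, using a factor model whose expected pairwise correlation
  equals the configured coupling strength,
* phenotype scores generated as linear combinations of z-scored imaging
  features plus noise, with the sign structure observed clinically
  (e.g. caudate connectivity coupling negatively to ADOS).

Every output is a pure function of (config, seed).
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

PREPROC_BAND = (0.005, 0.1)  # Hz, band applied by standard RS-fMRI preprocessing

SEED_NAMES = ("caudate", "ifg_opercularis", "ifg_triangularis", "dmn")

#: the nine subcortical volumes used as imaging features
CANONICAL_VOLUMES = (
    "caudate_L", "caudate_R",
    "thalamus_L", "thalamus_R",
    "pallidum_L", "pallidum_R",
    "hippocampus_L", "hippocampus_R",
    "cerebellum",
)

# typical volumes in cm^3 for the named structures
_VOLUME_MEANS = {
    "caudate_L": 3.6, "caudate_R": 3.7,
    "thalamus_L": 7.4, "thalamus_R": 7.3,
    "pallidum_L": 1.7, "pallidum_R": 1.7,
    "hippocampus_L": 4.0, "hippocampus_R": 4.1,
    "cerebellum": 140.0,
}
_SUPRATENTORIAL_MEAN = 1150.0

_LOBES = ("frontal", "parietal", "temporal", "occipital")


@dataclass
class PhenotypeSpec:
    """Linear generative model for one clinical score.

    ``score = intercept + sum_f beta_f * z_f + eps`` with ``z_f`` the
    cohort-z-scored imaging feature ``f`` and ``eps ~ N(0, noise_sd^2)``,
    then truncated to [minimum, maximum] and optionally rounded.
    """

    intercept: float
    betas: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    minimum: float = -np.inf
    maximum: float = np.inf
    integer: bool = False
    missing_rate: float = 0.0


def default_phenotype_model() -> dict[str, PhenotypeSpec]:
    """Clinical score models with negative connectivity-ADOS couplings.

    Feature names refer to the canonical 22-feature table
    (:data:`mpmri.integration.CANONICAL_FEATURES`).
    """
    return {
        "ados_total": PhenotypeSpec(8.0, {"fc_caudate_N": -2.0, "fc_ifg_triangularis_N": -1.5}, 2.5, 0, 22, True),
        "ados_module": PhenotypeSpec(6.0, {"fc_caudate_Z": -1.8, "fc_ifg_opercularis_Z": -1.5}, 2.0, 0, 22, True),
        "ados_social_affect": PhenotypeSpec(7.0, {"fc_caudate_N": -1.6}, 2.0, 0, 22, True),
        "ados_communication": PhenotypeSpec(5.0, {"fc_ifg_triangularis_N": -1.4}, 2.0, 0, 22, True),
        "ados_research": PhenotypeSpec(7.0, {"fc_caudate_N": -1.5}, 2.0, 0, 22, True),
        "adir_total": PhenotypeSpec(30.0, {"fc_caudate_Z": -4.0, "vol_caudate_R": 3.0}, 6.0, 0, 60, True),
        "iq_full": PhenotypeSpec(108.0, {"fc_caudate_N": -6.0, "fc_caudate_Z": -4.0}, 11.0, 40, 160, True),
        "iq_verbal": PhenotypeSpec(105.0, {"fc_ifg_triangularis_Z": -5.0}, 12.0, 40, 160, True),
        "iq_performance": PhenotypeSpec(106.0, {"fc_caudate_N": -4.0}, 12.0, 40, 160, True),
        "srs_total": PhenotypeSpec(60.0, {"fc_ifg_opercularis_Z": -8.0, "vmhc_Z": -5.0}, 12.0, 0, 195, True),
        "vabs_socialization": PhenotypeSpec(90.0, {"fc_caudate_N": 6.0, "fc_caudate_Z": 5.0}, 9.0, 20, 160, True),
        "vabs_interpersonal": PhenotypeSpec(12.0, {"fc_caudate_N": -2.0, "fc_ifg_triangularis_N": -1.5}, 2.5, 0, 24, True),
        "vabs_daily_living": PhenotypeSpec(90.0, {"fc_caudate_Z": 5.0}, 10.0, 20, 160, True),
    }


def _default_volume_effects() -> dict[str, float]:
    # caudate enlargement with milder hippocampal increase, emulating the
    # subcortical gray-matter increments reported in ASD
    return {"caudate_L": 0.065, "caudate_R": 0.08,
            "hippocampus_L": 0.02, "hippocampus_R": 0.02}


def _default_thickness_effects() -> dict[str, float]:
    # cortical thickening of ~3-5% spread over a subset of regions
    return {f"ctx_L_{k:03d}": 0.04 for k in range(0, 18, 2)} | {
        f"ctx_R_{k:03d}": 0.035 for k in range(1, 18, 2)}


def _default_covariance_strength() -> dict[str, dict[str, float]]:
    # TD: strong cohort-wide factor, weak local blocks (integrated network).
    # ASD: weak cohort-wide factor, strong local blocks (modular network).
    return {"TD": {"global": 0.35, "block": 0.10},
            "ASD": {"global": 0.05, "block": 0.45}}


def _default_seed_connectivity() -> dict[str, dict[str, float]]:
    # reduced caudate/IFG coupling in ASD; DMN nearly preserved
    return {
        "TD": {"caudate": 0.45, "ifg_opercularis": 0.40,
               "ifg_triangularis": 0.40, "dmn": 0.45},
        "ASD": {"caudate": 0.25, "ifg_opercularis": 0.22,
                "ifg_triangularis": 0.22, "dmn": 0.40},
    }


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study dimensions: 148 cortical regions,
    112 time-series ROIs, 180 volumes at TR = 2 s, 45 subcortical and
    70 white-matter volume regions, 140 subjects per group.
    """

    n_per_group: int = 140
    n_cortical: int = 148
    n_roi: int = 112
    n_timepoints: int = 180
    tr_seconds: float = 2.0
    n_subcortical: int = 45
    n_wm: int = 70
    volume_effects: dict[str, float] = field(default_factory=_default_volume_effects)
    thickness_effects: dict[str, float] = field(default_factory=_default_thickness_effects)
    covariance_strength: dict[str, dict[str, float]] = field(default_factory=_default_covariance_strength)
    seed_connectivity: dict[str, dict[str, float]] = field(default_factory=_default_seed_connectivity)
    homotopic_strength: dict[str, float] = field(default_factory=lambda: {"TD": 0.32, "ASD": 0.29})
    target_coupling: float = 0.5   # target-ROI coupling as a fraction of the seed strength
    coupling_sd: float = 0.04      # between-subject SD of seed coupling strengths
    homotopic_sd: float = 0.06     # between-subject SD of homotopic strength
    volume_noise_sd: float = 0.06    # fractional SD of regional volumes
    thickness_noise_sd: float = 0.05  # fractional SD of regional thickness
    phenotype_model: dict[str, PhenotypeSpec] = field(default_factory=default_phenotype_model)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_per_group", "n_cortical", "n_roi", "n_timepoints",
                     "n_subcortical", "n_wm"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.volume_noise_sd <= 0 or self.thickness_noise_sd <= 0:
            raise ValueError("noise SDs must be positive")
        for eff in list(self.volume_effects.values()) + list(self.thickness_effects.values()):
            if eff <= -1:
                raise ValueError(f"effect {eff} <= -1 would produce non-positive measures")
        if not 0 <= self.target_coupling < 1:
            raise ValueError("target_coupling must lie in [0, 1)")
        for group, per_seed in self.seed_connectivity.items():
            h = self.homotopic_strength.get(group, 0.0)
            if not 0 <= h < 1:
                raise ValueError(f"homotopic strength for {group} outside [0, 1)")
            for seed_name, c in per_seed.items():
                if not 0 <= c < 1:
                    raise ValueError(f"coupling {seed_name}={c} for {group} outside [0, 1)")
                if c + h >= 1:
                    raise ValueError(f"coupling + homotopic strength >= 1 for {group}/{seed_name}")
        for group, cs in self.covariance_strength.items():
            tot = cs.get("global", 0.0) + cs.get("block", 0.0)
            if not 0 <= tot < 1:
                raise ValueError(f"covariance strengths for {group} must sum into [0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phenotype_model"] = {k: dataclasses.asdict(v) for k, v in self.phenotype_model.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "phenotype_model" in d:
            d["phenotype_model"] = {k: PhenotypeSpec(**v) for k, v in d["phenotype_model"].items()}
        return cls(**d)


@dataclass
class Subject:
    id: str
    group: str                      # "ASD" | "TD"
    age: float
    sex: str                        # "F" | "M"
    thickness: np.ndarray           # (n_cortical,) mm
    volumes: dict[str, float]       # region -> raw volume
    supratentorial: float
    timeseries: np.ndarray | None = None   # (n_roi, n_timepoints)
    phenotypes: dict[str, float] = field(default_factory=dict)
    ts_seed: int = 0                # per-subject stream for time-series noise


@dataclass
class Cohort:
    subjects: list[Subject]
    cortical_regions: list[str]
    volume_regions: list[str]
    roi_names: list[str]
    homotopic_pairs: list[tuple[int, int]]
    seed_sets: dict[str, list[int]]
    config: CohortConfig

    def group(self, label: str) -> list[Subject]:
        return [s for s in self.subjects if s.group == label]

    def thickness_matrix(self, group: str | None = None) -> np.ndarray:
        subs = self.subjects if group is None else self.group(group)
        return np.array([s.thickness for s in subs])

    def volume_matrix(self, group: str | None = None, normalized: bool = False) -> pd.DataFrame:
        subs = self.subjects if group is None else self.group(group)
        rows = []
        for s in subs:
            v = pd.Series(s.volumes, index=self.volume_regions, dtype=float)
            if normalized:
                v = v / s.supratentorial * 1000.0
            rows.append(v)
        return pd.DataFrame(rows, index=[s.id for s in subs])

    def phenotype_frame(self, group: str | None = None) -> pd.DataFrame:
        subs = self.subjects if group is None else self.group(group)
        return pd.DataFrame([s.phenotypes for s in subs], index=[s.id for s in subs])


# ---------------------------------------------------------------------------
# region bookkeeping

def cortical_region_names(n_cortical: int) -> list[str]:
    half = n_cortical // 2
    names = [f"ctx_L_{k:03d}" for k in range(half)]
    names += [f"ctx_R_{k:03d}" for k in range(n_cortical - half)]
    return names


def cortical_blocks(n_cortical: int) -> np.ndarray:
    """Hemisphere-lobe block index per cortical region (8 blocks)."""
    half = n_cortical // 2
    blocks = np.empty(n_cortical, dtype=int)
    for hemi, (start, count) in enumerate(((0, half), (half, n_cortical - half))):
        # contiguous chunks per lobe within each hemisphere
        bounds = np.linspace(0, count, len(_LOBES) + 1).astype(int)
        for lobe in range(len(_LOBES)):
            blocks[start + bounds[lobe]: start + bounds[lobe + 1]] = hemi * len(_LOBES) + lobe
    return blocks


def volume_region_names(n_subcortical: int, n_wm: int) -> list[str]:
    if n_subcortical < len(CANONICAL_VOLUMES):
        raise ValueError("n_subcortical must cover the canonical subcortical set")
    names = list(CANONICAL_VOLUMES)
    names += [f"subcort_{k:03d}" for k in range(n_subcortical - len(CANONICAL_VOLUMES))]
    names += [f"wm_{k:03d}" for k in range(n_wm)]
    return names


def roi_names(n_roi: int) -> list[str]:
    half = n_roi // 2
    return [f"roi_L_{k:03d}" for k in range(half)] + \
           [f"roi_R_{k:03d}" for k in range(n_roi - half)]


def default_homotopic_pairs(n_roi: int) -> list[tuple[int, int]]:
    half = n_roi // 2
    return [(k, half + k) for k in range(half)]


def default_seed_sets(n_roi: int) -> dict[str, list[int]]:
    """Bilateral seed networks over homotopic ROI pairs.

    caudate and the two IFG subdivisions get 2 pairs each, the DMN core 3.
    """
    half = n_roi // 2
    if half < 9:
        raise ValueError("need at least 18 ROIs for the default seed sets")
    alloc = {"caudate": (0, 2), "ifg_opercularis": (2, 4),
             "ifg_triangularis": (4, 6), "dmn": (6, 9)}
    return {name: sorted([p for k in range(a, b) for p in (k, half + k)])
            for name, (a, b) in alloc.items()}


def default_target_sets(n_roi: int) -> dict[str, list[int]]:
    """Cortical projection targets of each seed network.

    Target ROIs receive the seed's network factor at an attenuated coupling
    (``target_coupling`` x the seed strength), so seed connectivity maps
    have genuine suprathreshold regions whose strength tracks the planted
    group difference. 4 homotopic pairs per seed (5 for the DMN), disjoint
    from all seed sets.
    """
    half = n_roi // 2
    if half < 26:
        raise ValueError("need at least 52 ROIs for the default target sets")
    alloc = {"caudate": (9, 13), "ifg_opercularis": (13, 17),
             "ifg_triangularis": (17, 21), "dmn": (21, 26)}
    return {name: sorted([p for k in range(a, b) for p in (k, half + k)])
            for name, (a, b) in alloc.items()}


# ---------------------------------------------------------------------------
# generators

def band_limited_noise(rng: np.random.Generator, n: int, tr: float,
                       low: float = PREPROC_BAND[0], high: float = PREPROC_BAND[1],
                       size: int = 1) -> np.ndarray:
    """Unit-variance white noise restricted to [low, high] Hz, shape (size, n)."""
    white = rng.standard_normal((size, n))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=tr)
    spec[:, (freqs < low) | (freqs > high)] = 0.0
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_timeseries(subject: Subject, config: CohortConfig) -> np.ndarray:
    """ROI time series from a shared-factor model.

    Each ROI i in seed network m follows
    ``x_i = sqrt(c_m) g_m + sqrt(h) q_p + sqrt(1 - c_m - h) e_i``
    with g_m a network factor, q_p a homotopic-pair factor and e_i private
    noise, all band-limited to the preprocessing band; the expected pairwise
    correlation within network m is c_m and h across a homotopic pair.
    """
    n_roi, T, tr = config.n_roi, config.n_timepoints, config.tr_seconds
    rng = np.random.default_rng(subject.ts_seed)

    # subject-level connectivity: group mean + between-subject jitter
    group_c = config.seed_connectivity[subject.group]
    c_by_seed = {name: float(np.clip(c + config.coupling_sd * rng.standard_normal(),
                                     0.0, 0.9))
                 for name, c in group_c.items()}
    h = config.homotopic_strength.get(subject.group, 0.0)
    if h > 0:
        h = float(np.clip(h + config.homotopic_sd * rng.standard_normal(), 0.0, 0.9))
    c_max = max(c_by_seed.values(), default=0.0)
    h = min(h, 0.98 - c_max)   # keep every variance decomposition valid
    seed_sets = default_seed_sets(n_roi)
    pairs = default_homotopic_pairs(n_roi)
    try:
        target_sets = default_target_sets(n_roi)
    except ValueError:
        target_sets = {}

    membership = np.full(n_roi, -1)
    is_target = np.zeros(n_roi, dtype=bool)
    for m, name in enumerate(SEED_NAMES):
        for i in seed_sets[name]:
            membership[i] = m
        for i in target_sets.get(name, ()):
            membership[i] = m
            is_target[i] = True
    pair_of = np.full(n_roi, -1)
    for p, (a, b) in enumerate(pairs):
        pair_of[a] = pair_of[b] = p

    g = band_limited_noise(rng, T, tr, size=len(SEED_NAMES))
    q = band_limited_noise(rng, T, tr, size=len(pairs))
    e = band_limited_noise(rng, T, tr, size=n_roi)

    ts = np.empty((n_roi, T))
    for i in range(n_roi):
        c = c_by_seed[SEED_NAMES[membership[i]]] if membership[i] >= 0 else 0.0
        if is_target[i]:
            c *= config.target_coupling
        hp = h if pair_of[i] >= 0 else 0.0
        parts = np.sqrt(1.0 - c - hp) * e[i]
        if c > 0:
            parts = parts + np.sqrt(c) * g[membership[i]]
        if hp > 0:
            parts = parts + np.sqrt(hp) * q[pair_of[i]]
        ts[i] = parts
    return ts


def generate_cohort(config: CohortConfig, timeseries: bool = True) -> Cohort:
    """Draw a full two-group cohort (2 * n_per_group subjects).

    Group effects are applied multiplicatively to the configured regions of
    the ASD group; identical seeds give bit-identical cohorts.
    """
    ss = np.random.SeedSequence(config.seed)
    anat_seed, ts_root, _ = ss.spawn(3)
    rng = np.random.default_rng(anat_seed)

    ctx_names = cortical_region_names(config.n_cortical)
    blocks = cortical_blocks(config.n_cortical)
    vol_names = volume_region_names(config.n_subcortical, config.n_wm)
    rois = roi_names(config.n_roi)

    # deterministic per-region baselines (same for both groups)
    ctx_mu = 2.2 + 0.8 * ((np.arange(config.n_cortical) * 37 % 100) / 100.0)
    vol_mu = np.array([_VOLUME_MEANS.get(nm, 1.0 + 9.0 * ((k * 53 % 97) / 97.0))
                       for k, nm in enumerate(vol_names)])

    thick_eff = np.ones(config.n_cortical)
    for nm, eff in config.thickness_effects.items():
        if nm in ctx_names:
            thick_eff[ctx_names.index(nm)] = 1.0 + eff
    vol_eff = np.ones(len(vol_names))
    for nm, eff in config.volume_effects.items():
        if nm in vol_names:
            vol_eff[vol_names.index(nm)] = 1.0 + eff

    ts_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                ts_root.spawn(2 * config.n_per_group)]

    subjects: list[Subject] = []
    idx = 0
    for group in ("TD", "ASD"):
        cs = config.covariance_strength.get(group, {"global": 0.0, "block": 0.0})
        a_glob = cs.get("global", 0.0)
        a_block = cs.get("block", 0.0)
        for _ in range(config.n_per_group):
            # thickness: cohort-wide + per-block latent factors + private noise
            f_global = rng.standard_normal()
            f_block = rng.standard_normal(blocks.max() + 1)
            eps = rng.standard_normal(config.n_cortical)
            dev = (np.sqrt(a_glob) * f_global + np.sqrt(a_block) * f_block[blocks]
                   + np.sqrt(max(1.0 - a_glob - a_block, 0.0)) * eps)
            thickness = ctx_mu * (thick_eff if group == "ASD" else 1.0) \
                * (1.0 + config.thickness_noise_sd * dev)
            thickness = np.maximum(thickness, 0.2)

            vols = vol_mu * (vol_eff if group == "ASD" else 1.0) \
                * (1.0 + config.volume_noise_sd * rng.standard_normal(len(vol_mu)))
            vols = np.maximum(vols, 0.05 * vol_mu)
            supra = max(_SUPRATENTORIAL_MEAN * (1.0 + 0.05 * rng.standard_normal()),
                        1.2 * vols.max())

            subjects.append(Subject(
                id=f"sub-{idx:04d}",
                group=group,
                age=float(rng.uniform(8.0, 20.0)),
                sex="F" if rng.random() < 0.24 else "M",
                thickness=thickness,
                volumes=dict(zip(vol_names, vols.astype(float))),
                supratentorial=float(supra),
                ts_seed=ts_seeds[idx],
            ))
            idx += 1

    cohort = Cohort(
        subjects=subjects,
        cortical_regions=ctx_names,
        volume_regions=vol_names,
        roi_names=rois,
        homotopic_pairs=default_homotopic_pairs(config.n_roi),
        seed_sets=default_seed_sets(config.n_roi),
        config=config,
    )
    if timeseries:
        for s in cohort.subjects:
            s.timeseries = generate_timeseries(s, config)
    return cohort


def generate_phenotypes(cohort: Cohort, config: CohortConfig,
                        features: "pd.DataFrame | None" = None) -> Cohort:
    """Attach clinical scores coupled linearly to z-scored imaging features.

    ``features`` defaults to the canonical 22-feature table computed from the
    cohort itself; pass a precomputed table to avoid recomputation.
    """
    if features is None:
        from .integration import compute_feature_table
        features = compute_feature_table(cohort).data

    mu = features.mean(axis=0)
    sd = features.std(axis=0, ddof=0).replace(0.0, 1.0)
    z = (features - mu) / sd

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    n = len(cohort.subjects)
    for score, spec in config.phenotype_model.items():
        unknown = [f for f in spec.betas if f not in z.columns]
        if unknown:
            raise KeyError(f"phenotype model for {score!r} references unknown "
                           f"features: {unknown}")
        vals = np.full(n, float(spec.intercept))
        for f, beta in spec.betas.items():
            vals = vals + beta * z[f].to_numpy()
        vals = vals + spec.noise_sd * rng.standard_normal(n)
        vals = np.clip(vals, spec.minimum, spec.maximum)
        if spec.integer:
            vals = np.round(vals)
        miss = rng.random(n) < spec.missing_rate
        for s, v, m in zip(cohort.subjects, vals, miss):
            s.phenotypes[score] = float("nan") if m else float(v)
    return cohort


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Full simulation: anatomy + time series + phenotypes."""
    cohort = generate_cohort(config, timeseries=True)
    return generate_phenotypes(cohort, config)


# ---------------------------------------------------------------------------
# cohort directory I/O (all TSV/JSON)

def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    path = Path(path)
    (path / "timeseries").mkdir(parents=True, exist_ok=True)

    pheno_cols = sorted({k for s in cohort.subjects for k in s.phenotypes})
    rows = []
    for s in cohort.subjects:
        row = {"id": s.id, "group": s.group, "age": s.age, "sex": s.sex,
               "supratentorial": s.supratentorial}
        row.update({k: s.phenotypes.get(k, float("nan")) for k in pheno_cols})
        rows.append(row)
    pd.DataFrame(rows).set_index("id").to_csv(path / "subjects.tsv", sep="\t")

    pd.DataFrame(cohort.thickness_matrix(), index=[s.id for s in cohort.subjects],
                 columns=cohort.cortical_regions).to_csv(path / "thickness.tsv", sep="\t")
    cohort.volume_matrix().to_csv(path / "volumes.tsv", sep="\t")
    for s in cohort.subjects:
        if s.timeseries is not None:
            pd.DataFrame(s.timeseries, index=cohort.roi_names).to_csv(
                path / "timeseries" / f"{s.id}.tsv", sep="\t")

    meta = {
        "cortical_regions": cohort.cortical_regions,
        "volume_regions": cohort.volume_regions,
        "roi_names": cohort.roi_names,
        "homotopic_pairs": [list(p) for p in cohort.homotopic_pairs],
        "seed_sets": cohort.seed_sets,
        "config": cohort.config.to_dict(),
        "seed": cohort.config.seed,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_cohort(path: str | Path) -> Cohort:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    config = CohortConfig.from_dict(meta["config"])
    subjects_df = pd.read_csv(path / "subjects.tsv", sep="\t", index_col=0)
    thickness = pd.read_csv(path / "thickness.tsv", sep="\t", index_col=0)
    volumes = pd.read_csv(path / "volumes.tsv", sep="\t", index_col=0)

    base_cols = {"group", "age", "sex", "supratentorial"}
    subjects = []
    for sid, row in subjects_df.iterrows():
        ts_file = path / "timeseries" / f"{sid}.tsv"
        ts = pd.read_csv(ts_file, sep="\t", index_col=0).to_numpy() if ts_file.exists() else None
        phen = {k: float(v) for k, v in row.items() if k not in base_cols}
        subjects.append(Subject(
            id=str(sid), group=str(row["group"]), age=float(row["age"]),
            sex=str(row["sex"]), thickness=thickness.loc[sid].to_numpy(dtype=float),
            volumes={k: float(v) for k, v in volumes.loc[sid].items()},
            supratentorial=float(row["supratentorial"]),
            timeseries=ts, phenotypes=phen,
        ))
    return Cohort(
        subjects=subjects,
        cortical_regions=list(meta["cortical_regions"]),
        volume_regions=list(meta["volume_regions"]),
        roi_names=list(meta["roi_names"]),
        homotopic_pairs=[tuple(p) for p in meta["homotopic_pairs"]],
        seed_sets={k: list(v) for k, v in meta["seed_sets"].items()},
        config=config,
    )
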