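"""Group-level statistics: volume normalization, percentage change,
two-sample t-tests with Bonferroni correction, and feature-phenotype
correlations.

Regional volumes are normalized to the supratentorial volume with a x1000
scale factor before comparison. Percentage change between group means is
(V2 - V1)/V1 * 100 (ASD relative to TD). Regional tests use a x8 Bonferroni
factor (4 lobes in two hemispheres); phenotype correlations are corrected by
the number of score categories (x5) times the category's sub-domain count
(ADOS x10, IQ x3, ADI-R x5, SRS x7, VABS x15).
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sstats

REGION_BONFERRONI = 8          # 4 lobes x 2 hemispheres
N_SCORE_CATEGORIES = 5
SUBDOMAIN_FACTORS = {"ADOS": 10, "IQ": 3, "ADI-R": 5, "SRS": 7, "VABS": 15}

#: phenotype score name -> category, for the default synthetic score set
DEFAULT_SCORE_CATEGORIES = {
    "ados_total": "ADOS", "ados_module": "ADOS", "ados_social_affect": "ADOS",
    "ados_communication": "ADOS", "ados_research": "ADOS",
    "adir_total": "ADI-R",
    "iq_full": "IQ", "iq_verbal": "IQ", "iq_performance": "IQ",
    "srs_total": "SRS",
    "vabs_socialization": "VABS", "vabs_interpersonal": "VABS",
    "vabs_daily_living": "VABS",
}


@dataclass
class RegionComparison:
    region: str
    v1: float                  # control (TD) group mean
    v2: float                  # ASD group mean
    t: float
    p_raw: float
    p_corrected: float
    pct_change: float


@dataclass
class PhenotypeCorrelation:
    feature: str
    test: str
    category: str
    r: float
    p_raw: float
    p_corrected: float
    n: int


def normalize_volume(raw: float, supratentorial: float) -> float:
    """raw / supratentorial * 1000 (unitless)."""
    if supratentorial <= 0:
        raise ValueError("supratentorial volume must be positive")
    return raw / supratentorial * 1000.0


def percent_change(v1: float, v2: float) -> float:
    """(v2 - v1) / v1 * 100, reported to 3 decimals."""
    if v1 == 0:
        raise ValueError("reference mean v1 must be nonzero")
    return round((v2 - v1) / v1 * 100.0, 3)


def two_sample_t(a: np.ndarray, b: np.ndarray, variant: str = "pooled") -> tuple[float, float]:
    """Two-sided two-sample t-test (pooled variance by default, Welch by flag)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    t, p = sstats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(t), float(p)


def bonferroni(p: float, factor: int) -> float:
    """min(1, factor * p)."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    return min(1.0, factor * p)


def compare_regions(td: pd.DataFrame, asd: pd.DataFrame,
                    variant: str = "pooled",
                    factor: int = REGION_BONFERRONI) -> list[RegionComparison]:
    """Per-region group comparison of two (subjects x regions) tables.

    Suitable for normalized volumes or raw thickness; regions are compared
    TD (v1) versus ASD (v2) with Bonferroni correction and percentage change.
    """
    out = []
    for region in td.columns:
        a = td[region].to_numpy(dtype=float)
        b = asd[region].to_numpy(dtype=float)
        t, p = two_sample_t(a, b, variant=variant)
        out.append(RegionComparison(
            region=region, v1=float(a.mean()), v2=float(b.mean()),
            t=t, p_raw=p, p_corrected=bonferroni(p, factor),
            pct_change=percent_change(float(a.mean()), float(b.mean()))))
    return out


def phenotype_correlations(features: pd.DataFrame, phenotypes: pd.DataFrame,
                           categories: dict[str, str] | None = None,
                           min_pairs: int = 4) -> list[PhenotypeCorrelation]:
    """Pearson correlations of each (feature, score) pair with pairwise
    deletion of missing scores and category-specific Bonferroni correction
    (x5 categories x the category's sub-domain factor)."""
    if categories is None:
        categories = DEFAULT_SCORE_CATEGORIES
    common = features.index.intersection(phenotypes.index)
    feats = features.loc[common]
    phen = phenotypes.loc[common]
    out = []
    for test in phen.columns:
        cat = categories.get(test)
        if cat is None:
            raise KeyError(f"no category for phenotype test {test!r}")
        factor = N_SCORE_CATEGORIES * SUBDOMAIN_FACTORS[cat]
        y = phen[test]
        ok = y.notna()
        if int(ok.sum()) < min_pairs:
            raise ValueError(f"fewer than {min_pairs} complete pairs for {test!r}")
        for feature in feats.columns:
            x = feats.loc[ok, feature].to_numpy(dtype=float)
            yy = y[ok].to_numpy(dtype=float)
            if x.std() == 0 or yy.std() == 0:
                r, p = float("nan"), float("nan")
                pc = float("nan")
            else:
                r, p = sstats.pearsonr(x, yy)
                pc = bonferroni(float(p), factor)
            out.append(PhenotypeCorrelation(feature=feature, test=test,
                                            category=cat, r=float(r),
                                            p_raw=float(p), p_corrected=pc,
                                            n=int(ok.sum())))
    return out


def comparisons_frame(rows: list[RegionComparison]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])


def correlations_frame(rows: list[PhenotypeCorrelation]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])


def load_reference_table(which: str) -> pd.DataFrame:
    """Bundled reference group means for an ASD vs. TD comparison.

    ``which`` is "volume" (normalized regional volumes, unitless) or
    "thickness" (mm). Columns: region, v1 (TD mean), v2 (ASD mean),
    p (reported raw p), pct_change (reported percentage change). Used by
    the worked examples to exercise :func:`percent_change`.
    """
    name = {"volume": "reference_volumes.tsv",
            "thickness": "reference_thickness.tsv"}[which]
    with (resources.files("mpmri") / "data" / name).open() as fh:
        return pd.read_csv(fh, sep="\t")
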