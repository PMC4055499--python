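"""Regional group comparisons and feature-phenotype correlations.

Normalized-volume and thickness t-tests with the x8 Bonferroni factor, and
Pearson correlations of each imaging feature with each clinical score in
the ASD group, corrected by 5 x the category's sub-domain factor. Writes
results/regions.tsv and results/phenotype_correlations.tsv.
"""
from pathlib import Path

import pandas as pd

from mpmri.cohort import read_cohort
from mpmri.integration import FeatureTable
from mpmri.stats import (compare_regions, comparisons_frame,
                         correlations_frame, phenotype_correlations)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort = read_cohort(ROOT / "scratch" / "cohort")
    rows = compare_regions(cohort.volume_matrix("TD", normalized=True),
                           cohort.volume_matrix("ASD", normalized=True))
    th_td = pd.DataFrame(cohort.thickness_matrix("TD"), columns=cohort.cortical_regions)
    th_asd = pd.DataFrame(cohort.thickness_matrix("ASD"), columns=cohort.cortical_regions)
    rows += compare_regions(th_td, th_asd)
    regions = comparisons_frame(rows)
    regions.to_csv(ROOT / "results" / "regions.tsv", sep="\t", index=False,
                   float_format="%.4f")
    sig = regions[regions.p_corrected < 0.05].sort_values("p_raw")
    print("regions significant after x8 Bonferroni correction:")
    print(sig[["region", "v1", "v2", "pct_change", "p_corrected"]]
          .head(12).round(4).to_string(index=False))

    table = FeatureTable.read(ROOT / "results" / "features.tsv")
    phen_asd = cohort.phenotype_frame("ASD")
    corr = correlations_frame(
        phenotype_correlations(table.data.loc[phen_asd.index], phen_asd))
    corr.to_csv(ROOT / "results" / "phenotype_correlations.tsv", sep="\t",
                index=False, float_format="%.4f")
    sig = corr[corr.p_corrected < 0.05].sort_values("p_raw")
    print("\nfeature-phenotype correlations significant after correction:")
    print(sig[["feature", "test", "r", "p_corrected", "n"]]
          .head(12).round(4).to_string(index=False))


if __name__ == "__main__":
    main()
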