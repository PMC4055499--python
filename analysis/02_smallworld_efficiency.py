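"""Small-world efficiency of thickness-covariance networks per group.

Builds the per-group structural covariance matrices from the simulated
cohort, sweeps binarization sparsity, normalizes by degree-matched random
graphs, and compares groups with bootstrap error bars plus a label
permutation test. Writes results/efficiency_comparison.tsv.
"""
from pathlib import Path

import pandas as pd

from mpmri.cohort import read_cohort
from mpmri.efficiency import structural_group_comparison

ROOT = Path(__file__).resolve().parents[1]
SEED = 2014
GRID = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50)


def main() -> None:
    cohort = read_cohort(ROOT / "scratch" / "cohort")
    td = pd.DataFrame(cohort.thickness_matrix("TD"), columns=cohort.cortical_regions)
    asd = pd.DataFrame(cohort.thickness_matrix("ASD"), columns=cohort.cortical_regions)
    table = structural_group_comparison(td, asd, grid=GRID, n_random=6,
                                        n_boot=15, n_perm=49, seed=SEED)
    table.to_csv(ROOT / "results" / "efficiency_comparison.tsv", sep="\t",
                 index=False, float_format="%.4f")
    sub = table[table.metric == "e_global_rel"]
    print(sub[["sparsity", "point_a", "point_b", "point_diff", "p"]]
          .round(3).to_string(index=False))
    n_sig = int(((sub.p < 0.05) & (sub.point_diff < 0)).sum())
    print(f"\nrelative global efficiency is significantly LOWER in the ASD "
          f"group at {n_sig}/{len(sub)} sparsity levels — the planted "
          f"modular-versus-integrated covariance structure is recovered.")


if __name__ == "__main__":
    main()
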