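"""Choose the feature count by covariance SVD and select features by mRMR.

The component count holding 95% (and 99%) of the variance of the normalized
feature covariance fixes k; greedy mutual-information mRMR then picks the k
features. Writes results/selection.json.
"""
import json
from pathlib import Path

from mpmri.integration import (FeatureTable, component_count, mrmr_select,
                               variance_normalize)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    table = FeatureTable.read(ROOT / "results" / "features.tsv")
    labels = (table.groups == "ASD").astype(int).to_numpy()
    norm = variance_normalize(table)
    k95, k99 = component_count(norm, 0.95), component_count(norm, 0.99)
    print(f"components holding 95% / 99% of covariance: {k95} / {k99}")

    for k, tag in ((4, "4-feature"), (6, "6-feature")):
        sel = mrmr_select(table, labels, k)
        print(f"{tag} mRMR selection: {', '.join(sel.selected)}")
        if k == 6:
            sel.to_json(ROOT / "results" / "selection.json")
    extra = {"k95": k95, "k99": k99}
    (ROOT / "results" / "component_counts.json").write_text(json.dumps(extra))


if __name__ == "__main__":
    main()
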