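"""Two-group classification with the random-tree classifier.

Full-dataset, k-fold and percentage-split protocols on the mRMR-selected
features, plus the margin curve. Writes results/classification.tsv and
results/margin_curve.tsv.
"""
from pathlib import Path

import pandas as pd

from mpmri.integration import FeatureTable, SelectionResult
from mpmri.models import evaluate, fit_random_tree, margin_curve

ROOT = Path(__file__).resolve().parents[1]
SEED = 2014


def main() -> None:
    table = FeatureTable.read(ROOT / "results" / "features.tsv")
    sel = SelectionResult.from_json(ROOT / "results" / "selection.json")
    X = table.data[sel.selected].to_numpy(dtype=float)
    y = (table.groups == "ASD").astype(int).to_numpy()

    rows = []
    for protocol, param in (("full_dataset", None), ("kfold", 10),
                            ("percentage_split", 0.8)):
        rep = evaluate(X, y, protocol, param, seed=SEED)
        rows.append({"protocol": protocol, "param": param,
                     "accuracy": rep.accuracy})
        print(f"{protocol:17s} param={param!s:5s} accuracy={rep.accuracy:.3f}")
    pd.DataFrame(rows).to_csv(ROOT / "results" / "classification.tsv",
                              sep="\t", index=False)

    model = fit_random_tree(X, y, seed=SEED)
    curve = margin_curve(model, X, y)
    curve.frame().to_csv(ROOT / "results" / "margin_curve.tsv", sep="\t",
                         index=False)
    print("full-dataset training memorizes (accuracy 1.0 on consistent "
          "data); cross-validated accuracy is the honest generalization "
          "estimate.")


if __name__ == "__main__":
    main()
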