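#!/usr/bin/env python
"""Score the fitted model on the held-out third with the +/-5% criterion.

A prediction counts as correct when it lands within 5 percentage points of
the observed isopropanol elution concentration; accuracy is reported per
observed fraction and as their mean, alongside RMSE and R^2.

Run: python analysis/04_evaluate_accuracy.py
"""

import argparse
from pathlib import Path

import pandas as pd

from ciffrac import io as cio
from ciffrac import model as md

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--matrix", type=Path, default=ROOT / "results/matrix")
    ap.add_argument("--model", type=Path, default=ROOT / "results/model")
    ap.add_argument("--out", type=Path, default=ROOT / "results/model")
    ap.add_argument("--tolerance", type=float, default=5.0)
    args = ap.parse_args()

    X = pd.read_csv(args.matrix / "features_normalized.tsv", sep="\t",
                    index_col="Sequence")
    obs = pd.read_csv(args.matrix / "observations.tsv", sep="\t",
                      index_col="Sequence")["observed_conc"].astype(float)
    test_index = pd.read_csv(args.model / "test_index.tsv", sep="\t")["Sequence"]
    spec = cio.read_model(args.model / "model.json")

    report = md.evaluate(
        spec, X.loc[test_index], obs.loc[test_index],
        tolerance=args.tolerance, normalized=True,
    )
    report.as_frame().to_csv(args.out / "report.tsv", sep="\t", index=False)
    cio.write_manifest(args.out, {"script": "04_evaluate_accuracy",
                                  "tolerance": args.tolerance})

    print(f"test set: n = {report.n}")
    for conc, acc in sorted(report.per_fraction.items(), reverse=True):
        print(f"  {conc:.0f}% fraction: {acc:.2f}% within +/-{args.tolerance:.0f}")
    print(f"mean accuracy {report.accuracy:.2f}%  "
          f"RMSE {report.rmse:.2f}  R2 {report.r2:.3f}")


if __name__ == "__main__":
    main()
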