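#!/usr/bin/env python
"""Fit the Lasso elution model with tenfold CV and the one-SE rule.

Splits the matrix 2/3 train : 1/3 test, fits the L1 path over 100
log-spaced penalties, picks the most regularized model within one standard
error of the CV minimum, prunes minimally contributing features, and
writes model.json plus the CV path. Compares the surviving coefficients
with the generating reference model when ground truth is available.

Run: python analysis/03_fit_elution_model.py [--seed 1]
"""

import argparse
from pathlib import Path

import pandas as pd

from ciffrac import io as cio
from ciffrac import pipeline as pl
from ciffrac import preprocess as pp
from ciffrac.model import REFERENCE_MODEL

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--matrix", type=Path, default=ROOT / "results/matrix")
    ap.add_argument("--out", type=Path, default=ROOT / "results/model")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    X = pd.read_csv(args.matrix / "features_normalized.tsv", sep="\t",
                    index_col="Sequence")
    obs = pd.read_csv(args.matrix / "observations.tsv", sep="\t",
                      index_col="Sequence")["observed_conc"]
    bounds = pd.read_csv(args.matrix / "normalization_bounds.tsv", sep="\t",
                         index_col="feature")
    matrix = pp.ModelMatrix(X=X, y=obs.astype(float), bounds=bounds)

    result = pl.train_and_evaluate(matrix, seed=args.seed)
    out = args.out
    cio.write_model(result.spec, out / "model.json")
    result.cv.as_frame().to_csv(out / "cv.tsv", sep="\t", index=False)
    pd.DataFrame({"Sequence": result.test_index}).to_csv(
        out / "test_index.tsv", sep="\t", index=False
    )
    cio.write_manifest(out, {"script": "03_fit_elution_model", "seed": args.seed})

    print(f"selected lambda {result.spec.lam:.4g} "
          f"(CV minimum at {result.cv.alpha_min:.4g}); "
          f"{len(result.spec.coefficients)} features survive pruning")
    coefs = pd.Series(result.spec.coefficients, name="fitted").sort_values()
    comparison = pd.concat(
        [coefs, pd.Series(REFERENCE_MODEL.coefficients, name="reference")],
        axis=1,
    )
    print(f"intercept {result.spec.intercept:.2f} "
          f"(reference {REFERENCE_MODEL.intercept})")
    print(comparison.round(2).to_string())


if __name__ == "__main__":
    main()
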