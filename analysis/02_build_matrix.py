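#!/usr/bin/env python
"""Build the normalized model matrix from fraction-wise LFQ intensities.

Assigns each peptide the isopropanol concentration of its maximum LFQ
intensity across replicates and fractions (dropping 0%-wash and all-zero
rows), computes the 23 physicochemical predictors per retained sequence,
and Max-Min normalizes the full matrix, storing the bounds for later
prediction. Reads the tables written by 01_simulate_study.py (or any
MaxQuant-style peptides.txt plus sample key).

Run: python analysis/02_build_matrix.py
"""

import argparse
from pathlib import Path

from ciffrac import io as cio
from ciffrac import pipeline as pl
from ciffrac import preprocess as pp

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--study", type=Path, default=ROOT / "results/synthetic_study")
    ap.add_argument("--out", type=Path, default=ROOT / "results/matrix")
    args = ap.parse_args()

    key = cio.read_sample_key(args.study / "sample_key.tsv")
    lfq = cio.read_peptides_table(args.study / "peptides.txt", key)
    observed = pp.assign_elution_concentration(lfq)
    matrix = pl.build_matrix_from_lfq(lfq)

    out = args.out
    out.mkdir(parents=True, exist_ok=True)
    observed.rename("observed_conc").reset_index().to_csv(
        out / "observations.tsv", sep="\t", index=False
    )
    matrix.X.reset_index().to_csv(out / "features_normalized.tsv", sep="\t",
                                  index=False)
    matrix.bounds.reset_index(names="feature").to_csv(
        out / "normalization_bounds.tsv", sep="\t", index=False
    )
    cio.write_manifest(out, {"script": "02_build_matrix"},
                       inputs=[args.study / "peptides.txt"])

    print(f"matrix: {matrix.X.shape[0]} peptides x {matrix.X.shape[1]} "
          f"predictors (dropped {len(lfq) - len(observed)} of {len(lfq)} "
          f"rows as 0%-max or unobserved) -> {out}")
    print("observed fraction counts:")
    print(observed.value_counts().sort_index().to_string())


if __name__ == "__main__":
    main()
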