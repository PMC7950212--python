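#!/usr/bin/env python
"""Distribution index of PSM retention times, per fraction.

Bins each fraction's PSM retention times into 1-min bins over the 70-min
gradient and reports the overlap with a perfectly flat elution profile
(100% = perfectly even use of the gradient; 100/70 ~ 1.43% = everything in
one bin). Consumes the evidence.txt written by 01_simulate_study.py or any
MaxQuant-style evidence table.

Run: python analysis/05_distribution_index.py
"""

import argparse
from pathlib import Path

from ciffrac import evenness as dx
from ciffrac import io as cio

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--evidence", type=Path,
                    default=ROOT / "results/synthetic_study/evidence.txt")
    ap.add_argument("--out", type=Path, default=ROOT / "results/distribution_index.tsv")
    ap.add_argument("--gradient-length", type=float, default=70.0)
    ap.add_argument("--n-bins", type=int, default=70)
    args = ap.parse_args()

    table = cio.read_evidence(args.evidence)
    result = dx.per_fraction_distribution_index(
        table, gradient_length=args.gradient_length, n_bins=args.n_bins
    )
    args.out.parent.mkdir(parents=True, exist_ok=True)
    result.to_csv(args.out, sep="\t", index=False)
    print(result.round(2).to_string(index=False))
    print(f"-> {args.out}")


if __name__ == "__main__":
    main()
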