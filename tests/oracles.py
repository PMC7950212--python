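"""Independent brute-force oracles for the feature formulas.

Deliberately naive re-implementations (per-position loops, scipy root
finding, biopython's calculator where it implements the same published
formula) kept separate from the package's computation paths.
"""

from __future__ import annotations

from Bio.SeqUtils.ProtParam import ProteinAnalysis
from scipy.optimize import brentq

from ciffrac.features import DEFAULT_AA_CLASSES, LEHNINGER


def oracle_aliphatic_index(seq: str) -> float:
    n = len(seq)
    ala = val = ile = leu = 0
    for ch in seq:
        if ch == "A":
            ala += 1
        elif ch == "V":
            val += 1
        elif ch == "I":
            ile += 1
        elif ch == "L":
            leu += 1
    return (100.0 * ala / n) + 2.9 * (100.0 * val / n) + 3.9 * (
        100.0 * ile / n + 100.0 * leu / n
    )


def oracle_net_charge(seq: str, pH: float, pka=LEHNINGER) -> float:
    """Per-group Henderson-Hasselbalch summation, one term per residue."""
    def basic(pk):
        return 1.0 / (1.0 + 10.0 ** (pH - pk))

    def acidic(pk):
        return -1.0 / (1.0 + 10.0 ** (pk - pH))

    total = basic(pka.n_term) + acidic(pka.c_term)
    for ch in seq:
        if ch in pka.side_chains:
            pk = pka.side_chains[ch]
            total += basic(pk) if ch in pka.basic_side_chains else acidic(pk)
    return total


def oracle_isoelectric_point(seq: str, pka=LEHNINGER) -> float:
    return brentq(
        lambda pH: oracle_net_charge(seq, pH, pka), 1e-9, 14 - 1e-9, xtol=1e-13
    )


def oracle_instability_index(seq: str) -> float:
    return ProteinAnalysis(seq).instability_index()


def oracle_hydrophobicity(seq: str) -> float:
    return ProteinAnalysis(seq).gravy()


def oracle_composition(seq: str) -> dict:
    out = {}
    for cls, members in DEFAULT_AA_CLASSES.items():
        count = 0
        for ch in seq:
            if ch in members:
                count += 1
        out[f"{cls} No."] = float(count)
        out[f"{cls} mole %"] = 100.0 * count / len(seq)
    return out


def oracle_feature_vector(seq: str, pH: float = 7.0) -> dict:
    out = {
        "a-Index": oracle_aliphatic_index(seq),
        "Charge": oracle_net_charge(seq, pH),
        "pI": oracle_isoelectric_point(seq),
        "Instability index": oracle_instability_index(seq),
        "Hydrophobicity": oracle_hydrophobicity(seq),
    }
    out.update(oracle_composition(seq))
    return out
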