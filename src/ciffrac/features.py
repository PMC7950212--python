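"""Peptide physicochemical featurization.

Computes, from a bare amino-acid sequence, the 23 predictors used by the
elution model: five physicochemical properties (aliphatic index, net charge
at a configured pH, isoelectric point, instability index, GRAVY
hydrophobicity) and 18 composition parameters (count and mole percent of
nine residue classes).

All formulas are implemented here. Two published data tables are imported
as constants from biopython (`Bio.SeqUtils.ProtParamData`): the DIWV
dipeptide instability matrix and the Kyte-Doolittle hydropathy scale. Both
are swappable through the function arguments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import DIWV as _BIO_DIWV
from Bio.SeqUtils.ProtParamData import kd as _BIO_KD

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Kyte-Doolittle hydropathy values, complete over the 20 standard residues.
KYTE_DOOLITTLE: Mapping[str, float] = dict(_BIO_KD)

#: Guruprasad dipeptide instability weight values (DIWV), 20x20.
DIWV: Mapping[str, Mapping[str, float]] = {a: dict(row) for a, row in _BIO_DIWV.items()}


class InvalidResidueError(ValueError):
    """A sequence contains a character outside the 20 standard codes."""


def validate_sequence(seq: str, min_length: int = 1) -> str:
    """Check *seq* contains only upper-case standard residues; return it.

    Raises :class:`InvalidResidueError` naming the first offending character
    and its 1-based position, or ``ValueError`` if shorter than *min_length*.
    """
    if not isinstance(seq, str):
        raise TypeError(f"sequence must be a string, got {type(seq).__name__}")
    if len(seq) < min_length:
        raise ValueError(
            f"sequence {seq!r} has length {len(seq)}, need at least {min_length}"
        )
    for pos, ch in enumerate(seq, start=1):
        if ch not in _AA_INDEX:
            raise InvalidResidueError(
                f"invalid residue {ch!r} at position {pos} in sequence {seq!r}; "
                f"only the 20 standard one-letter codes are accepted"
            )
    return seq


# ---------------------------------------------------------------------------
# ionization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PKaTable:
    """Acid-dissociation constants for the nine ionizable groups of a peptide.

    ``basic`` names the groups that carry +1 when protonated (the N-terminus
    and H/K/R side chains); all others carry -1 when deprotonated.
    """

    n_term: float
    c_term: float
    side_chains: Mapping[str, float]  # residue -> pKa, for D E C Y H K R
    basic_side_chains: frozenset = frozenset({"H", "K", "R"})

    def __post_init__(self) -> None:
        expected = {"D", "E", "C", "Y", "H", "K", "R"}
        if set(self.side_chains) != expected:
            raise ValueError(
                f"side-chain pKa table must cover exactly {sorted(expected)}, "
                f"got {sorted(self.side_chains)}"
            )
        for name, value in self.items():
            if not 0.0 < value < 14.0:
                raise ValueError(f"pKa for {name} out of (0, 14): {value}")

    def items(self):
        yield "n_term", self.n_term
        yield "c_term", self.c_term
        yield from self.side_chains.items()


#: Lehninger textbook pKa values (the default scale of common property
#: calculators); swap via the ``pka`` argument of the charge/pI functions.
LEHNINGER = PKaTable(
    n_term=9.69,
    c_term=2.34,
    side_chains={
        "D": 3.65,
        "E": 4.25,
        "C": 8.18,
        "Y": 10.07,
        "H": 6.00,
        "K": 10.53,
        "R": 12.48,
    },
)


def _ionizable_counts(seq: str, pka: PKaTable) -> tuple[list, list]:
    """(basic, acidic) lists of (count, pKa) pairs for one sequence."""
    basic = [(1.0, pka.n_term)]
    acidic = [(1.0, pka.c_term)]
    for res, value in pka.side_chains.items():
        n = seq.count(res)
        if n == 0:
            continue
        if res in pka.basic_side_chains:
            basic.append((float(n), value))
        else:
            acidic.append((float(n), value))
    return basic, acidic


def net_charge(seq: str, pH: float = 7.0, pka: PKaTable = LEHNINGER) -> float:
    """Net charge (elementary charges) by Henderson-Hasselbalch summation.

    charge = sum over basic groups of 1/(1+10^(pH-pKa))
           - sum over acidic groups of 1/(1+10^(pKa-pH)).
    """
    validate_sequence(seq)
    if not 0.0 < pH < 14.0:
        raise ValueError(f"pH must be in (0, 14), got {pH}")
    basic, acidic = _ionizable_counts(seq, pka)
    pos = sum(n / (1.0 + 10.0 ** (pH - p)) for n, p in basic)
    neg = sum(n / (1.0 + 10.0 ** (p - pH)) for n, p in acidic)
    return pos - neg


def isoelectric_point(seq: str, pka: PKaTable = LEHNINGER) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    Net charge is strictly decreasing in pH and both termini always ionize,
    so a unique root exists; 64 bisection steps locate it to machine precision.
    """
    validate_sequence(seq)
    lo, hi = 0.0, 14.0
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pka) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# scalar properties
# ---------------------------------------------------------------------------

def aliphatic_index(seq: str) -> float:
    """Ikai aliphatic index: X_Ala + 2.9 X_Val + 3.9 (X_Ile + X_Leu).

    X are mole percentages; the coefficients are the side-chain volumes of
    V and I/L relative to A.
    """
    validate_sequence(seq)
    n = len(seq)
    x = {aa: 100.0 * seq.count(aa) / n for aa in "AVIL"}
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


def instability_index(
    seq: str, table: Mapping[str, Mapping[str, float]] = DIWV
) -> float:
    """Guruprasad instability index: (10/L) * sum of DIWV over dipeptides."""
    validate_sequence(seq, min_length=2)
    total = 0.0
    for a, b in zip(seq, seq[1:]):
        total += table[a][b]
    return 10.0 / len(seq) * total


def hydrophobicity(seq: str, scale: Mapping[str, float] = KYTE_DOOLITTLE) -> float:
    """GRAVY: arithmetic mean of the per-residue hydropathy values."""
    validate_sequence(seq)
    return sum(scale[a] for a in seq) / len(seq)


# ---------------------------------------------------------------------------
# composition classes
# ---------------------------------------------------------------------------

#: Nine (overlapping) residue classes; nonpolar and polar partition the 20
#: standard residues, charged = basic + acidic.
DEFAULT_AA_CLASSES: Mapping[str, frozenset] = {
    "Tiny": frozenset("ACGST"),
    "Small": frozenset("ACDGNPSTV"),
    "Aliphatic": frozenset("AILV"),
    "Aromatic": frozenset("FHWY"),
    "Nonpolar": frozenset("ACFGILMPVWY"),
    "Polar": frozenset("DEHKNQRST"),
    "Charged": frozenset("DEHKR"),
    "Basic": frozenset("HKR"),
    "Acidic": frozenset("DE"),
}

CLASS_ORDER = list(DEFAULT_AA_CLASSES)

#: Canonical names and order of the 23 model predictors.
FEATURE_NAMES: tuple = tuple(
    ["a-Index", "Charge", "pI", "Instability index", "Hydrophobicity"]
    + [name for cls in CLASS_ORDER for name in (f"{cls} No.", f"{cls} mole %")]
)


def aa_composition(
    seq: str, classes: Mapping[str, frozenset] = DEFAULT_AA_CLASSES
) -> dict:
    """Count and mole percent of each residue class: 18 named values."""
    validate_sequence(seq)
    n = len(seq)
    out: dict = {}
    for cls, members in classes.items():
        count = sum(1 for a in seq if a in members)
        out[f"{cls} No."] = float(count)
        out[f"{cls} mole %"] = 100.0 * count / n
    return out


# ---------------------------------------------------------------------------
# full feature vector
# ---------------------------------------------------------------------------

def featurize(
    seq: str,
    pH: float = 7.0,
    pka: PKaTable = LEHNINGER,
    hydro_scale: Mapping[str, float] = KYTE_DOOLITTLE,
    classes: Mapping[str, frozenset] = DEFAULT_AA_CLASSES,
) -> pd.Series:
    """The 23-entry feature vector of one peptide, canonically named/ordered."""
    validate_sequence(seq, min_length=2)
    values = {
        "a-Index": aliphatic_index(seq),
        "Charge": net_charge(seq, pH, pka),
        "pI": isoelectric_point(seq, pka),
        "Instability index": instability_index(seq),
        "Hydrophobicity": hydrophobicity(seq, hydro_scale),
    }
    values.update(aa_composition(seq, classes))
    return pd.Series([values[name] for name in FEATURE_NAMES],
                     index=list(FEATURE_NAMES), name=seq, dtype=float)


# Vectorized path. `featurize_many` reproduces `featurize` bit-identically
# (both reduce to the same float operations on residue counts) and is the one
# the pipeline uses at scale.

_DIWV_MATRIX = np.array(
    [[DIWV[a][b] for b in AMINO_ACIDS] for a in AMINO_ACIDS], dtype=float
)
_KD_VECTOR = np.array([KYTE_DOOLITTLE[a] for a in AMINO_ACIDS], dtype=float)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


_CODE_TO_INDEX = np.full(128, -1, dtype=np.int64)
for _aa, _i in _AA_INDEX.items():
    _CODE_TO_INDEX[ord(_aa)] = _i


def residue_counts(seqs: Sequence[str]) -> np.ndarray:
    """(n_peptides, 20) matrix of residue counts, columns in AMINO_ACIDS order."""
    out = np.zeros((len(seqs), 20), dtype=float)
    for i, seq in enumerate(seqs):
        idx = _CODE_TO_INDEX[_encode(seq)]
        np.add.at(out[i], idx, 1.0)
    return out


def _charge_from_counts(
    counts: np.ndarray, pH: np.ndarray | float, pka: PKaTable
) -> np.ndarray:
    pH = np.asarray(pH, dtype=float)
    pos = 1.0 / (1.0 + 10.0 ** (pH - pka.n_term))
    neg = 1.0 / (1.0 + 10.0 ** (pka.c_term - pH))
    for res, pk in pka.side_chains.items():
        n = counts[:, _AA_INDEX[res]]
        if res in pka.basic_side_chains:
            pos = pos + n / (1.0 + 10.0 ** (pH - pk))
        else:
            neg = neg + n / (1.0 + 10.0 ** (pk - pH))
    return pos - neg


def featurize_many(
    seqs: Sequence[str],
    pH: float = 7.0,
    pka: PKaTable = LEHNINGER,
    hydro_scale: Mapping[str, float] = KYTE_DOOLITTLE,
    classes: Mapping[str, frozenset] = DEFAULT_AA_CLASSES,
) -> pd.DataFrame:
    """Feature matrix (rows = peptides, 23 canonical columns) for many peptides."""
    seqs = list(seqs)
    for s in seqs:
        validate_sequence(s, min_length=2)
    counts = residue_counts(seqs)
    lengths = counts.sum(axis=1)

    mole = 100.0 * counts / lengths[:, None]
    a_index = (
        mole[:, _AA_INDEX["A"]]
        + 2.9 * mole[:, _AA_INDEX["V"]]
        + 3.9 * (mole[:, _AA_INDEX["I"]] + mole[:, _AA_INDEX["L"]])
    )
    gravy = counts @ _KD_VECTOR / lengths
    charge = _charge_from_counts(counts, pH, pka)

    # pI by vectorized bisection (charge is strictly decreasing in pH)
    lo = np.zeros(len(seqs))
    hi = np.full(len(seqs), 14.0)
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        positive = _charge_from_counts(counts, mid, pka) > 0.0
        lo = np.where(positive, mid, lo)
        hi = np.where(positive, hi, mid)
    pi = 0.5 * (lo + hi)

    instab = np.empty(len(seqs))
    for i, seq in enumerate(seqs):
        idx = _CODE_TO_INDEX[_encode(seq)]
        instab[i] = _DIWV_MATRIX[idx[:-1], idx[1:]].sum() * 10.0 / len(seq)

    data = {
        "a-Index": a_index,
        "Charge": charge,
        "pI": pi,
        "Instability index": instab,
        "Hydrophobicity": gravy,
    }
    for cls, members in classes.items():
        member_idx = [_AA_INDEX[a] for a in members]
        n = counts[:, member_idx].sum(axis=1)
        data[f"{cls} No."] = n
        data[f"{cls} mole %"] = 100.0 * n / lengths

    return pd.DataFrame(data, index=pd.Index(seqs, name="Sequence"),
                        columns=list(FEATURE_NAMES))
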