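"""Synthetic tryptic-peptide study sets for exercising the pipeline.

Emulates the statistical structure the analysis assumes: a tryptic digest
of a proteome-like protein population; a ground-truth elution concentration
per peptide generated by the published nine-variable model plus Gaussian
noise (sd defaulting to the reported model RMSE of 3.82%); fraction-wise
LFQ intensity tables peaked at the true fraction with configurable
carryover into adjacent fractions; and per-fraction retention-time sets
over a 70-min gradient.

Every generator is a pure function of (seed, parameters); a sample-set seed
fans out to independent substreams per stage, so stages are individually
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import parser as _pyt_parser

from .features import AMINO_ACIDS, featurize_many
from .model import REFERENCE_MODEL, ElutionModelSpec, predict, snap_to_fractions
from .preprocess import ELUTION_CONCENTRATIONS, make_lfq_columns

#: Trypsin: cleave C-terminal to K/R, suppressed before proline.
TRYPSIN_RULE = r"(?<=[KR])(?!P)"

#: Average human proteome residue frequencies (mole fraction), normalized to 1.
_RAW_FREQ = {
    "A": 7.01, "R": 5.64, "N": 3.59, "D": 4.74, "C": 2.30,
    "Q": 4.77, "E": 7.10, "G": 6.58, "H": 2.63, "I": 4.33,
    "L": 9.97, "K": 5.72, "M": 2.13, "F": 3.65, "P": 6.31,
    "S": 8.33, "T": 5.36, "W": 1.22, "Y": 2.66, "V": 5.96,
}
_TOTAL = sum(_RAW_FREQ.values())
HUMAN_AA_FREQUENCIES: Mapping[str, float] = {
    aa: _RAW_FREQ[aa] / _TOTAL for aa in AMINO_ACIDS
}


def _check_frequencies(freqs: Mapping[str, float]) -> np.ndarray:
    if set(freqs) != set(AMINO_ACIDS):
        raise ValueError("aa_frequencies must cover exactly the 20 standard residues")
    p = np.array([freqs[a] for a in AMINO_ACIDS], dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"aa_frequencies must sum to 1 (got {p.sum():.12f})")
    return p


def _default_lengths(rng: np.random.Generator, n: int) -> np.ndarray:
    # lognormal protein lengths, median ~375 residues, clipped to [60, 2000]
    return np.clip(rng.lognormal(np.log(375.0), 0.55, n), 60, 2000).astype(int)


def generate_proteins(
    n: int,
    length_distribution: int | Sequence[int] | Callable | None = None,
    aa_frequencies: Mapping[str, float] = HUMAN_AA_FREQUENCIES,
    seed=None,
) -> list:
    """Random protein records [(id, sequence), ...], reproducible given seed.

    *length_distribution* may be a fixed integer, a sequence of n lengths,
    or a callable ``(rng, n) -> lengths``; default is a lognormal typical of
    proteome length distributions.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    p = _check_frequencies(aa_frequencies)
    rng = np.random.default_rng(seed)
    if length_distribution is None:
        lengths = _default_lengths(rng, n)
    elif callable(length_distribution):
        lengths = np.asarray(length_distribution(rng, n), dtype=int)
    elif np.ndim(length_distribution) == 0:
        lengths = np.full(n, int(length_distribution))
    else:
        lengths = np.asarray(length_distribution, dtype=int)
        if len(lengths) != n:
            raise ValueError("length_distribution sequence must have n entries")
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    records = []
    for i, L in enumerate(lengths):
        seq = alphabet[rng.choice(20, size=int(L), p=p)].tobytes().decode()
        records.append((f"SYN{i + 1:05d}", seq))
    return records


@dataclass(frozen=True)
class DigestionParams:
    """Tryptic digestion settings (cleave after K/R, not before P)."""

    missed_cleavages: int = 2
    min_length: int = 7
    max_length: int = 40

    def __post_init__(self) -> None:
        if not 0 <= self.missed_cleavages <= 2:
            raise ValueError("missed_cleavages must be 0-2")
        if not 0 < self.min_length <= self.max_length:
            raise ValueError("length bounds must be positive and ordered")


def digest(sequence: str, params: DigestionParams = DigestionParams()) -> list:
    """Tryptic peptides of one protein, N-to-C ordered, length-filtered."""
    peptides = [
        pep
        for _, pep in _pyt_parser.icleave(
            sequence, TRYPSIN_RULE, missed_cleavages=params.missed_cleavages
        )
        if params.min_length <= len(pep) <= params.max_length
    ]
    return peptides


def digest_proteome(
    proteins: Sequence, params: DigestionParams = DigestionParams()
) -> list:
    """Unique peptides over a protein list, first-occurrence order."""
    seen = {}
    for _, seq in proteins:
        for pep in digest(seq, params):
            seen.setdefault(pep, None)
    return list(seen)


def label_elution(
    peptides: Sequence[str],
    spec: ElutionModelSpec = REFERENCE_MODEL,
    noise_sd: float = 3.82,
    seed=None,
    pH: float = 7.0,
) -> tuple[pd.DataFrame, ElutionModelSpec]:
    """Ground-truth elution labels from the reference model plus noise.

    Features are computed for the peptide population, Max-Min bounds are
    fit on that population and attached to *spec*; the latent elution value
    is the model prediction plus Gaussian(0, noise_sd), and the observed
    fraction is the nearest of {90, 85, 80, 75, 70}.

    Returns (observations, bounded_spec); observations is indexed by
    sequence with columns ``latent`` and ``observed_conc``.
    """
    peptides = list(dict.fromkeys(peptides))  # dedupe, keep order
    if not peptides:
        raise ValueError("no peptides to label")
    raw = featurize_many(peptides, pH=pH)
    bounds = pd.DataFrame({"min": raw.min(axis=0), "max": raw.max(axis=0)})
    bounded = spec.with_bounds(bounds)
    rng = np.random.default_rng(seed)
    latent = np.asarray(predict(bounded, raw), dtype=float)
    if noise_sd > 0:
        latent = latent + rng.normal(0.0, noise_sd, len(peptides))
    observed = snap_to_fractions(latent)
    obs = pd.DataFrame(
        {"latent": latent, "observed_conc": observed.astype(int)},
        index=pd.Index(peptides, name="Sequence"),
    )
    return obs, bounded


def render_lfq(
    observations: pd.DataFrame,
    replicates: int = 3,
    carryover: float = 0.2,
    seed=None,
    log_intensity_mean: float = np.log(1e7),
    log_intensity_sigma: float = 1.0,
    noise_sigma: float = 0.1,
) -> pd.DataFrame:
    """LFQ intensity table peaked at each peptide's true fraction.

    Per replicate, the true fraction receives share (1 - carryover) of the
    peptide's intensity and each adjacent elution step receives
    carryover / 2; at the 90% and 70% edges the share that would spill
    outside the collected window is lost (eluted outside the gradient), and
    the 0% column stays empty. Multiplicative log-normal noise is truncated
    at +/- 3 sigma, so with the default ``noise_sigma`` the worst-case noise
    distortion e^(6 sigma) < 2 <= (1 - c)/(c / 2) and the fraction-wise
    argmax provably equals the true fraction for any carryover c < 0.5.
    """
    if not 0.0 <= carryover < 0.5:
        raise ValueError(f"carryover must be in [0, 0.5), got {carryover}")
    concs = list(ELUTION_CONCENTRATIONS)
    true = observations["observed_conc"].to_numpy()
    n = len(observations)

    share = np.zeros((n, len(concs)))
    pos = np.array([concs.index(int(c)) for c in true])
    share[np.arange(n), pos] = 1.0 - carryover
    for i, p in enumerate(pos):
        for q in (p - 1, p + 1):
            if 0 <= q < len(concs):
                share[i, q] = carryover / 2.0

    rng = np.random.default_rng(seed)
    base = np.exp(rng.normal(log_intensity_mean, log_intensity_sigma, n))
    columns = make_lfq_columns(replicates=replicates)
    table = np.zeros((n, len(columns)))
    col_list = list(columns)
    for j, (conc, rep) in enumerate(col_list):
        if conc == 0:
            continue
        k = concs.index(conc)
        z = np.clip(rng.standard_normal(n), -3.0, 3.0)
        table[:, j] = base * share[:, k] * np.exp(noise_sigma * z)
    return pd.DataFrame(table, index=observations.index.copy(), columns=columns)


def render_retention_times(
    n_psms: int,
    shape: str = "uniform",
    gradient_length: float = 70.0,
    seed=None,
    centers: Sequence[float] | None = None,
    widths: Sequence[float] | None = None,
    weights: Sequence[float] | None = None,
) -> np.ndarray:
    """Retention times (minutes) for one fraction's PSMs.

    ``shape="uniform"`` draws uniformly over the gradient (distribution
    index -> 100% as n grows); ``shape="gaussian"`` draws from a Gaussian
    mixture (a single narrow component gives a low index).
    """
    if n_psms < 1:
        raise ValueError(f"n_psms must be >= 1, got {n_psms}")
    rng = np.random.default_rng(seed)
    if shape == "uniform":
        return rng.uniform(0.0, gradient_length, n_psms)
    if shape == "gaussian":
        centers = np.asarray(
            [gradient_length / 2.0] if centers is None else centers, dtype=float
        )
        widths = np.asarray(
            [gradient_length / 14.0] if widths is None else widths, dtype=float
        )
        weights = (
            np.full(len(centers), 1.0 / len(centers))
            if weights is None
            else np.asarray(weights, dtype=float) / np.sum(weights)
        )
        comp = rng.choice(len(centers), size=n_psms, p=weights)
        rts = rng.normal(centers[comp], widths[comp])
        return np.clip(rts, 0.0, gradient_length)
    raise ValueError(f"unknown shape {shape!r}; use 'uniform' or 'gaussian'")


@dataclass
class SyntheticSampleSet:
    """One complete simulated study: proteins, labels, LFQ table, RTs."""

    proteins: list
    observations: pd.DataFrame  # sequence -> latent, observed_conc
    spec: ElutionModelSpec  # generating model with population bounds
    lfq: pd.DataFrame
    retention_times: dict  # fraction label -> np.ndarray of minutes
    seed: int | None
    params: dict = field(default_factory=dict)


def generate_sample_set(
    n_proteins: int = 200,
    target_n_peptides: int | None = None,
    seed: int | None = None,
    digestion: DigestionParams = DigestionParams(),
    noise_sd: float = 3.82,
    carryover: float = 0.2,
    replicates: int = 3,
    n_psms_per_fraction: int = 5000,
    rt_shape: str = "uniform",
    gradient_length: float = 70.0,
) -> SyntheticSampleSet:
    """End-to-end simulated study set, bit-reproducible from (seed, params).

    With *target_n_peptides*, protein batches are generated until the
    unique-peptide count reaches the target, then truncated to it.
    """
    ss = np.random.SeedSequence(seed)
    s_prot, s_label, s_lfq, s_rt = ss.spawn(4)

    prot_children = s_prot.spawn(64)
    proteins: list = []
    peptides: list = []
    batch = 0
    while True:
        proteins.extend(
            generate_proteins(n_proteins, seed=prot_children[batch])
        )
        peptides = digest_proteome(proteins, digestion)
        batch += 1
        if target_n_peptides is None or len(peptides) >= target_n_peptides:
            break
        if batch >= len(prot_children):
            raise RuntimeError("could not reach target_n_peptides; raise n_proteins")
    if target_n_peptides is not None:
        peptides = peptides[:target_n_peptides]

    observations, bounded_spec = label_elution(
        peptides, noise_sd=noise_sd, seed=s_label
    )
    lfq = render_lfq(observations, replicates=replicates, carryover=carryover, seed=s_lfq)
    rt_children = s_rt.spawn(len(ELUTION_CONCENTRATIONS))
    retention_times = {
        f"CIF{conc}": render_retention_times(
            n_psms_per_fraction, rt_shape, gradient_length, seed=child
        )
        for conc, child in zip(ELUTION_CONCENTRATIONS, rt_children)
    }
    return SyntheticSampleSet(
        proteins=proteins,
        observations=observations,
        spec=bounded_spec,
        lfq=lfq,
        retention_times=retention_times,
        seed=seed,
        params={
            "n_proteins": n_proteins,
            "target_n_peptides": target_n_peptides,
            "digestion": digestion,
            "noise_sd": noise_sd,
            "carryover": carryover,
            "replicates": replicates,
            "n_psms_per_fraction": n_psms_per_fraction,
            "rt_shape": rt_shape,
            "gradient_length": gradient_length,
        },
    )
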