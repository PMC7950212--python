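"""Readers and writers: MaxQuant-style tables, FASTA, model JSON, manifests.

Tables are tab-separated UTF-8 with a header row; MaxQuant column names are
matched case-insensitively. A *sample key* (TSV or JSON) maps each LFQ
sample name to its isopropanol concentration and replicate id.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from importlib import metadata as _im
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import ElutionModelSpec
from .preprocess import ALL_CONCENTRATIONS

log = logging.getLogger(__name__)

LFQ_PREFIX = "lfq intensity "


def _find_column(columns, wanted: str) -> str:
    for c in columns:
        if c.lower() == wanted.lower():
            return c
    raise ValueError(f"required column {wanted!r} not found (have {list(columns)})")


# ---------------------------------------------------------------------------
# sample key
# ---------------------------------------------------------------------------

def read_sample_key(path) -> pd.DataFrame:
    """Sample-name -> (isopropanol %, replicate) mapping from TSV or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        frame = pd.DataFrame(json.loads(path.read_text()))
    else:
        frame = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in frame.columns}
    for needed in ("sample_name", "isopropanol_percent", "replicate"):
        if needed not in cols:
            raise ValueError(f"sample key lacks column {needed!r}")
    frame = frame.rename(columns={cols[k]: k for k in cols})
    frame["isopropanol_percent"] = frame["isopropanol_percent"].astype(int)
    frame["replicate"] = frame["replicate"].astype(int)
    bad = set(frame["isopropanol_percent"]) - set(ALL_CONCENTRATIONS)
    if bad:
        raise ValueError(f"sample key has unknown concentrations: {sorted(bad)}")
    return frame[["sample_name", "isopropanol_percent", "replicate"]]


def write_sample_key(frame: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MaxQuant-style peptides.txt
# ---------------------------------------------------------------------------

def read_peptides_table(path, sample_key: pd.DataFrame) -> pd.DataFrame:
    """LFQ table from a peptides.txt-style TSV.

    Requires a ``Sequence`` column and one ``LFQ intensity <sample>`` column
    per sample-key row; returns a frame indexed by sequence with
    (isopropanol %, replicate) MultiIndex columns, missing intensities as 0.
    """
    frame = pd.read_csv(path, sep="\t")
    seq_col = _find_column(frame.columns, "Sequence")
    lower = {c.lower(): c for c in frame.columns}
    data = {}
    for row in sample_key.itertuples(index=False):
        wanted = f"{LFQ_PREFIX}{row.sample_name}".lower()
        if wanted not in lower:
            raise ValueError(
                f"column 'LFQ intensity {row.sample_name}' not found in {path}"
            )
        data[(row.isopropanol_percent, row.replicate)] = (
            pd.to_numeric(frame[lower[wanted]], errors="coerce")
            .fillna(0.0)
            .to_numpy()
        )
    out = pd.DataFrame(data, index=frame[seq_col].str.upper())
    out.index.name = "Sequence"
    out.columns = pd.MultiIndex.from_tuples(
        out.columns, names=["isopropanol_percent", "replicate"]
    )
    return out


def write_peptides_table(lfq: pd.DataFrame, path) -> pd.DataFrame:
    """Write an LFQ table as MaxQuant-style peptides.txt; return its sample key."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = pd.DataFrame(index=lfq.index)
    key_rows = []
    for conc, rep in lfq.columns:
        sample = f"C{conc:02d}_R{rep}"
        out[f"LFQ intensity {sample}"] = lfq[(conc, rep)].to_numpy()
        key_rows.append(
            {"sample_name": sample, "isopropanol_percent": conc, "replicate": rep}
        )
    out.reset_index().to_csv(path, sep="\t", index=False)
    return pd.DataFrame(key_rows)


# ---------------------------------------------------------------------------
# evidence.txt (PSM retention times)
# ---------------------------------------------------------------------------

def read_evidence(
    path, rt_column: str = "Retention time", fraction_column: str = "Raw file"
) -> pd.DataFrame:
    """PSM table with retention times; column names matched case-insensitively."""
    frame = pd.read_csv(path, sep="\t")
    rt = _find_column(frame.columns, rt_column)
    frac = _find_column(frame.columns, fraction_column)
    return frame.rename(columns={rt: rt_column, frac: fraction_column})


def write_evidence(retention_times: dict, path) -> None:
    """Write per-fraction retention-time arrays as an evidence-style TSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for fraction, rts in retention_times.items():
        rows.append(
            pd.DataFrame({"Raw file": fraction, "Retention time": np.asarray(rts)})
        )
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequences, features
# ---------------------------------------------------------------------------

def read_sequences(path) -> list:
    """Peptide sequences from a one-per-line text file or a TSV with `Sequence`."""
    path = Path(path)
    first = path.read_text().splitlines()
    if not first:
        raise ValueError(f"{path} is empty")
    if "\t" in first[0] or first[0].strip().lower() == "sequence":
        frame = pd.read_csv(path, sep="\t")
        col = _find_column(frame.columns, "Sequence")
        return [str(s).upper() for s in frame[col]]
    return [line.strip().upper() for line in first if line.strip()]


def write_features(features: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    features.reset_index().to_csv(path, sep="\t", index=False)


def write_fasta(records, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="synthetic") for name, seq in records),
        str(path),
        "fasta",
    )


def read_fasta(path) -> list:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# model spec JSON
# ---------------------------------------------------------------------------

def model_to_dict(spec: ElutionModelSpec) -> dict:
    bounds = None
    if spec.normalization_bounds is not None:
        bounds = {
            name: [float(row["min"]), float(row["max"])]
            for name, row in spec.normalization_bounds.iterrows()
        }
    return {
        "intercept": spec.intercept,
        "coefficients": dict(spec.coefficients),
        "lambda": spec.lam,
        "normalization_bounds": bounds,
        "provenance": spec.provenance,
    }


def write_model(spec: ElutionModelSpec, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(model_to_dict(spec), indent=2, sort_keys=True))


def read_model(path) -> ElutionModelSpec:
    payload = json.loads(Path(path).read_text())
    bounds = payload.get("normalization_bounds")
    bounds_frame = None
    if bounds:
        bounds_frame = pd.DataFrame(
            {name: {"min": lo, "max": hi} for name, (lo, hi) in bounds.items()}
        ).T[["min", "max"]]
    return ElutionModelSpec(
        intercept=float(payload["intercept"]),
        coefficients={k: float(v) for k, v in payload["coefficients"].items()},
        lam=payload.get("lambda"),
        normalization_bounds=bounds_frame,
        provenance=payload.get("provenance", "trained"),
    )


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: dict, inputs=()) -> Path:
    """JSON run manifest: config, seed, versions, input checksums."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        version = _im.version("ciffrac")
    except _im.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    manifest = {
        "config": {k: repr(v) if not _jsonable(v) else v for k, v in config.items()},
        "versions": {
            "ciffrac": version,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "inputs": {str(p): _sha256(p) for p in inputs if Path(p).is_file()},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _jsonable(value) -> bool:
    try:
        json.dumps(value)
        return True
    except TypeError:
        return False
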