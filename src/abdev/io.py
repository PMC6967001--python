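"""Reading and validating antibody sequence and measurement inputs.

Sequences arrive either as FASTA or as a two/three-column table. The FASTA
pairing convention is ``><id>|VH`` / ``><id>|VL`` for separate chains, or a
single ``><id>`` record holding a pre-concatenated Fv (VH followed by VL).
Measurements are a CSV/TSV with an ``id`` column plus any subset of the 12
platform columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .config import AMINO_ACIDS, canonical_platform
from .errors import JoinError, PairingError, SequenceError

_VALID = set(AMINO_ACIDS)


@dataclass
class FvRecord:
    """One antibody: id, heavy/light variable-domain chains, concatenated Fv.

    ``vh``/``vl`` may be empty strings when only the pre-concatenated Fv is
    known; ``fv`` is always populated and equals ``vh + vl`` when both chains
    are present.
    """

    id: str
    vh: str = ""
    vl: str = ""
    fv: str = ""
    stage: str | None = None

    def __post_init__(self) -> None:
        self.vh = _validate_sequence(self.vh, self.id, allow_empty=True)
        self.vl = _validate_sequence(self.vl, self.id, allow_empty=True)
        if not self.fv and (self.vh or self.vl):
            self.fv = self.vh + self.vl
        self.fv = _validate_sequence(self.fv, self.id)
        if self.vh and self.vl and self.fv != self.vh + self.vl:
            raise SequenceError(
                f"{self.id}: fv must be the concatenation of vh and vl"
            )


@dataclass
class Dataset:
    """Fv records joined with a per-platform measurement table.

    ``measurements`` is indexed by record id with one column per canonical
    platform id; missing values are permitted.
    """

    records: list[FvRecord]
    measurements: pd.DataFrame
    platform_config: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def record(self, rid: str) -> FvRecord:
        for rec in self.records:
            if rec.id == rid:
                return rec
        raise KeyError(rid)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def _validate_sequence(seq: str, rid: str, allow_empty: bool = False) -> str:
    if seq is None:
        seq = ""
    seq = str(seq).strip().upper()
    if not seq:
        if allow_empty:
            return ""
        raise SequenceError(f"{rid}: empty sequence")
    for pos, ch in enumerate(seq):
        if ch not in _VALID:
            raise SequenceError(
                f"{rid}: non-canonical amino-acid character {ch!r} at "
                f"position {pos}"
            )
    return seq


def read_sequences(path: str | Path, format: str = "fasta") -> list[FvRecord]:
    """Read FvRecords from a FASTA file or a delimited table.

    FASTA headers ``<id>|VH`` and ``<id>|VL`` are paired into one record;
    a bare ``<id>`` header is a pre-concatenated Fv. Tables need columns
    ``id`` plus either ``fv`` or both ``vh`` and ``vl``. Input order of ids
    is preserved.
    """
    path = Path(path)
    if format == "fasta":
        return _read_fasta(path)
    if format == "table":
        return _read_table(path)
    raise ValueError(f"unknown sequence format: {format!r}")


def _read_fasta(path: Path) -> list[FvRecord]:
    order: list[str] = []
    chains: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        seq = str(rec.seq)
        if "|" in header:
            rid, _, chain = header.partition("|")
            chain = chain.strip().upper()
            if chain not in ("VH", "VL"):
                raise PairingError(
                    f"{rid}: unrecognized chain tag {chain!r} "
                    "(expected VH or VL)"
                )
        else:
            rid, chain = header, "FV"
        if rid not in chains:
            chains[rid] = {}
            order.append(rid)
        if chain in chains[rid]:
            raise PairingError(f"{rid}: duplicate {chain} record")
        chains[rid][chain] = seq
    if not order:
        raise SequenceError(f"{path}: no sequences found")
    records = []
    for rid in order:
        parts = chains[rid]
        if "FV" in parts:
            if len(parts) > 1:
                raise PairingError(
                    f"{rid}: mixes a plain Fv record with VH/VL records"
                )
            records.append(FvRecord(id=rid, fv=parts["FV"]))
        else:
            missing = {"VH", "VL"} - set(parts)
            if missing:
                raise PairingError(
                    f"{rid}: missing {'/'.join(sorted(missing))} record"
                )
            records.append(FvRecord(id=rid, vh=parts["VH"], vl=parts["VL"]))
    return records


def _read_table(path: Path) -> list[FvRecord]:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise SequenceError(f"{path}: empty table")
    cols = {c.lower(): c for c in df.columns}
    if "id" not in cols:
        raise SequenceError(f"{path}: table needs an 'id' column")
    records = []
    for _, row in df.iterrows():
        rid = str(row[cols["id"]])
        stage = row.get(cols.get("stage", ""), None)
        stage = None if pd.isna(stage) else stage
        if "vh" in cols and "vl" in cols:
            records.append(
                FvRecord(id=rid, vh=row[cols["vh"]], vl=row[cols["vl"]],
                         stage=stage)
            )
        elif "fv" in cols:
            records.append(FvRecord(id=rid, fv=row[cols["fv"]], stage=stage))
        else:
            raise SequenceError(
                f"{path}: table needs 'fv' or both 'vh' and 'vl' columns"
            )
    return records


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read the assay table; canonicalize platform column names.

    Unrecognized columns are dropped with a warning. Returns a DataFrame
    indexed by id with canonical platform columns.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    if "id" not in cols:
        raise JoinError(f"{path}: measurement table needs an 'id' column")
    df = df.set_index(cols["id"])
    df.index = df.index.astype(str)
    df.index.name = "id"
    keep, unknown = {}, []
    for col in df.columns:
        pid = canonical_platform(col)
        if pid is None:
            unknown.append(col)
        else:
            keep[col] = pid
    if unknown:
        warnings.warn(
            f"ignoring unrecognized measurement columns: {', '.join(unknown)}",
            stacklevel=2,
        )
    if not keep:
        raise JoinError(f"{path}: no recognized platform columns")
    out = df[list(keep)].rename(columns=keep)
    return out.astype(float)


def read_dataset(seq_path: str | Path, measurements_path: str | Path,
                 seq_format: str = "fasta") -> Dataset:
    """Join sequences with measurements into a Dataset."""
    records = read_sequences(seq_path, format=seq_format)
    meas = read_measurements(measurements_path)
    known = set(r.id for r in records)
    orphans = [rid for rid in meas.index if rid not in known]
    if orphans:
        raise JoinError(
            "measurement ids absent from sequences: " + ", ".join(orphans)
        )
    # reindex so every record has a (possibly all-NaN) measurement row
    meas = meas.reindex([r.id for r in records])
    return Dataset(records=records, measurements=meas)


def write_dataset(dataset: Dataset, seq_path: str | Path,
                  measurements_path: str | Path) -> None:
    """Write a Dataset back to FASTA + CSV (round-trips with read_dataset)."""
    with open(seq_path, "w") as fh:
        for rec in dataset.records:
            if rec.vh and rec.vl:
                fh.write(f">{rec.id}|VH\n{rec.vh}\n>{rec.id}|VL\n{rec.vl}\n")
            else:
                fh.write(f">{rec.id}\n{rec.fv}\n")
    dataset.measurements.to_csv(measurements_path, index_label="id")
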