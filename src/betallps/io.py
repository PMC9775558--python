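"""Readers/writers for the standard formats and the compatibility filter.

All tables are tab-delimited with one header line; all stretch
coordinates in files are 1-based inclusive.  FASTA goes through
Biopython.  The compatibility filter mirrors the constraints of the
external pi-pi scorer: sequences shorter than 140 residues, or containing
letters outside the 20 standard amino acids, get no P value and are
removed before scoring.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pairing import AMINO_ACIDS

MIN_COMPATIBLE_LENGTH = 140

_STANDARD = set(AMINO_ACIDS)


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input."""


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("record with empty id")
        if not self.residues:
            raise FastaFormatError(f"record {self.id!r} has no residues")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path) -> list[SequenceRecord]:
    """Parse a FASTA file into upper-cased records; ids must be unique."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, rec.description, str(rec.seq)))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    seqs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def filter_sequences(
    records: Sequence[SequenceRecord], min_len: int = MIN_COMPATIBLE_LENGTH
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Drop records the external pi-pi scorer cannot handle.

    Removes sequences with length < ``min_len`` or any non-standard letter.
    Returns ``(kept, report)`` where ``report`` has columns id, reason for
    every dropped record; filtering itself never raises.
    """
    kept = []
    dropped = []
    for rec in records:
        if len(rec) < min_len:
            dropped.append({"id": rec.id, "reason": "too_short"})
        elif set(rec.residues) - _STANDARD:
            dropped.append({"id": rec.id, "reason": "nonstandard_letter"})
        else:
            kept.append(rec)
    return kept, pd.DataFrame(dropped, columns=["id", "reason"])


# -- tables ---------------------------------------------------------------


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_pscores(path) -> pd.Series:
    """Per-sequence P table: TSV with columns id, P."""
    df = read_table(path)
    missing = {"id", "P"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: PScore table missing columns {sorted(missing)}")
    return df.set_index("id")["P"]


def read_weights(path) -> dict:
    """Weights JSON keyed by score name, each a feature -> coefficient map."""
    with open(path) as fh:
        return json.load(fh)


def write_weights(weights: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(weights, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_config(path) -> dict:
    """YAML or JSON configuration document."""
    text = open(path).read()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    try:
        return obj.item()  # numpy scalars
    except AttributeError:
        return str(obj)


def file_checksum(path) -> str:
    """Short sha256 digest of a file, for run logging."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


def config_hash(params: dict) -> str:
    """Digest of a parameter mapping, for run logging."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
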