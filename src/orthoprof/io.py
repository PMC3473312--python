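"""File formats and core containers: proteomes (FASTA), hit tables, TSV, config.

Conventions: FASTA ids are the first whitespace-delimited header token,
sequences are uppercased with a trailing ``*`` stripped, and written files
wrap at 60 columns. Hit tables follow BLAST tabular (outfmt 6) with two
native extension columns (query length, subject length) so that coverage
can be recomputed without the original sequences.
"""

from __future__ import annotations

import hashlib
import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

OUTFMT6_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]
NATIVE_EXTRA_COLUMNS = ["qcov", "qlen", "slen"]


@dataclass
class Proteome:
    """An organism's identified protein sequences, in input order."""

    organism: str
    records: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.records.items())

    @property
    def total_residues(self) -> int:
        return sum(len(s) for s in self.records.values())

    def add(self, protein_id: str, sequence: str) -> None:
        if protein_id in self.records:
            raise ValueError(f"duplicate protein id {protein_id!r} in proteome {self.organism!r}")
        self.records[protein_id] = sequence


def _normalize_sequence(seq: str, protein_id: str) -> str:
    seq = seq.upper().rstrip("*")
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise ValueError(
            f"protein {protein_id!r} contains invalid residues {sorted(bad)}; "
            f"allowed are the 20 amino acids plus X"
        )
    return seq


def read_fasta(path: str | Path, organism: str | None = None) -> Proteome:
    """Read one organism's proteome from a FASTA file.

    The record id is the first whitespace-delimited header token. Sequences
    are uppercased and a trailing stop ``*`` is stripped. Duplicate ids are
    an error; an empty file yields an empty proteome with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"proteome file not found: {path}")
    name = organism if organism is not None else path.stem
    proteome = Proteome(organism=name)
    for rec in SeqIO.parse(str(path), "fasta"):
        proteome.add(rec.id, _normalize_sequence(str(rec.seq), rec.id))
    if len(proteome) == 0:
        warnings.warn(f"empty proteome file: {path}", stacklevel=2)
    return proteome


def write_fasta(proteome: Proteome, path: str | Path) -> None:
    """Write a proteome as 60-column-wrapped uppercase FASTA."""
    records = [
        SeqRecord(Seq(seq), id=pid, description="")
        for pid, seq in proteome
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def fasta_string(proteome: Proteome) -> str:
    buf = _io.StringIO()
    writer = SeqIO.FastaIO.FastaWriter(buf, wrap=60)
    writer.write_file(
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in proteome
    )
    return buf.getvalue()


# --- tabular I/O -----------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_hit_table(hits: Iterable, path: str | Path, native: bool = True) -> None:
    """Write alignment hits as BLAST outfmt-6 rows.

    With ``native=True`` three extra columns (query coverage, query length,
    subject length) are appended after the standard twelve.
    """
    rows = [h.to_outfmt6_row(native=native) for h in hits]
    cols = OUTFMT6_COLUMNS + (NATIVE_EXTRA_COLUMNS if native else [])
    df = pd.DataFrame(rows, columns=cols)
    write_tsv(df, path)


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read a BLAST outfmt-6-like hit table (12 columns, native extras optional).

    Headerless files (as produced by ``blastp -outfmt 6``) are detected and
    the standard column names applied.
    """
    path = Path(path)
    first = path.read_text().split("\n", 1)[0] if path.stat().st_size else ""
    has_header = first.startswith("query\t")
    ncol = len(first.split("\t")) if first else 12
    if has_header:
        df = pd.read_csv(path, sep="\t")
    else:
        names = OUTFMT6_COLUMNS + NATIVE_EXTRA_COLUMNS[: max(0, ncol - 12)]
        df = pd.read_csv(path, sep="\t", header=None, names=names)
    missing = set(OUTFMT6_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hit table {path} lacks required columns: {sorted(missing)}")
    return df


# --- config ----------------------------------------------------------------

def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a key-value mapping")
    return data


def write_config(data: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
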