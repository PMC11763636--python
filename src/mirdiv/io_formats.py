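"""Readers and writers for the four table/sequence formats the pipeline touches.

All tabular inputs are tab-separated UTF-8 files with a header row.  Because
public databases (dbDEMC-style expression exports, miRTarBase-style target
links, OncoDB-style gene logFC tables) each use their own column names, every
reader takes a *dialect*: a mapping from the logical column names used here to
the header names found in the file.  Synthetic files written by this package
use the logical names directly, so the default dialect is the identity.

Sequences are read from FASTA (miRBase / PMRD style).  Sequences are
normalized to uppercase A/C/G/U (DNA-style T is mapped to U) and gated to the
mature-miRNA length range [15, 30] nt to exclude precursor contamination.

Malformed rows are never silently dropped: every reader returns the parsed
records together with counters describing what was skipped or flagged, and a
reader that skips more than half of its rows raises (wrong file).
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "Status",
    "Kingdom",
    "ExpressionRecord",
    "TargetLink",
    "GeneExpressionRecord",
    "SequenceRecord",
    "ReadCounters",
    "FormatError",
    "MIN_SEQ_LEN",
    "MAX_SEQ_LEN",
    "normalize_sequence",
    "read_expression_table",
    "read_target_links",
    "read_gene_expression_table",
    "read_fasta_sequences",
    "write_tsv",
    "write_fasta",
]

MIN_SEQ_LEN = 15
MAX_SEQ_LEN = 30

#: Maximum tolerated fraction of skipped data rows before a read aborts.
MAX_SKIP_FRACTION = 0.5

_RNA_ALPHABET = frozenset("ACGU")
_SEQ_TRANSLATION = str.maketrans({"T": "U", "t": "U"})


class FormatError(ValueError):
    """Raised for unreadable files, missing columns, or mostly-bad content."""


class Status(str, enum.Enum):
    """Recorded direction of differential expression in one experiment."""

    UP = "up"
    DOWN = "down"

    def __str__(self) -> str:  # keeps TSV output plain
        return self.value


class Kingdom(str, enum.Enum):
    HUMAN = "human"
    PLANT = "plant"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class ExpressionRecord:
    """One miRNA-in-one-experiment differential-expression observation."""

    mirna_id: str
    cancer_type: str
    subtype: str
    cell_type: str
    experiment_type: str
    log_fc: float
    status: Status


@dataclass(frozen=True)
class TargetLink:
    """An experimentally supported miRNA → target-gene relationship."""

    mirna_id: str
    gene_id: str


@dataclass(frozen=True)
class GeneExpressionRecord:
    """Per-gene log2 fold change in one cancer type."""

    gene_id: str
    cancer_type: str
    log_fc: float


@dataclass(frozen=True)
class SequenceRecord:
    """A mature miRNA sequence over the RNA alphabet A/C/G/U."""

    seq_id: str
    sequence: str
    kingdom: Kingdom

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadCounters:
    """Bookkeeping for one read: nothing is dropped without being counted."""

    n_rows: int = 0
    n_kept: int = 0
    n_skipped: int = 0
    n_sign_disagreements: int = 0
    n_rejected_sequences: int = 0
    n_duplicates: int = 0


# Identity dialects; real exports override these with their own header names.
EXPRESSION_COLUMNS = (
    "mirna_id",
    "cancer_type",
    "subtype",
    "cell_type",
    "experiment_type",
    "log_fc",
    "status",
)
LINK_COLUMNS = ("mirna_id", "gene_id")
GENE_EXPRESSION_COLUMNS = ("gene_id", "cancer_type", "log_fc")


def normalize_sequence(raw: str) -> str:
    """Uppercase a nucleotide string and map T to U (idempotent)."""
    return raw.strip().upper().translate(_SEQ_TRANSLATION)


def _load_table(
    path: str | Path, dialect: Mapping[str, str] | None, required: Sequence[str]
) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    dialect = dict(dialect) if dialect else {}
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty file (no header): {path}") from exc
    rename = {dialect.get(col, col): col for col in required}
    missing = [dialect.get(col, col) for col in required if dialect.get(col, col) not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return frame.rename(columns=rename)


def _check_skip_fraction(path: str | Path, counters: ReadCounters) -> None:
    if counters.n_rows and counters.n_skipped / counters.n_rows > MAX_SKIP_FRACTION:
        raise FormatError(
            f"{path}: {counters.n_skipped}/{counters.n_rows} rows unparsable; "
            "this does not look like the expected table"
        )


def read_expression_table(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> tuple[list[ExpressionRecord], ReadCounters]:
    """Read a dbDEMC-style miRNA differential-expression table.

    The up/down *status* string is authoritative for direction; a nonzero
    log_fc whose sign disagrees with it is kept but counted in
    ``n_sign_disagreements`` (up should be positive, down negative).
    Rows with an empty miRNA id or an unparsable status are skipped and
    counted.
    """
    frame = _load_table(path, dialect, EXPRESSION_COLUMNS)
    counters = ReadCounters(n_rows=len(frame))
    records: list[ExpressionRecord] = []
    for row in frame.itertuples(index=False):
        mirna_id = str(row.mirna_id).strip()
        status_raw = str(row.status).strip().lower()
        if not mirna_id or status_raw not in ("up", "down"):
            counters.n_skipped += 1
            continue
        status = Status(status_raw)
        try:
            log_fc = float(row.log_fc) if str(row.log_fc).strip() else 0.0
        except ValueError:
            counters.n_skipped += 1
            continue
        if log_fc != 0.0:
            expected_sign = 1.0 if status is Status.UP else -1.0
            if log_fc * expected_sign < 0:
                counters.n_sign_disagreements += 1
        records.append(
            ExpressionRecord(
                mirna_id=mirna_id,
                cancer_type=str(row.cancer_type).strip(),
                subtype=str(row.subtype).strip(),
                cell_type=str(row.cell_type).strip(),
                experiment_type=str(row.experiment_type).strip(),
                log_fc=log_fc,
                status=status,
            )
        )
    counters.n_kept = len(records)
    _check_skip_fraction(path, counters)
    return records, counters


def read_target_links(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> tuple[list[TargetLink], ReadCounters]:
    """Read a miRTarBase-style miRNA → gene link table, deduplicating pairs."""
    frame = _load_table(path, dialect, LINK_COLUMNS)
    counters = ReadCounters(n_rows=len(frame))
    seen: set[tuple[str, str]] = set()
    records: list[TargetLink] = []
    for row in frame.itertuples(index=False):
        mirna_id = str(row.mirna_id).strip()
        gene_id = str(row.gene_id).strip()
        if not mirna_id or not gene_id:
            counters.n_skipped += 1
            continue
        key = (mirna_id, gene_id)
        if key in seen:
            counters.n_duplicates += 1
            continue
        seen.add(key)
        records.append(TargetLink(mirna_id=mirna_id, gene_id=gene_id))
    counters.n_kept = len(records)
    _check_skip_fraction(path, counters)
    return records, counters


def read_gene_expression_table(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> tuple[list[GeneExpressionRecord], ReadCounters]:
    """Read an OncoDB-style per-gene per-cancer log2 fold-change table."""
    frame = _load_table(path, dialect, GENE_EXPRESSION_COLUMNS)
    counters = ReadCounters(n_rows=len(frame))
    records: list[GeneExpressionRecord] = []
    for row in frame.itertuples(index=False):
        gene_id = str(row.gene_id).strip()
        try:
            log_fc = float(row.log_fc)
        except ValueError:
            counters.n_skipped += 1
            continue
        if not gene_id or not math.isfinite(log_fc):
            counters.n_skipped += 1
            continue
        records.append(
            GeneExpressionRecord(
                gene_id=gene_id,
                cancer_type=str(row.cancer_type).strip(),
                log_fc=log_fc,
            )
        )
    counters.n_kept = len(records)
    _check_skip_fraction(path, counters)
    return records, counters


def read_fasta_sequences(
    path: str | Path, kingdom: Kingdom | str
) -> tuple[list[SequenceRecord], ReadCounters]:
    """Read mature miRNA sequences from FASTA (miRBase / PMRD style).

    Sequences are normalized (uppercase, T→U); the record id is the first
    whitespace-delimited token of the header.  Records with characters outside
    A/C/G/U after normalization, or with length outside [15, 30] nt, are
    rejected and counted.  Zero valid records is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    kingdom = Kingdom(kingdom)
    counters = ReadCounters()
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        counters.n_rows += 1
        seq = normalize_sequence(str(entry.seq))
        if set(seq) - _RNA_ALPHABET or not (MIN_SEQ_LEN <= len(seq) <= MAX_SEQ_LEN):
            counters.n_rejected_sequences += 1
            continue
        records.append(SequenceRecord(seq_id=entry.id, sequence=seq, kingdom=kingdom))
    counters.n_kept = len(records)
    if not records:
        raise FormatError(f"{path}: no valid miRNA sequences (of {counters.n_rows} records)")
    return records, counters


def write_tsv(rows: Iterable, path: str | Path) -> None:
    """Write dataclass records as a TSV with a header, preserving input order.

    Field order follows the dataclass definition, so a write/read round trip
    through the matching reader reproduces the records exactly.
    """
    rows = list(rows)
    if not rows:
        raise FormatError("write_tsv: refusing to write an empty table (no schema)")
    fields = [f.name for f in dataclasses.fields(rows[0])]
    frame = pd.DataFrame(
        [[getattr(row, name) for name in fields] for row in rows], columns=fields
    )
    for col in frame.columns:
        if frame[col].map(lambda v: isinstance(v, enum.Enum)).any():
            frame[col] = frame[col].map(str)
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write sequence records as single-line FASTA in input order."""
    with open(path, "w", encoding="utf-8") as handle:
        for rec in records:
            handle.write(f">{rec.seq_id}\n{rec.sequence}\n")
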