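"""Readers and writers for the formats the tool touches.

FASTA parsing and writing delegate to Bio.SeqIO; feature matrices are
written as CSV/TSV with full-precision decimals so a write/read round trip
is bit-exact.
"""

from __future__ import annotations

import csv
import logging
from typing import IO, Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .encode import SequenceRecord
from .pipeline import FeatureMatrix

logger = logging.getLogger(__name__)


class FastaFormatError(ValueError):
    pass


def _dedup_ids(ids: list[str]) -> list[str]:
    """Deduplicate ids by suffixing _2, _3, ... (warning per collision)."""
    counts: dict[str, int] = {}
    out = []
    for i in ids:
        counts[i] = counts.get(i, 0) + 1
        if counts[i] == 1:
            out.append(i)
        else:
            new = f"{i}_{counts[i]}"
            logger.warning("duplicate FASTA id %r renamed to %r", i, new)
            out.append(new)
    return out


def read_fasta(stream: IO[str]) -> list[SequenceRecord]:
    """Read a (possibly line-wrapped) FASTA stream.

    Ids are the first whitespace-delimited token after '>'.  Sequence data
    before any header is a format error reported with its line number.
    Duplicate ids are renamed with _2, _3, ... suffixes.
    """
    text = stream.read()
    for line_no, line in enumerate(text.splitlines(), start=1):
        s = line.strip()
        if not s:
            continue
        if not s.startswith(">"):
            raise FastaFormatError(
                f"line {line_no}: sequence data before any '>' header"
            )
        break
    from io import StringIO

    records = list(SeqIO.parse(StringIO(text), "fasta"))
    ids = _dedup_ids([r.id for r in records])
    out = []
    for rid, rec in zip(ids, records):
        if len(rec.seq) == 0:
            raise FastaFormatError(f"record {rid!r}: empty sequence")
        out.append(SequenceRecord(id=rid, residues=str(rec.seq)))
    return out


def write_fasta(records: Iterable[SequenceRecord], stream: IO[str]) -> None:
    SeqIO.write(
        (_BioRecord(Seq(r.residues), id=r.id, description="") for r in records),
        stream,
        "fasta",
    )


def read_labels(stream: IO[str]) -> np.ndarray:
    """Read one 0/1 label per line."""
    labels = []
    for line_no, line in enumerate(stream, start=1):
        s = line.strip()
        if not s:
            continue
        if s not in ("0", "1"):
            raise ValueError(f"label line {line_no}: expected 0 or 1, got {s!r}")
        labels.append(int(s))
    return np.array(labels, dtype=int)


def write_labels(labels: Iterable[int], stream: IO[str]) -> None:
    for y in labels:
        stream.write(f"{int(y)}\n")


def write_matrix(matrix: FeatureMatrix, stream: IO[str], dialect: str = "csv") -> None:
    """Write a feature matrix with header ``id,p1..pD``.

    Floats are rendered with 17 significant digits, enough for an exact
    binary round trip through :func:`read_matrix`.
    """
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}; use csv or tsv")
    delim = "," if dialect == "csv" else "\t"
    writer = csv.writer(stream, delimiter=delim, lineterminator="\n")
    writer.writerow(["id"] + [f"p{j}" for j in range(1, matrix.dims + 1)])
    for rid, row in zip(matrix.row_ids, matrix.data):
        writer.writerow([rid] + [format(v, ".17g") for v in row])


def read_matrix(stream: IO[str], dialect: str = "csv") -> FeatureMatrix:
    delim = "," if dialect == "csv" else "\t"
    reader = csv.reader(stream, delimiter=delim)
    header = next(reader, None)
    if header is None or header[:1] != ["id"]:
        raise ValueError("matrix stream missing 'id,p1..pD' header")
    ids, rows = [], []
    for rec in reader:
        if not rec:
            continue
        ids.append(rec[0])
        rows.append([float(v) for v in rec[1:]])
    data = np.array(rows, dtype=float) if rows else np.empty((0, len(header) - 1))
    return FeatureMatrix(row_ids=ids, data=data)
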