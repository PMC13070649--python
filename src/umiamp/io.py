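"""Readers and writers for the file formats the toolkit touches.

All output is bit-stable: '\n' newlines, deterministic ordering, fixed float
rendering.  Coordinates everywhere in the package are 0-based, half-open;
1-based conversion happens only in the human-facing variant table
(:mod:`umiamp.variants`).
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadRecord:
    """One sequencing read.

    qualities are Phred scores (Phred+33 decoded); None for FASTA input.
    batch_id records the live-mode file of origin, empty otherwise.
    """

    read_id: str
    sequence: str
    qualities: list[int] | None = None
    sample_id: str = ""
    batch_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class TargetRegion:
    """A named region of a reference amplicon, 0-based half-open."""

    name: str
    reference_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"target {self.name!r}: invalid interval [{self.start}, {self.end})")


def _open_maybe_gzip(path: str | Path) -> IO[bytes]:
    # gzip detected by magic bytes, never by extension
    handle = open(path, "rb")
    magic = handle.read(2)
    handle.seek(0)
    if magic == b"\x1f\x8b":
        return gzip.open(handle, "rb")
    return handle


def read_fastq(path: str | Path, sample_id: str = "") -> Iterator[ReadRecord]:
    """Stream ReadRecords from a (possibly gzipped) 4-line FASTQ file.

    Sequences are uppercased and 'U' is mapped to 'T'; qualities are decoded
    as Phred+33.  A length mismatch between sequence and quality lines is a
    hard error naming the offending read.
    """
    with _open_maybe_gzip(path) as handle:
        while True:
            header = handle.readline()
            if not header:
                return
            header = header.decode().rstrip("\n")
            if not header.startswith("@"):
                raise ValueError(f"{path}: malformed FASTQ header line {header!r}")
            read_id = header[1:].split()[0] if len(header) > 1 else ""
            seq = handle.readline().decode().rstrip("\n").upper().replace("U", "T")
            plus = handle.readline()
            qual = handle.readline().decode().rstrip("\n")
            if not plus:
                raise ValueError(f"{path}: truncated record for read {read_id!r}")
            if len(qual) != len(seq):
                raise ValueError(
                    f"{path}: read {read_id!r} has sequence length {len(seq)} "
                    f"but quality length {len(qual)}"
                )
            yield ReadRecord(
                read_id=read_id,
                sequence=seq,
                qualities=[ord(c) - 33 for c in qual],
                sample_id=sample_id,
            )


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    """Write 4-line Phred+33 FASTQ (plain text)."""
    with open(path, "w", newline="\n") as out:
        for rec in records:
            quals = rec.qualities if rec.qualities is not None else [40] * len(rec.sequence)
            out.write(f"@{rec.read_id}\n{rec.sequence}\n+\n")
            out.write("".join(chr(q + 33) for q in quals) + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, uppercase sequence) pairs."""
    from Bio import SeqIO

    with _open_maybe_gzip(path) as raw:
        text = raw.read().decode()
    from io import StringIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(StringIO(text), "fasta")]


_WS = re.compile(r"\s+")


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write FASTA, 80-column wrapped, input order preserved.

    Whitespace in ids is replaced with '_' (and logged) so downstream tables
    stay unambiguous; duplicate ids are an error.
    """
    seen: set[str] = set()
    with open(path, "w", newline="\n") as out:
        for rec_id, seq in records:
            clean = _WS.sub("_", rec_id)
            if clean != rec_id:
                logger.warning("FASTA id %r sanitized to %r", rec_id, clean)
            if clean in seen:
                raise ValueError(f"duplicate FASTA id {clean!r}")
            seen.add(clean)
            out.write(f">{clean}\n")
            for i in range(0, len(seq), 80):
                out.write(seq[i : i + 80] + "\n")


def _render(value: object) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_tsv_table(rows: Iterable[Sequence[object]], schema: Sequence[str], path: str | Path) -> None:
    """Write a TSV with a header from *schema*; floats rendered to 6 significant digits."""
    n = len(schema)
    with open(path, "w", newline="\n") as out:
        out.write("\t".join(schema) + "\n")
        for row in rows:
            if len(row) != n:
                raise ValueError(f"row {row!r} does not match schema {list(schema)!r}")
            out.write("\t".join(_render(v) for v in row) + "\n")


def read_tsv_table(path: str | Path) -> tuple[list[str], list[list[str]]]:
    """Read a TSV written by :func:`write_tsv_table`; returns (header, string rows)."""
    with open(path) as handle:
        lines = handle.read().splitlines()
    if not lines:
        return [], []
    header = lines[0].split("\t")
    return header, [line.split("\t") for line in lines[1:]]
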