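"""Anchor-based UMI extraction.

Dual-UMI amplicon constructs place a fixed anchor sequence (typically the
universal amplification primer tail) immediately before a random UMI at each
end of the molecule:

    fwd_anchor + fwd_umi + insert + revcomp(rev_umi) + revcomp(rev_anchor)

Extraction locates each anchor by semi-global alignment inside a terminal
window of the read, harvests the ``umi_length`` bases immediately following
the anchor, validates them against the design's IUPAC pattern, and trims the
read down to the insert.  Both read orientations are tried and the one with
the lower total anchor edit distance wins (ties go to the plus orientation),
so a read and its reverse complement always give the same canonical UMI.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from umiamp.io import ReadRecord, revcomp

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}


@dataclass(frozen=True)
class UmiDesign:
    """Declarative description of a dual-UMI amplicon construct.

    Anchors are given as they appear on the plus strand of the construct:
    ``fwd_anchor`` immediately precedes the forward UMI at the 5' end;
    ``rev_anchor`` plays the same role at the 3' end and is given in the
    orientation in which its reverse complement appears on the plus strand
    (i.e. as it reads on the minus strand, anchor-then-UMI).
    ``pattern`` is an IUPAC string of length ``umi_length`` applied to each
    UMI arm.  ``terminal_window`` bases at each read end are searched for
    anchors.  The length gate [min_read_length, max_read_length] is applied
    to whole reads before extraction.
    """

    fwd_anchor: str
    rev_anchor: str
    umi_length: int
    pattern: str
    max_anchor_edits: int = 3
    max_pattern_mismatches: int = 2
    terminal_window: int = 200
    min_read_length: int = 1
    max_read_length: int = 10**9

    def __post_init__(self) -> None:
        if len(self.pattern) != self.umi_length:
            raise ValueError("pattern length must equal umi_length")
        if not self.fwd_anchor or not self.rev_anchor:
            raise ValueError("anchors must be non-empty")
        for symbol in self.pattern:
            if symbol not in IUPAC:
                raise ValueError(f"invalid IUPAC symbol {symbol!r} in pattern")
        longest = max(len(self.fwd_anchor), len(self.rev_anchor))
        if self.terminal_window < longest + self.umi_length:
            raise ValueError("terminal_window must cover anchor + UMI")
        if not (0 <= self.max_anchor_edits < min(len(self.fwd_anchor), len(self.rev_anchor))):
            raise ValueError("max_anchor_edits must be in [0, len(anchor))")


@dataclass(frozen=True)
class AnchorHit:
    """Best semi-global placement of an anchor inside a terminal window."""

    read_id: str
    terminus: str  # {"head", "tail"}
    strand: str  # {"plus", "minus"}
    edit_distance: int
    anchor_end: int  # 0-based position immediately after the anchor


@dataclass(frozen=True)
class UmiExtraction:
    """Per-read result of anchor search and UMI harvesting.

    ``canonical_umi`` is the forward UMI concatenated with the reverse
    complement of the reverse UMI, always expressed on the plus strand of the
    insert, hence identical for a read and its reverse complement.
    ``insert_start``/``insert_end`` are 0-based half-open coordinates of the
    anchor- and UMI-trimmed insert in plus-orientation read coordinates.
    """

    read_id: str
    fwd_umi: str = ""
    rev_umi: str = ""
    canonical_umi: str = ""
    strand: str = "plus"
    insert_start: int = 0
    insert_end: int = 0
    pattern_mismatches: int = 0
    status: str = "pass"  # {pass, fail_anchor, fail_pattern, fail_length}


def _semiglobal_row(window: str, anchor: str) -> np.ndarray:
    """Final DP row of a semi-global alignment (anchor global, window ends free).

    Entry j holds the minimum edit distance of the anchor against any window
    substring ending at position j; unit costs for mismatch, insertion and
    deletion.
    """
    w = np.frombuffer(window.encode(), dtype=np.uint8)
    n = w.size
    offsets = np.arange(n + 1, dtype=np.int32)
    prev = np.zeros(n + 1, dtype=np.int32)
    t = np.empty(n + 1, dtype=np.int32)
    for i, ch in enumerate(anchor.encode(), start=1):
        diag = prev[:-1] + (w != ch)
        up = prev[1:] + 1
        t[0] = i
        t[1:] = np.minimum(diag, up) - offsets[1:]
        prev = np.minimum.accumulate(t) + offsets
    return prev


def locate_anchor(
    read_window: str,
    anchor: str,
    max_edits: int,
    *,
    read_id: str = "",
    terminus: str = "head",
    strand: str = "plus",
) -> AnchorHit | None:
    """Find the best placement of *anchor* within *read_window*.

    Semi-global alignment: the anchor aligns end-to-end, gaps at the window
    boundaries are free, unit costs.  Returns the minimum-distance hit, ties
    broken by the smallest ``anchor_end``; None if the minimum exceeds
    *max_edits*.
    """
    if len(anchor) > len(read_window):
        raise ValueError("anchor longer than search window")
    row = _semiglobal_row(read_window, anchor)
    best_end = int(np.argmin(row))  # argmin returns the first minimum
    best = int(row[best_end])
    if best > max_edits:
        return None
    return AnchorHit(
        read_id=read_id,
        terminus=terminus,
        strand=strand,
        edit_distance=best,
        anchor_end=best_end,
    )


def validate_pattern(umi: str, pattern: str) -> int:
    """Count positions where the UMI base is outside the pattern's IUPAC class."""
    if len(umi) != len(pattern):
        raise ValueError(f"UMI length {len(umi)} != pattern length {len(pattern)}")
    return sum(base not in IUPAC[symbol] for base, symbol in zip(umi, pattern))


def _anchor_pair(seq: str, design: UmiDesign, read_id: str, strand: str):
    """Locate fwd anchor in the head window and rev anchor at the head of the
    reverse complement (i.e. the tail of *seq*).  Returns (head hit, tail hit,
    total distance) with missing anchors costing just above the budget."""
    window = min(design.terminal_window, len(seq))
    head = locate_anchor(
        seq[:window], design.fwd_anchor, design.max_anchor_edits,
        read_id=read_id, terminus="head", strand=strand,
    )
    rc = revcomp(seq)
    tail = locate_anchor(
        rc[:window], design.rev_anchor, design.max_anchor_edits,
        read_id=read_id, terminus="tail", strand=strand,
    )
    miss = design.max_anchor_edits + 1
    total = (head.edit_distance if head else miss) + (tail.edit_distance if tail else miss)
    return head, tail, total


def extract_umis(read: ReadRecord, design: UmiDesign) -> UmiExtraction:
    """Extract both UMIs from a read and canonicalize the orientation.

    The plus hypothesis searches the forward anchor at the head of the read
    as-is and the reverse anchor at the head of its reverse complement; the
    minus hypothesis does the same on the reverse-complemented read.  The
    hypothesis with the lower total anchor edit distance wins (tie: plus).
    Failures are statuses, never exceptions, applied in gate order
    length -> anchor -> pattern.
    """
    n = len(read.sequence)
    if not (design.min_read_length <= n <= design.max_read_length):
        return UmiExtraction(read_id=read.read_id, status="fail_length")

    plus_seq = read.sequence
    minus_seq = revcomp(plus_seq)
    p_head, p_tail, p_total = _anchor_pair(plus_seq, design, read.read_id, "plus")
    m_head, m_tail, m_total = _anchor_pair(minus_seq, design, read.read_id, "minus")

    if m_total < p_total:
        strand, seq, head, tail = "minus", minus_seq, m_head, m_tail
    else:
        strand, seq, head, tail = "plus", plus_seq, p_head, p_tail

    if head is None or tail is None:
        return UmiExtraction(read_id=read.read_id, strand=strand, status="fail_anchor")

    k = design.umi_length
    fwd_umi = seq[head.anchor_end : head.anchor_end + k]
    rc = revcomp(seq)
    rev_umi = rc[tail.anchor_end : tail.anchor_end + k]
    insert_start = head.anchor_end + k
    insert_end = n - (tail.anchor_end + k)
    if len(fwd_umi) < k or len(rev_umi) < k or insert_start >= insert_end:
        return UmiExtraction(read_id=read.read_id, strand=strand, status="fail_anchor")

    mismatches = validate_pattern(fwd_umi, design.pattern) + validate_pattern(
        rev_umi, design.pattern
    )
    canonical = fwd_umi + revcomp(rev_umi)
    status = "pass" if mismatches <= design.max_pattern_mismatches else "fail_pattern"
    return UmiExtraction(
        read_id=read.read_id,
        fwd_umi=fwd_umi,
        rev_umi=rev_umi,
        canonical_umi=canonical,
        strand=strand,
        insert_start=insert_start,
        insert_end=insert_end,
        pattern_mismatches=mismatches,
        status=status,
    )


def filter_reads(
    reads: Iterable[ReadRecord], design: UmiDesign
) -> tuple[list[tuple[ReadRecord, UmiExtraction]], Counter]:
    """Run extraction over a read stream and trim passing reads to their insert.

    Returns the passing (trimmed read, extraction) pairs in input order and a
    tally of statuses that counts every input read exactly once.
    """
    passed: list[tuple[ReadRecord, UmiExtraction]] = []
    tally: Counter = Counter()
    for read in reads:
        ext = extract_umis(read, design)
        tally[ext.status] += 1
        if ext.status != "pass":
            continue
        seq = read.sequence if ext.strand == "plus" else revcomp(read.sequence)
        quals = read.qualities
        if quals is not None and ext.strand == "minus":
            quals = quals[::-1]
        insert = seq[ext.insert_start : ext.insert_end]
        insert_quals = quals[ext.insert_start : ext.insert_end] if quals is not None else None
        trimmed = ReadRecord(
            read_id=read.read_id,
            sequence=insert,
            qualities=insert_quals,
            sample_id=read.sample_id,
            batch_id=read.batch_id,
        )
        passed.append((trimmed, ext))
    return passed, tally
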