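"""Consensus-level variant calling and comparison metrics.

A "variant level" here is the fraction of single-molecule consensus
sequences carrying an alternative allele at a reference position — the
natural frequency estimate once every original molecule is represented by
exactly one polished sequence.  Because sequencing errors are removed at the
consensus stage, the counting itself needs no error model.

Internal coordinates are 0-based; indels are represented per alignment
column: a deletion is (pos, ref_base, '-') and an insertion before position
pos is (pos, '-', base).  The human-facing TSV and the minimal VCF writer
convert to 1-based anchored representations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from umiamp.consensus import ConsensusRecord, align_to_reference
from umiamp.io import write_tsv_table


@dataclass(frozen=True)
class VariantCall:
    """One alternative allele at one reference column, with its level."""

    reference_id: str
    pos: int  # 0-based reference position
    ref_allele: str
    alt_allele: str
    alt_count: int
    depth: int

    @property
    def level(self) -> float:
        return self.alt_count / self.depth

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref_allele, self.alt_allele)


@dataclass
class VariantComparison:
    """Set- and level-agreement between a test and a truth variant set."""

    recall: float
    precision: float
    specificity: float
    f1: float
    n_shared: int
    level_r2: float | None  # None when fewer than 2 shared variants
    precision_defined: bool = True


def call_variants(
    consensuses: Sequence[ConsensusRecord],
    reference: str,
    min_level: float = 0.01,
    min_alt_count: int = 3,
    reference_id: str = "ref",
) -> list[VariantCall]:
    """Tally alleles column-wise across consensus sequences.

    Each consensus is globally aligned to the reference and contributes one
    allele per column.  Calls are emitted when the level is at least
    *min_level* AND the alternative is seen in at least *min_alt_count*
    consensuses, ordered by (position, alt allele).  At every column, the
    allele counts (reference plus alternatives) sum to the column depth.
    """
    if not consensuses:
        raise ValueError("cannot call variants from an empty consensus set")
    depth = len(consensuses)
    columns: dict[tuple[int, int], Counter] = {}
    for record in consensuses:
        for pos, rank, base in align_to_reference(record.sequence, reference):
            columns.setdefault((pos, rank), Counter())[base] += 1

    calls: list[VariantCall] = []
    for (pos, rank), counts in columns.items():
        ref_allele = reference[pos] if rank == 0 and pos < len(reference) else "-"
        for base, count in counts.items():
            if base == ref_allele:
                continue
            alt = base
            if rank > 0 and base == "-":
                continue  # absence of an insertion is the reference state
            if count >= min_alt_count and count / depth >= min_level:
                calls.append(
                    VariantCall(
                        reference_id=reference_id,
                        pos=pos,
                        ref_allele=ref_allele,
                        alt_allele=alt,
                        alt_count=count,
                        depth=depth,
                    )
                )
    calls.sort(key=lambda c: (c.pos, c.alt_allele, c.ref_allele))
    return calls


def compare_variant_sets(
    test: Sequence[VariantCall], truth: Sequence[VariantCall], n_positions: int
) -> VariantComparison:
    """Recall/precision/specificity/F1 plus level agreement (R^2).

    Variants are keyed by (pos, ref, alt).  Specificity is computed over the
    *n_positions* callable positions not in the truth set.  The level R^2 is
    the squared Pearson correlation over shared variants, reported as missing
    when fewer than 2 are shared.  An empty test set yields precision 0 with
    ``precision_defined=False``.
    """
    if n_positions < len(truth):
        raise ValueError("n_positions must be at least the truth set size")
    test_map = {c.key: c for c in test}
    truth_map = {c.key: c for c in truth}
    shared = sorted(set(test_map) & set(truth_map))
    fp = len(set(test_map) - set(truth_map))

    recall = len(shared) / len(truth) if truth else 1.0
    precision_defined = bool(test)
    precision = len(shared) / len(test_map) if test_map else 0.0
    n_neg = n_positions - len(truth_map)
    specificity = (n_neg - fp) / n_neg if n_neg > 0 else 1.0
    specificity = max(0.0, specificity)
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )

    level_r2: float | None = None
    if len(shared) >= 2:
        x = np.array([truth_map[k].level for k in shared])
        y = np.array([test_map[k].level for k in shared])
        if np.ptp(x) > 0 and np.ptp(y) > 0:
            level_r2 = float(stats.pearsonr(x, y).statistic ** 2)
        else:
            level_r2 = 1.0 if np.allclose(x, y) else 0.0
    return VariantComparison(
        recall=recall,
        precision=precision,
        specificity=specificity,
        f1=f1,
        n_shared=len(shared),
        level_r2=level_r2,
        precision_defined=precision_defined,
    )


def recover_simulated_levels(
    truth_levels: dict[tuple[int, str, str], float],
    calls: Sequence[VariantCall],
    z: float = 1.96,
) -> list[dict]:
    """Check called levels against simulated truth with binomial 95% CIs.

    For every truth variant, the called level and a normal-approximation CI
    from the call's depth are reported along with whether the CI contains
    the true level.  Truth variants with no call are flagged as missed.
    """
    by_key = {c.key: c for c in calls}
    rows: list[dict] = []
    for key, truth_level in sorted(truth_levels.items()):
        call = by_key.get(key)
        if call is None:
            rows.append(
                {"key": key, "truth": truth_level, "called": 0.0, "in_ci": False, "missed": True}
            )
            continue
        if call.depth <= 0:
            raise ValueError(f"variant {key} has zero depth")
        p = call.level
        half = z * np.sqrt(p * (1 - p) / call.depth)
        rows.append(
            {
                "key": key,
                "truth": truth_level,
                "called": p,
                "in_ci": bool(p - half <= truth_level <= p + half),
                "missed": False,
            }
        )
    return rows


VARIANT_TABLE_SCHEMA = ["reference_id", "pos_1based", "ref", "alt", "alt_count", "depth", "level"]


def write_variant_table(calls: Sequence[VariantCall], path: str | Path) -> None:
    """Human-facing TSV with 1-based positions."""
    rows = [
        (c.reference_id, c.pos + 1, c.ref_allele, c.alt_allele, c.alt_count, c.depth, c.level)
        for c in calls
    ]
    write_tsv_table(rows, VARIANT_TABLE_SCHEMA, path)


def read_variant_table(path: str | Path) -> list[VariantCall]:
    from umiamp.io import read_tsv_table

    header, rows = read_tsv_table(path)
    if header != VARIANT_TABLE_SCHEMA:
        raise ValueError(f"unexpected variant table header in {path}")
    return [
        VariantCall(
            reference_id=r[0],
            pos=int(r[1]) - 1,
            ref_allele=r[2],
            alt_allele=r[3],
            alt_count=int(r[4]),
            depth=int(r[5]),
        )
        for r in rows
    ]


def write_vcf(
    calls: Sequence[VariantCall], reference: str, reference_id: str, path: str | Path
) -> None:
    """Minimal VCF 4.2 emission with AF (level) and DP (depth) INFO fields.

    Indels are anchored on the preceding reference base as VCF requires;
    an indel at reference position 0 is anchored on the following base.
    """
    with open(path, "w", newline="\n") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write(f"##contig=<ID={reference_id},length={len(reference)}>\n")
        out.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Consensus-level allele frequency">\n')
        out.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Number of consensus sequences">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.pos, c.alt_allele)):
            if c.ref_allele != "-" and c.alt_allele != "-":
                pos1, ref, alt = c.pos + 1, c.ref_allele, c.alt_allele
            elif c.alt_allele == "-":  # deletion of the base at pos
                if c.pos > 0:
                    anchor = reference[c.pos - 1]
                    pos1, ref, alt = c.pos, anchor + c.ref_allele, anchor
                else:
                    anchor = reference[c.pos + 1]
                    pos1, ref, alt = 1, c.ref_allele + anchor, anchor
            else:  # insertion before pos
                if c.pos > 0:
                    anchor = reference[c.pos - 1]
                    pos1, ref, alt = c.pos, anchor, anchor + c.alt_allele
                else:
                    anchor = reference[0]
                    pos1, ref, alt = 1, anchor, c.alt_allele + anchor
            out.write(
                f"{c.reference_id}\t{pos1}\t.\t{ref}\t{alt}\t.\tPASS\t"
                f"AF={c.level:.6g};DP={c.depth}\n"
            )
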