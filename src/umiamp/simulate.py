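"""Deterministic simulator for UMI-tagged amplicon reads with full ground truth.

Each simulated molecule is a template

    fwd_anchor + fwd_umi + insert(haplotype) + revcomp(rev_umi) + revcomp(rev_anchor)

with both UMIs drawn from the design's IUPAC pattern.  Read multiplicity per
molecule follows a truncated log-normal, emulating the skewed cluster-size
distributions that PCR jackpotting produces in real libraries.  Each read is
optionally emitted as the reverse complement (strand mixture) and then
corrupted with independent per-base substitution, insertion and deletion
errors — a deliberately simple uniform error model with no homopolymer
awareness.  Optional haplotypes (edit lists applied to the insert) are
assigned multinomially at target levels, and optional chimeras splice a
random prefix of one read onto a random suffix of another.

Everything is driven by a single integer seed: two runs with the same config
produce byte-identical FASTQ files and truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from umiamp.extraction import IUPAC, UmiDesign
from umiamp.io import ReadRecord, revcomp, write_fasta, write_fastq, write_tsv_table

BASES = "ACGT"

#: edit spec: ("sub", pos, base) | ("ins", pos, base) | ("del", pos)
Edit = tuple


@dataclass(frozen=True)
class Haplotype:
    """A variant haplotype: named list of edits applied to the reference
    insert, spiked in at a target molecule fraction."""

    haplotype_id: str
    edits: tuple[Edit, ...]
    level: float


@dataclass
class SimConfig:
    """Study conditions for one simulated run.

    Defaults describe a realistic small targeted experiment: a 500 bp
    amplicon, 100 tagged molecules, log-normal read multiplicity around 30
    reads per molecule, 5% total per-base read error (half substitutions,
    one quarter each insertions and deletions), and an even strand mixture.
    """

    design: UmiDesign
    reference: str | None = None
    reference_length: int = 500
    n_molecules: int = 100
    haplotypes: tuple[Haplotype, ...] = ()
    read_mu: float = float(np.log(30.0))
    read_sigma: float = 0.6
    reads_per_molecule: int | None = None  # fixed count overrides the log-normal
    max_reads_per_molecule: int = 200
    sub_rate: float = 0.025
    ins_rate: float = 0.0125
    del_rate: float = 0.0125
    minus_strand_fraction: float = 0.5
    chimera_rate: float = 0.0
    n_batches: int = 1
    sample_id: str = "sample01"
    seed: int = 1
    allow_umi_collisions: bool = False

    def __post_init__(self) -> None:
        for rate in (self.sub_rate, self.ins_rate, self.del_rate):
            if not (0.0 <= rate < 1.0):
                raise ValueError("error rates must be in [0, 1)")
        if sum(h.level for h in self.haplotypes) > 1.0 + 1e-9:
            raise ValueError("haplotype levels must sum to at most 1")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")


@dataclass
class Molecule:
    molecule_id: str
    sample_id: str
    haplotype_id: str
    fwd_umi: str
    rev_umi: str
    insert: str
    template: str

    @property
    def canonical_umi(self) -> str:
        return self.fwd_umi + revcomp(self.rev_umi)


@dataclass
class SimTruth:
    """Ground truth: molecule table plus read-to-molecule assignments."""

    molecules: list[Molecule]
    # read_id -> (molecule_id, strand, n_errors); chimeras map to "chimera"
    reads: dict[str, tuple[str, str, int]] = field(default_factory=dict)
    reference: str = ""
    haplotype_inserts: dict[str, str] = field(default_factory=dict)

    def reads_per_molecule(self) -> dict[str, int]:
        counts: dict[str, int] = {m.molecule_id: 0 for m in self.molecules}
        for mol_id, _, _ in self.reads.values():
            if mol_id in counts:
                counts[mol_id] += 1
        return counts


def sample_umi(pattern: str, rng: np.random.Generator) -> str:
    """Draw a UMI uniformly from an IUPAC pattern, position by position."""
    out = []
    for symbol in pattern:
        if symbol not in IUPAC:
            raise ValueError(f"invalid IUPAC symbol {symbol!r}")
        choices = IUPAC[symbol]
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def apply_edits(insert: str, edits: Sequence[Edit]) -> str:
    """Apply substitution/insertion/deletion edits (0-based insert coordinates).

    Edits are applied right-to-left so earlier positions stay valid.
    """
    seq = list(insert)
    for edit in sorted(edits, key=lambda e: -e[1]):
        kind, pos = edit[0], edit[1]
        if kind == "sub":
            seq[pos] = edit[2]
        elif kind == "ins":
            seq.insert(pos, edit[2])
        elif kind == "del":
            del seq[pos]
        else:
            raise ValueError(f"unknown edit kind {kind!r}")
    return "".join(seq)


def build_molecules(config: SimConfig) -> tuple[list[Molecule], SimTruth]:
    """Draw UMIs and haplotype assignments; build full tagged templates.

    Unless ``allow_umi_collisions`` is set, any molecule whose canonical UMI
    lands within the default step-1 clustering distance of an existing
    molecule's UMI is re-drawn (up to 100 attempts) so that cluster-recovery
    runs have an unambiguous truth.
    """
    import edlib

    rng = np.random.default_rng(config.seed)
    reference = config.reference or random_dna(config.reference_length, rng)

    hap_ids = ["ref"] + [h.haplotype_id for h in config.haplotypes]
    hap_levels = [1.0 - sum(h.level for h in config.haplotypes)] + [
        h.level for h in config.haplotypes
    ]
    hap_inserts = {"ref": reference}
    for h in config.haplotypes:
        hap_inserts[h.haplotype_id] = apply_edits(reference, h.edits)
    assignments = rng.choice(len(hap_ids), size=config.n_molecules, p=hap_levels)

    min_sep = 4  # one more than the default step-1 threshold
    molecules: list[Molecule] = []
    seen: list[str] = []
    failures: list[str] = []
    for i in range(config.n_molecules):
        for _ in range(100):
            fwd = sample_umi(config.design.pattern, rng)
            rev = sample_umi(config.design.pattern, rng)
            canonical = fwd + revcomp(rev)
            if config.allow_umi_collisions or all(
                edlib.align(canonical, other, mode="NW", k=min_sep - 1)["editDistance"] == -1
                for other in seen
            ):
                break
        else:
            failures.append(f"molecule {i}")
            continue
        seen.append(canonical)
        hap = hap_ids[assignments[i]]
        insert = hap_inserts[hap]
        template = (
            config.design.fwd_anchor
            + fwd
            + insert
            + revcomp(rev)
            + revcomp(config.design.rev_anchor)
        )
        molecules.append(
            Molecule(
                molecule_id=f"mol{i:05d}",
                sample_id=config.sample_id,
                haplotype_id=hap,
                fwd_umi=fwd,
                rev_umi=rev,
                insert=insert,
                template=template,
            )
        )
    if failures:
        raise RuntimeError(
            "could not draw collision-free UMIs for: " + ", ".join(failures)
        )
    truth = SimTruth(molecules=molecules, reference=reference, haplotype_inserts=hap_inserts)
    return molecules, truth


def corrupt(seq: str, config: SimConfig, rng: np.random.Generator) -> tuple[str, int]:
    """Apply independent per-base substitution/insertion/deletion errors."""
    if config.sub_rate == config.ins_rate == config.del_rate == 0.0:
        return seq, 0
    out: list[str] = []
    n_errors = 0
    draws = rng.random(len(seq) * 3).reshape(-1, 3)
    ins_bases = rng.integers(0, 4, size=len(seq))
    sub_shift = rng.integers(1, 4, size=len(seq))
    for i, base in enumerate(seq):
        if draws[i, 0] < config.del_rate:
            n_errors += 1
            continue
        if draws[i, 1] < config.sub_rate:
            base = BASES[(BASES.index(base) + sub_shift[i]) % 4] if base in BASES else base
            n_errors += 1
        out.append(base)
        if draws[i, 2] < config.ins_rate:
            out.append(BASES[ins_bases[i]])
            n_errors += 1
    if not out:  # pathological: everything deleted
        out.append(seq[0])
    return "".join(out), n_errors


def emit_reads(
    molecules: Sequence[Molecule], config: SimConfig, truth: SimTruth
) -> list[ReadRecord]:
    """Emit error-bearing reads for every molecule, shuffled deterministically.

    Per molecule the read count is fixed (``reads_per_molecule``) or drawn
    from the truncated log-normal; each read flips to the minus strand with
    ``minus_strand_fraction`` and is then corrupted base by base.  Chimeras
    (``chimera_rate`` of total reads) splice a random prefix of one read
    template onto the suffix of another and are marked in the truth table.
    """
    rng = np.random.default_rng([config.seed, 1])
    total_rate = config.sub_rate + config.ins_rate + config.del_rate
    qual = 40 if total_rate == 0 else max(2, round(-10 * np.log10(total_rate)))

    reads: list[ReadRecord] = []
    for mol in molecules:
        if config.reads_per_molecule is not None:
            n_reads = config.reads_per_molecule
        else:
            n_reads = int(np.clip(round(np.exp(rng.normal(config.read_mu, config.read_sigma))),
                                  1, config.max_reads_per_molecule))
        for k in range(n_reads):
            read_id = f"{mol.molecule_id}_r{k:04d}"
            strand = "minus" if rng.random() < config.minus_strand_fraction else "plus"
            template = mol.template if strand == "plus" else revcomp(mol.template)
            seq, n_errors = corrupt(template, config, rng)
            reads.append(
                ReadRecord(
                    read_id=read_id,
                    sequence=seq,
                    qualities=[qual] * len(seq),
                    sample_id=config.sample_id,
                )
            )
            truth.reads[read_id] = (mol.molecule_id, strand, n_errors)

    n_chimeras = int(round(config.chimera_rate * len(reads)))
    for c in range(n_chimeras):
        a, b = rng.integers(0, len(molecules), size=2)
        ta, tb = molecules[a].template, molecules[b].template
        cut_a = int(rng.integers(1, len(ta)))
        cut_b = int(rng.integers(1, len(tb)))
        seq, n_errors = corrupt(ta[:cut_a] + tb[cut_b:], config, rng)
        read_id = f"chimera_{c:04d}"
        reads.append(
            ReadRecord(
                read_id=read_id,
                sequence=seq,
                qualities=[qual] * len(seq),
                sample_id=config.sample_id,
            )
        )
        truth.reads[read_id] = ("chimera", "plus", n_errors)

    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


def simulate_run(config: SimConfig) -> tuple[list[ReadRecord], SimTruth]:
    """Convenience: build molecules and emit their shuffled reads."""
    molecules, truth = build_molecules(config)
    reads = emit_reads(molecules, config, truth)
    return reads, truth


MOLECULE_SCHEMA = [
    "molecule_id", "sample_id", "haplotype_id", "fwd_umi", "rev_umi", "canonical_umi", "n_reads",
]
READ_SCHEMA = ["read_id", "molecule_id", "strand", "n_errors"]


def write_run(
    reads: Sequence[ReadRecord], truth: SimTruth, config: SimConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Write FASTQ (split into batches for live mode), reference FASTA,
    truth tables, and a config echo; returns the paths written."""
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    n_batches = max(1, config.n_batches)
    per_batch = -(-len(reads) // n_batches) if reads else 1
    batch_paths = []
    for b in range(n_batches):
        chunk = reads[b * per_batch : (b + 1) * per_batch]
        if b > 0 and not chunk:
            break
        name = f"{config.sample_id}_batch{b:03d}.fastq"
        write_fastq(chunk, out / name)
        batch_paths.append(out / name)
    paths["fastq"] = batch_paths[0]
    paths["batches"] = batch_paths

    write_fasta([("ref", truth.reference)], out / "reference.fasta")
    paths["reference"] = out / "reference.fasta"

    counts = truth.reads_per_molecule()
    write_tsv_table(
        [
            (m.molecule_id, m.sample_id, m.haplotype_id, m.fwd_umi, m.rev_umi,
             m.canonical_umi, counts[m.molecule_id])
            for m in truth.molecules
        ],
        MOLECULE_SCHEMA,
        out / "truth_molecules.tsv",
    )
    paths["truth_molecules"] = out / "truth_molecules.tsv"
    write_tsv_table(
        [(rid, mid, strand, ne) for rid, (mid, strand, ne) in truth.reads.items()],
        READ_SCHEMA,
        out / "truth_reads.tsv",
    )
    paths["truth_reads"] = out / "truth_reads.tsv"

    echo = {
        "sample_id": config.sample_id,
        "seed": config.seed,
        "n_molecules": config.n_molecules,
        "reference_length": len(truth.reference),
        "sub_rate": config.sub_rate,
        "ins_rate": config.ins_rate,
        "del_rate": config.del_rate,
        "minus_strand_fraction": config.minus_strand_fraction,
        "chimera_rate": config.chimera_rate,
        "n_batches": config.n_batches,
        "haplotypes": [
            {"haplotype_id": h.haplotype_id, "level": h.level, "edits": [list(e) for e in h.edits]}
            for h in config.haplotypes
        ],
    }
    with open(out / "sim_config.yaml", "w", newline="\n") as fh:
        yaml.safe_dump(echo, fh, sort_keys=True)
    paths["config"] = out / "sim_config.yaml"
    return paths


def default_design() -> UmiDesign:
    """The dual-UMI design used throughout the examples and tests: 22 bp
    anchors flanking 18 bp UMIs with the classic NNNYR-repeat pattern."""
    return UmiDesign(
        fwd_anchor="CAAGCAGAAGACGGCATACGAG",
        rev_anchor="AATGATACGGCGACCACCGAGA",
        umi_length=18,
        pattern="NNNYRNNNYRNNNYRNNN",
        max_anchor_edits=3,
        max_pattern_mismatches=2,
        terminal_window=200,
        min_read_length=100,
        max_read_length=100_000,
    )
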