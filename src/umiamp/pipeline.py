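"""Offline pipeline orchestration: extract -> cluster -> subsample -> batch
-> polish -> call, per (sample, target).

Each (sample, target) unit is fully independent, so units may run
concurrently; every output file belongs to exactly one unit and the report
is assembled serially in sorted order, which makes parallel runs
byte-identical to serial ones.  All configuration is carried by
:class:`RunConfig`, loadable from a versioned YAML file; validation is
fail-fast so a bad config never leaves partial outputs.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

from umiamp.clustering import (
    ClusterParams,
    batch_clusters,
    subsample_cluster,
    two_step_cluster,
)
from umiamp.consensus import ConsensusRecord, poa_consensus, reference_consensus
from umiamp.extraction import UmiDesign, filter_reads
from umiamp.io import ReadRecord, TargetRegion, read_fasta, read_fastq, write_fasta, write_tsv_table
from umiamp.variants import VariantCall, call_variants, write_variant_table, write_vcf

logger = logging.getLogger(__name__)

REPORT_SCHEMA = [
    "sample_id", "target", "reads_in", "reads_pass", "clusters_raw",
    "clusters_merged", "clusters_passing", "consensus_count", "variant_count",
    "strategy", "seed", "version",
]
CLUSTER_SCHEMA = [
    "cluster_id", "step", "size_raw", "size_after_subsample", "centroid_umi", "parent_ids",
]
CONSENSUS_STATS_SCHEMA = ["cluster_id", "strategy", "n_reads", "mean_support", "length"]
EXTRACTION_SCHEMA = ["read_id", "canonical_umi", "strand", "status"]
TALLY_SCHEMA = ["sample_id", "status", "count"]


@dataclass
class Target:
    """A named target with its reference sequence (may be None for POA mode)."""

    region: TargetRegion
    reference: str | None

    @property
    def name(self) -> str:
        return self.region.name

    @property
    def region_sequence(self) -> str | None:
        if self.reference is None:
            return None
        return self.reference[self.region.start : self.region.end]


@dataclass
class RunConfig:
    samples: list[tuple[str, list[Path]]]
    targets: list[Target]
    design: UmiDesign
    cluster: ClusterParams = field(default_factory=ClusterParams)
    strategy: str = "reference"  # {"poa", "reference"}
    min_level: float = 0.01
    min_alt_count: int = 3
    clusters_per_batch: int = 50
    output_dir: Path = Path("umiamp_out")
    threads: int = 1
    seed: int = 0
    emit_umi_table: bool = False
    emit_vcf: bool = False

    def validate(self) -> None:
        ids = [s for s, _ in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        if self.strategy not in ("poa", "reference"):
            raise ValueError(f"unknown consensus strategy {self.strategy!r}")
        if self.strategy == "reference":
            missing = [t.name for t in self.targets if t.reference is None]
            if missing:
                raise ValueError(
                    "reference strategy requires a reference for targets: " + ", ".join(missing)
                )
        for sample_id, paths in self.samples:
            for p in paths:
                if not Path(p).exists():
                    raise FileNotFoundError(f"sample {sample_id}: missing FASTQ {p}")


@dataclass
class WorkCounters:
    """Hardware-independent counters of algorithmic work done.

    Used by the scaling probe: all three grow linearly with sample count
    because per-sample work is independent.
    """

    reads_processed: int = 0
    alignment_cells: int = 0  # read length x reference length, summed
    clusters_polished: int = 0

    def merge(self, other: "WorkCounters") -> None:
        self.reads_processed += other.reads_processed
        self.alignment_cells += other.alignment_cells
        self.clusters_polished += other.clusters_polished


@dataclass
class UnitResult:
    sample_id: str
    target: str
    reads_in: int
    reads_pass: int
    clusters_raw: int
    clusters_merged: int
    clusters_passing: int
    consensus_count: int
    variant_count: int
    counters: WorkCounters


def load_run_config(path: str | Path) -> RunConfig:
    """Load a versioned YAML run configuration."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw.get("version", 1) != 1:
        raise ValueError("unsupported config version")
    design = UmiDesign(**raw["design"])
    cluster = ClusterParams(**raw.get("cluster", {}))
    targets = []
    for t in raw.get("targets", []):
        reference = None
        ref_id = t.get("reference_id", t["name"])
        if "reference" in t and t["reference"]:
            records = read_fasta(t["reference"])
            if not records:
                raise ValueError(f"empty reference FASTA for target {t['name']}")
            ref_id, reference = records[0]
        length = t.get("end", len(reference) if reference else None)
        if length is None:
            raise ValueError(f"target {t['name']}: end required when no reference is given")
        targets.append(
            Target(
                region=TargetRegion(t["name"], ref_id, t.get("start", 0), length),
                reference=reference,
            )
        )
    samples = [(s["sample_id"], [Path(p) for p in s["fastq"]]) for s in raw["samples"]]
    cfg = RunConfig(
        samples=samples,
        targets=targets,
        design=design,
        cluster=cluster,
        strategy=raw.get("strategy", "reference"),
        min_level=raw.get("min_level", 0.01),
        min_alt_count=raw.get("min_alt_count", 3),
        clusters_per_batch=raw.get("clusters_per_batch", 50),
        output_dir=Path(raw.get("output_dir", "umiamp_out")),
        threads=raw.get("threads", 1),
        seed=raw.get("seed", 0),
        emit_umi_table=raw.get("emit_umi_table", False),
        emit_vcf=raw.get("emit_vcf", False),
    )
    return cfg


def polish_clusters(
    clusters,
    reads_by_id: dict[str, ReadRecord],
    strategy: str,
    reference: str | None,
    cluster_params: ClusterParams,
    seed: int,
    clusters_per_batch: int = 50,
    counters: WorkCounters | None = None,
) -> list[ConsensusRecord]:
    """Subsample, batch and polish clusters with the chosen strategy."""
    capped = [
        subsample_cluster(c, cluster_params.max_reads_per_cluster, seed) for c in clusters
    ]
    records: list[ConsensusRecord] = []
    for batch in batch_clusters(capped, clusters_per_batch):
        for cluster in batch:
            seqs = [reads_by_id[r].sequence for r in cluster.member_read_ids]
            if strategy == "reference":
                assert reference is not None
                record = reference_consensus(seqs, reference, cluster_id=cluster.cluster_id)
                if counters:
                    counters.alignment_cells += sum(len(s) for s in seqs) * len(reference)
            else:
                record = poa_consensus(seqs, cluster_id=cluster.cluster_id)
                if counters:
                    counters.alignment_cells += sum(len(s) for s in seqs) * len(seqs[0])
            if counters:
                counters.clusters_polished += 1
            records.append(record)
    return records


def _run_unit(
    sample_id: str,
    fastq_paths: Sequence[Path],
    target: Target,
    config: RunConfig,
    out_dir: Path,
) -> UnitResult:
    counters = WorkCounters()
    reads: list[ReadRecord] = []
    for path in fastq_paths:
        reads.extend(read_fastq(path, sample_id=sample_id))
    counters.reads_processed = len(reads)

    passed, tally = filter_reads(reads, config.design)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_tsv_table(
        [(sample_id, status, count) for status, count in sorted(tally.items())],
        TALLY_SCHEMA,
        out_dir / "extraction.tsv",
    )
    if config.emit_umi_table:
        write_tsv_table(
            [(e.read_id, e.canonical_umi, e.strand, e.status) for _, e in passed],
            EXTRACTION_SCHEMA,
            out_dir / "umi_table.tsv",
        )

    extractions = [e for _, e in passed]
    reads_by_id = {r.read_id: r for r, _ in passed}
    merged = two_step_cluster(extractions, None, config.design, config.cluster)
    passing = [c for c in merged if c.size >= config.cluster.min_reads_per_cluster]

    capped = [
        subsample_cluster(c, config.cluster.max_reads_per_cluster, config.seed) for c in passing
    ]
    write_tsv_table(
        [
            (c.cluster_id, c.step, orig.size, c.size, c.centroid_umi, ";".join(c.parent_ids))
            for orig, c in zip(passing, capped)
        ],
        CLUSTER_SCHEMA,
        out_dir / "clusters.tsv",
    )

    reference = target.region_sequence
    consensuses = polish_clusters(
        passing,
        reads_by_id,
        config.strategy,
        reference,
        config.cluster,
        config.seed,
        config.clusters_per_batch,
        counters,
    )
    write_fasta(
        [
            (f"{sample_id}/{c.cluster_id}/{c.n_reads}", c.sequence)
            for c in consensuses
        ],
        out_dir / "consensus.fasta",
    )
    write_tsv_table(
        [
            (
                c.cluster_id,
                c.strategy,
                c.n_reads,
                sum(c.per_base_support) / len(c.per_base_support) if c.per_base_support else 0.0,
                len(c.sequence),
            )
            for c in consensuses
        ],
        CONSENSUS_STATS_SCHEMA,
        out_dir / "consensus_stats.tsv",
    )

    calls: list[VariantCall] = []
    if reference is not None and consensuses:
        calls = call_variants(
            consensuses,
            reference,
            min_level=config.min_level,
            min_alt_count=config.min_alt_count,
            reference_id=target.region.reference_id,
        )
        write_variant_table(calls, out_dir / "variants.tsv")
        if config.emit_vcf:
            write_vcf(calls, reference, target.region.reference_id, out_dir / "variants.vcf")

    # step-1 cluster count: number of distinct parents across merged clusters
    clusters_raw = sum(len(c.parent_ids) for c in merged)
    return UnitResult(
        sample_id=sample_id,
        target=target.name,
        reads_in=len(reads),
        reads_pass=len(passed),
        clusters_raw=clusters_raw,
        clusters_merged=len(merged),
        clusters_passing=len(passing),
        consensus_count=len(consensuses),
        variant_count=len(calls),
        counters=counters,
    )


def run_pipeline(config: RunConfig) -> tuple[list[UnitResult], WorkCounters]:
    """Execute the full pipeline for every (sample, target) unit.

    Units run on a thread pool of ``config.threads`` workers; outputs are
    byte-identical to a serial run because units share no mutable state and
    the report is written in sorted unit order after all units finish.
    """
    config.validate()
    out_root = Path(config.output_dir)
    units = [
        (sample_id, paths, target)
        for sample_id, paths in config.samples
        for target in config.targets
    ]

    def work(unit):
        sample_id, paths, target = unit
        unit_dir = out_root / sample_id / target.name
        logger.info("running %s/%s", sample_id, target.name)
        return _run_unit(sample_id, paths, target, config, unit_dir)

    if config.threads > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            results = list(pool.map(work, units))
    else:
        results = [work(u) for u in units]

    results.sort(key=lambda r: (r.sample_id, r.target))
    from umiamp import __version__

    write_tsv_table(
        [
            (
                r.sample_id, r.target, r.reads_in, r.reads_pass, r.clusters_raw,
                r.clusters_merged, r.clusters_passing, r.consensus_count,
                r.variant_count, config.strategy, config.seed, __version__,
            )
            for r in results
        ],
        REPORT_SCHEMA,
        out_root / "report.tsv",
    )
    total = WorkCounters()
    for r in results:
        total.merge(r.counters)
    return results, total


def scaling_probe(
    base_config: "SimProbeConfig", sample_counts: Sequence[int], out_path: str | Path | None = None
) -> list[tuple[int, int, int, int]]:
    """Measure algorithmic work as a function of sample count.

    For each n in *sample_counts* the probe simulates n identical samples
    (different seeds), runs the full pipeline, and records the work counters.
    The counters are hardware-independent mirrors of runtime: if they grow
    linearly in n, so does any per-unit-cost runtime model.
    """
    if not sample_counts or min(sample_counts) < 1:
        raise ValueError("sample_counts must be positive")
    rows: list[tuple[int, int, int, int]] = []
    for n in sample_counts:
        _, counters = run_probe_instance(base_config, n)
        rows.append(
            (n, counters.reads_processed, counters.alignment_cells, counters.clusters_polished)
        )
    if out_path is not None:
        write_tsv_table(
            rows, ["n_samples", "reads_processed", "alignment_cells", "clusters_polished"], out_path
        )
    return rows


@dataclass
class SimProbeConfig:
    """Simulation settings for the scaling probe (kept small on purpose)."""

    n_molecules: int = 20
    reference_length: int = 300
    reads_per_molecule: int = 12
    seed: int = 0
    work_dir: Path = Path("scaling_probe")
    threads: int = 1


def run_probe_instance(probe: SimProbeConfig, n_samples: int) -> tuple[list[UnitResult], WorkCounters]:
    import shutil

    from umiamp.simulate import SimConfig, default_design, simulate_run, write_run

    design = default_design()
    work = Path(probe.work_dir) / f"n{n_samples}"
    if work.exists():
        shutil.rmtree(work)
    samples = []
    reference = None
    for s in range(n_samples):
        # error-free reads: per-sample work is then identical by construction,
        # so the counters isolate scaling with sample count
        sim = SimConfig(
            design=design,
            reference=reference,
            reference_length=probe.reference_length,
            n_molecules=probe.n_molecules,
            reads_per_molecule=probe.reads_per_molecule,
            sub_rate=0.0,
            ins_rate=0.0,
            del_rate=0.0,
            sample_id=f"s{s:02d}",
            seed=probe.seed * 1000 + s + 1,
        )
        reads, truth = simulate_run(sim)
        reference = truth.reference  # share one reference across samples
        paths = write_run(reads, truth, sim, work / f"s{s:02d}")
        samples.append((f"s{s:02d}", [paths["fastq"]]))
    target = Target(
        region=TargetRegion("amplicon", "ref", 0, len(reference)), reference=reference
    )
    cfg = RunConfig(
        samples=samples,
        targets=[target],
        design=design,
        cluster=ClusterParams(min_reads_per_cluster=5),
        strategy="reference",
        output_dir=work / "out",
        seed=probe.seed,
        threads=probe.threads,
    )
    return run_pipeline(cfg)
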