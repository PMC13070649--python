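"""Real-time monitoring of an ongoing sequencing run.

Nanopore instruments write reads in batches while the run is still going;
monitoring the number of UMI clusters per sample as batches arrive lets the
operator stop the run — and free flow-cell capacity — once every sample has
enough molecules for the downstream question.  The monitor keeps a
per-sample incremental cluster store: each new read's canonical UMI joins
the nearest existing centroid within the step-1 edit-distance threshold
(ties to the earliest-founded centroid) or founds a new one.  No global
re-sort is possible online, so the full two-step clustering pass is always
re-run at stop time before polishing; the live counts only drive the stop
decision.

Batch discovery is by polling a watch directory (optionally constrained by a
manifest file listing batch FASTQs in order); the timeline of per-sample
cluster counts is written as TSV.
"""

from __future__ import annotations

import time
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib

from umiamp.clustering import ClusterParams, UmiCluster
from umiamp.extraction import UmiDesign, extract_umis
from umiamp.io import ReadRecord, read_fastq, write_tsv_table

TIMELINE_SCHEMA = ["batch_id", "wall_label", "sample_id", "n_reads", "n_clusters"]


@dataclass
class _SampleStore:
    """Incremental cluster store for one sample."""

    centroids: list[str] = field(default_factory=list)
    member_ids: list[list[str]] = field(default_factory=list)
    n_reads_total: int = 0
    rejections: Counter = field(default_factory=Counter)

    def assign(self, read_id: str, umi: str, max_dist: int) -> None:
        best_idx, best_dist = -1, max_dist + 1
        for idx, centroid in enumerate(self.centroids):
            res = edlib.align(umi, centroid, mode="NW", k=best_dist - 1)
            dist = res["editDistance"]
            if dist != -1 and dist < best_dist:  # strict: ties keep the earliest
                best_idx, best_dist = idx, dist
                if dist == 0:
                    break
        if best_idx >= 0:
            self.member_ids[best_idx].append(read_id)
        else:
            self.centroids.append(umi)
            self.member_ids.append([read_id])

    def n_passing(self, min_reads: int) -> int:
        return sum(1 for members in self.member_ids if len(members) >= min_reads)


@dataclass
class MonitorState:
    """Incremental clustering state plus the cluster-count timeline."""

    threshold: int = 500
    samples: dict[str, _SampleStore] = field(default_factory=dict)
    processed_batches: list[str] = field(default_factory=list)
    timeline: list[tuple[str, str, str, int, int]] = field(default_factory=list)
    stop_flag: bool = False


def process_batch(
    state: MonitorState,
    batch: Iterable[ReadRecord],
    design: UmiDesign,
    params: ClusterParams,
    batch_id: str,
    wall_label: str = "",
) -> MonitorState:
    """Fold one batch of reads into the incremental cluster store.

    Every passing read's canonical UMI is assigned to the nearest existing
    centroid within ``max_edit_dist_step1`` (ties to the earliest-founded
    centroid) or founds a new centroid.  One timeline row per known sample is
    appended; the reported cluster count only includes clusters with at
    least ``min_reads_per_cluster`` reads, since early counts would otherwise
    be inflated by singletons.  Re-submitting a batch_id is an error.
    """
    if batch_id in state.processed_batches:
        raise ValueError(f"batch {batch_id!r} already processed")
    for read in batch:
        store = state.samples.setdefault(read.sample_id, _SampleStore())
        store.n_reads_total += 1
        ext = extract_umis(read, design)
        if ext.status != "pass":
            store.rejections[ext.status] += 1
            continue
        store.assign(read.read_id, ext.canonical_umi, params.max_edit_dist_step1)
    state.processed_batches.append(batch_id)
    for sample_id in sorted(state.samples):
        store = state.samples[sample_id]
        state.timeline.append(
            (
                batch_id,
                wall_label,
                sample_id,
                store.n_reads_total,
                store.n_passing(params.min_reads_per_cluster),
            )
        )
    state.stop_flag = should_stop(state, state.threshold, params)
    return state


def should_stop(state: MonitorState, threshold: int, params: ClusterParams) -> bool:
    """True iff every sample's passing-cluster count has reached *threshold*."""
    if not state.processed_batches:
        raise ValueError("no batches processed yet")
    if not state.samples:
        return False
    return all(
        store.n_passing(params.min_reads_per_cluster) >= threshold
        for store in state.samples.values()
    )


def final_clusters(state: MonitorState, sample_id: str) -> list[UmiCluster]:
    """The incremental clusters for one sample, in founding order.

    These back the live counts only; run the offline two-step pass over the
    accumulated reads before polishing.
    """
    store = state.samples[sample_id]
    return [
        UmiCluster(
            cluster_id=f"l{idx:05d}",
            centroid_umi=centroid,
            member_read_ids=list(members),
            step="raw",
        )
        for idx, (centroid, members) in enumerate(zip(store.centroids, store.member_ids))
    ]


def sample_from_batch_name(name: str) -> str:
    """Samples are encoded in batch file names as '<sample>_batch<NNN>.fastq'."""
    stem = Path(name).name
    for suffix in (".fastq.gz", ".fastq", ".fq.gz", ".fq"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    if "_batch" in stem:
        return stem.rsplit("_batch", 1)[0]
    return stem


def _batch_index(name: str) -> int:
    stem = Path(name).name.split(".", 1)[0]
    if "_batch" in stem:
        suffix = stem.rsplit("_batch", 1)[1]
        if suffix.isdigit():
            return int(suffix)
    return -1


def _discover(run_directory: Path, manifest: Path | None) -> list[Path]:
    if manifest is not None:
        with open(manifest) as fh:
            names = [line.strip() for line in fh if line.strip()]
        return [run_directory / n for n in names]
    # interleave samples by batch index (arrival order on a real run),
    # then name for determinism
    found = sorted(
        (
            p for p in run_directory.iterdir()
            if p.suffix in (".fastq", ".fq") or p.name.endswith((".fastq.gz", ".fq.gz"))
        ),
        key=lambda p: (_batch_index(p.name), p.name),
    )
    return found


def replay(
    run_directory: str | Path,
    design: UmiDesign,
    params: ClusterParams,
    threshold: int = 500,
    manifest: str | Path | None = None,
    stop_early: bool = False,
    timeline_path: str | Path | None = None,
) -> MonitorState:
    """Process every batch file in a run directory in deterministic order.

    Order is the manifest's if given, else lexicographic file name order
    (batch files carry zero-padded indices, so name order is arrival order).
    With ``stop_early`` the replay stops at the first batch after which every
    sample meets *threshold*.  A convenience harness for tests and the live
    demo; the polling loop in the CLI calls the same :func:`process_batch`.
    """
    run_directory = Path(run_directory)
    batches = _discover(run_directory, Path(manifest) if manifest else None)
    if not batches:
        raise ValueError(f"no FASTQ batches found in {run_directory}")
    state = MonitorState(threshold=threshold)
    for path in batches:
        sample_id = sample_from_batch_name(path.name)
        reads = read_fastq(path, sample_id=sample_id)
        tagged = (
            ReadRecord(r.read_id, r.sequence, r.qualities, r.sample_id, path.name)
            for r in reads
        )
        process_batch(state, tagged, design, params, batch_id=path.name)
        if stop_early and state.stop_flag:
            break
    if timeline_path is not None:
        write_tsv_table(state.timeline, TIMELINE_SCHEMA, timeline_path)
    return state


def watch(
    run_directory: str | Path,
    design: UmiDesign,
    params: ClusterParams,
    threshold: int = 500,
    poll_seconds: float = 5.0,
    manifest: str | Path | None = None,
    max_polls: int | None = None,
    status_path: str | Path | None = None,
    timeline_path: str | Path | None = None,
) -> MonitorState:
    """Poll a directory for new batch FASTQs until the stop condition holds.

    Polling (rather than file-system event APIs) is the contract: it is
    portable and testable.  ``max_polls`` bounds the loop for tests; the stop
    decision is written as a one-line status file when *status_path* is set.
    """
    run_directory = Path(run_directory)
    state = MonitorState(threshold=threshold)
    polls = 0
    while True:
        for path in _discover(run_directory, Path(manifest) if manifest else None):
            if path.name in state.processed_batches or not path.exists():
                continue
            sample_id = sample_from_batch_name(path.name)
            reads = read_fastq(path, sample_id=sample_id)
            tagged = (
                ReadRecord(r.read_id, r.sequence, r.qualities, r.sample_id, path.name)
                for r in reads
            )
            process_batch(state, tagged, design, params, batch_id=path.name)
        if state.processed_batches and state.stop_flag:
            break
        polls += 1
        if max_polls is not None and polls >= max_polls:
            break
        time.sleep(poll_seconds)
    if timeline_path is not None:
        write_tsv_table(state.timeline, TIMELINE_SCHEMA, timeline_path)
    if status_path is not None:
        decision = "STOP" if state.stop_flag else "CONTINUE"
        counts = {
            s: state.samples[s].n_passing(params.min_reads_per_cluster)
            for s in sorted(state.samples)
        }
        with open(status_path, "w", newline="\n") as fh:
            fh.write(
                f"{decision}\tthreshold={threshold}\t"
                + "\t".join(f"{s}={c}" for s, c in counts.items())
                + "\n"
            )
    return state
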