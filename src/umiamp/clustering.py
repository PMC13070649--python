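"""Two-step greedy UMI clustering.

Step 1 groups raw canonical UMIs by greedy abundance-sorted centroid
clustering at an edit-distance threshold — the classic amplicon heuristic:
identical UMIs are grouped, groups are visited in order of descending
abundance (ties lexicographic), and each group joins the first existing
cluster whose centroid is within the threshold or founds a new one.  Step 2
builds a column-majority consensus UMI for every surviving cluster and
re-clusters those, merging clusters whose consensus UMIs still fall within a
(typically tighter) threshold.  The second pass absorbs satellite clusters
founded by error-bearing UMI copies of an abundant molecule, which is what
makes the clustering robust to the high indel rate of nanopore reads.

All ordering rules (abundance sort, founding order, lexicographic
tie-breaks) are explicit so results are bit-reproducible under any
permutation of the input reads.
"""

from __future__ import annotations

import zlib
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import edlib
import numpy as np

from umiamp.extraction import UmiDesign, UmiExtraction
from umiamp.io import ReadRecord


@dataclass
class UmiCluster:
    """A set of reads sharing (approximately) one canonical UMI."""

    cluster_id: str
    centroid_umi: str
    member_read_ids: list[str]
    step: str = "raw"  # {"raw", "merged"}
    parent_ids: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_read_ids)


@dataclass(frozen=True)
class ClusterParams:
    """Thresholds and caps for the two clustering steps.

    Edit-distance thresholds apply to the concatenated (2 x umi_length)
    canonical UMI.  ``max_reads_per_cluster`` caps cluster size by uniform
    subsampling before polishing.
    """

    max_edit_dist_step1: int = 3
    max_edit_dist_step2: int = 2
    min_reads_per_cluster: int = 10
    max_reads_per_cluster: int = 60
    subsample_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_reads_per_cluster < 1:
            raise ValueError("min_reads_per_cluster must be >= 1")
        if self.max_reads_per_cluster < self.min_reads_per_cluster:
            raise ValueError("max_reads_per_cluster must be >= min_reads_per_cluster")


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance with unit costs."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, mode="NW")["editDistance"]


def _within(a: str, b: str, max_dist: int) -> bool:
    if not a or not b:
        return abs(len(a) - len(b)) <= max_dist and max(len(a), len(b)) <= max_dist
    return edlib.align(a, b, mode="NW", k=max_dist)["editDistance"] != -1


def greedy_cluster(
    umis: Sequence[tuple[str, str]],
    max_dist: int,
    *,
    sort_groups: bool = True,
    id_prefix: str = "c",
) -> list[UmiCluster]:
    """Greedy centroid clustering of (read_id, canonical_umi) pairs.

    Identical UMIs are grouped first; groups are scanned in descending
    abundance (ties by lexicographic UMI) and each joins the first existing
    cluster whose centroid is within *max_dist*, else founds a new cluster
    with itself as centroid.  Centroids never change after founding; output
    order is founding order.

    ``sort_groups=False`` scans groups in first-appearance order instead,
    which is the behaviour the streaming live monitor can reproduce.
    """
    groups: dict[str, list[str]] = {}
    for read_id, umi in umis:
        groups.setdefault(umi, []).append(read_id)
    keys = list(groups)
    if sort_groups:
        keys.sort(key=lambda u: (-len(groups[u]), u))

    clusters: list[UmiCluster] = []
    for umi in keys:
        members = groups[umi]
        for cluster in clusters:
            if _within(umi, cluster.centroid_umi, max_dist):
                cluster.member_read_ids.extend(members)
                break
        else:
            clusters.append(
                UmiCluster(
                    cluster_id=f"{id_prefix}{len(clusters):05d}",
                    centroid_umi=umi,
                    member_read_ids=list(members),
                    step="raw",
                )
            )
    return clusters


def consensus_umi(member_umis: Sequence[str], centroid: str) -> str:
    """Column-wise majority over equal-length canonical UMIs; ties keep the
    centroid base.  Canonical UMIs are fixed-length by design, so no MSA is
    needed."""
    length = len(centroid)
    out = []
    for col in range(length):
        counts = Counter(u[col] for u in member_umis if len(u) == length)
        if not counts:
            out.append(centroid[col])
            continue
        top = max(counts.values())
        winners = sorted(b for b, c in counts.items() if c == top)
        out.append(centroid[col] if centroid[col] in winners else winners[0])
    return "".join(out)


def two_step_cluster(
    extractions: Sequence[UmiExtraction],
    reads: Sequence[ReadRecord] | None,
    design: UmiDesign,
    params: ClusterParams,
    consensus_fn: Callable | None = None,
) -> list[UmiCluster]:
    """Robust two-step clustering of extracted canonical UMIs.

    Step 1: greedy clustering of raw canonical UMIs at
    ``max_edit_dist_step1``; clusters smaller than ``min_reads_per_cluster``
    are discarded.  Step 2: each surviving cluster is summarized by a
    column-majority consensus UMI over its members' canonical UMIs; these
    consensus UMIs are greedily re-clustered at ``max_edit_dist_step2`` with
    each weighted by its step-1 size, and co-clustered step-1 clusters are
    merged (member sets unioned, provenance kept in ``parent_ids``).

    *reads* and *consensus_fn* are accepted for interface symmetry with the
    polishing stage; the UMI-level consensus is always column majority.
    """
    umi_by_read = {e.read_id: e.canonical_umi for e in extractions if e.status == "pass"}
    pairs = [(e.read_id, e.canonical_umi) for e in extractions if e.status == "pass"]
    step1 = greedy_cluster(pairs, params.max_edit_dist_step1, id_prefix="c")
    step1 = [c for c in step1 if c.size >= params.min_reads_per_cluster]

    # weight each consensus UMI by its step-1 cluster size: repeat the UMI so
    # the abundance sort in greedy_cluster sees the true weights
    cons_umis: dict[str, str] = {}
    weighted: list[tuple[str, str]] = []
    for cluster in step1:
        cu = consensus_umi([umi_by_read[r] for r in cluster.member_read_ids], cluster.centroid_umi)
        cons_umis[cluster.cluster_id] = cu
        weighted.extend((cluster.cluster_id, cu) for _ in range(cluster.size))

    step2 = greedy_cluster(weighted, params.max_edit_dist_step2, id_prefix="m")

    by_id = {c.cluster_id: c for c in step1}
    merged: list[UmiCluster] = []
    for meta in step2:
        parents = list(dict.fromkeys(meta.member_read_ids))  # de-duplicate, keep order
        members: list[str] = []
        for pid in parents:
            members.extend(by_id[pid].member_read_ids)
        merged.append(
            UmiCluster(
                cluster_id=f"m{len(merged):05d}",
                centroid_umi=meta.centroid_umi,
                member_read_ids=members,
                step="merged",
                parent_ids=parents,
            )
        )
    return merged


def subsample_cluster(cluster: UmiCluster, max_reads: int, seed: int) -> UmiCluster:
    """Cap cluster size by uniform sampling without replacement.

    Deterministic under (seed, cluster_id); the sampled members keep their
    original relative order.  Returns the cluster unchanged if already within
    the cap.
    """
    if max_reads < 1:
        raise ValueError("max_reads must be >= 1")
    if cluster.size <= max_reads:
        return cluster
    rng = np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(cluster.cluster_id.encode())])
    idx = np.sort(rng.choice(cluster.size, size=max_reads, replace=False))
    return UmiCluster(
        cluster_id=cluster.cluster_id,
        centroid_umi=cluster.centroid_umi,
        member_read_ids=[cluster.member_read_ids[i] for i in idx],
        step=cluster.step,
        parent_ids=list(cluster.parent_ids),
    )


def batch_clusters(clusters: Sequence[UmiCluster], clusters_per_batch: int) -> list[list[UmiCluster]]:
    """Stable partition into consecutive batches; all full except possibly the last."""
    if clusters_per_batch < 1:
        raise ValueError("clusters_per_batch must be >= 1")
    return [
        list(clusters[i : i + clusters_per_batch])
        for i in range(0, len(clusters), clusters_per_batch)
    ]
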