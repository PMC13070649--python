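"""End-to-end accuracy benchmarks computed on simulated runs.

These harnesses drive the full pipeline on simulator output and measure
accuracy against the simulator's ground truth.  They are used by the
reproduction script and the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from umiamp.clustering import ClusterParams, subsample_cluster, two_step_cluster
from umiamp.consensus import poa_consensus, reference_consensus
from umiamp.extraction import filter_reads
from umiamp.simulate import SimConfig, default_design, simulate_run


@dataclass
class ConsensusAccuracy:
    mean_error_percent: float
    n_clusters: int
    n_reads_simulated: int


def consensus_accuracy(
    seed: int,
    n_molecules: int = 100,
    reads_per_molecule: int = 50,
    reference_length: int = 500,
    sub_rate: float = 0.025,
    ins_rate: float = 0.0125,
    del_rate: float = 0.0125,
    strategy: str = "reference",
    params: ClusterParams | None = None,
) -> ConsensusAccuracy:
    """Mean consensus-vs-truth per-base error over simulated UMI clusters.

    Simulates tagged molecules with a fixed read multiplicity and the given
    per-base error rates, runs extraction, two-step clustering and consensus
    polishing, matches every cluster to its molecule by nearest canonical
    UMI, and averages edit distance / true length over clusters.  The result
    is a percentage (0.01 means one error per 10 kb).
    """
    design = default_design()
    params = params or ClusterParams()
    config = SimConfig(
        design=design,
        reference_length=reference_length,
        n_molecules=n_molecules,
        reads_per_molecule=reads_per_molecule,
        sub_rate=sub_rate,
        ins_rate=ins_rate,
        del_rate=del_rate,
        seed=seed,
    )
    reads, truth = simulate_run(config)
    passed, _ = filter_reads(reads, design)
    by_id = {r.read_id: r for r, _ in passed}
    clusters = two_step_cluster([e for _, e in passed], None, design, params)
    total = 0.0
    n = 0
    for cluster in clusters:
        capped = subsample_cluster(cluster, params.max_reads_per_cluster, seed)
        seqs = [by_id[r].sequence for r in capped.member_read_ids]
        if strategy == "reference":
            record = reference_consensus(seqs, truth.reference, cluster_id=cluster.cluster_id)
        else:
            record = poa_consensus(seqs, cluster_id=cluster.cluster_id)
        molecule = min(
            truth.molecules,
            key=lambda m: edlib.align(cluster.centroid_umi, m.canonical_umi, mode="NW")[
                "editDistance"
            ],
        )
        dist = edlib.align(record.sequence, molecule.insert, mode="NW")["editDistance"]
        total += dist / len(molecule.insert)
        n += 1
    return ConsensusAccuracy(
        mean_error_percent=100.0 * total / n if n else float("nan"),
        n_clusters=n,
        n_reads_simulated=len(reads),
    )
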