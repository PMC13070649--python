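from __future__ import annotations

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import levenshtein
from umiamp.clustering import (
    ClusterParams,
    batch_clusters,
    consensus_umi,
    edit_distance,
    greedy_cluster,
    subsample_cluster,
    two_step_cluster,
    UmiCluster,
)
from umiamp.extraction import filter_reads
from umiamp.simulate import simulate_run

from conftest import make_sim

dna = st.text(alphabet="ACGT", max_size=12)


class TestEditDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [("", "", 0), ("ACGT", "ACGA", 1), ("AC", "CA", 2), ("", "ACG", 3), ("ACG", "", 3)],
    )
    def test_examples(self, a, b, expected):
        assert edit_distance(a, b) == expected

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(dna, dna)
    def test_matches_dp_oracle(self, a, b):
        assert edit_distance(a, b) == levenshtein(a, b)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(dna, dna, dna)
    def test_metric_properties(self, a, b, c):
        assert edit_distance(a, b) == edit_distance(b, a)
        assert edit_distance(a, c) <= edit_distance(a, b) + edit_distance(b, c)
        assert (edit_distance(a, b) == 0) == (a == b)


class TestGreedyCluster:
    def test_threshold_zero_is_exact_grouping(self):
        umis = [("r1", "AAAA"), ("r2", "AAAA"), ("r3", "CCCC")]
        clusters = greedy_cluster(umis, 0)
        assert sorted(c.size for c in clusters) == [1, 2]

    def test_satellite_joins_abundant_centroid(self):
        umis = [(f"r{i}", "AAAA") for i in range(3)] + [("r3", "AAAT")]
        assert levenshtein("AAAA", "AAAT") == 1
        clusters = greedy_cluster(umis, 1)
        assert len(clusters) == 1
        assert clusters[0].centroid_umi == "AAAA"
        assert clusters[0].size == 4

    def test_distant_umis_stay_separate(self):
        umis = [("r1", "AAAA"), ("r2", "AAAA"), ("r3", "TTTT"), ("r4", "TTTT")]
        assert len(greedy_cluster(umis, 1)) == 2

    def test_empty_input(self):
        assert greedy_cluster([], 2) == []

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.sampled_from(["AAAA", "AAAT", "CCCC", "GGGG", "CCCG"]), max_size=20))
    def test_threshold_zero_matches_hash_grouping(self, umi_list):
        umis = [(f"r{i}", u) for i, u in enumerate(umi_list)]
        clusters = greedy_cluster(umis, 0)
        want = Counter(umi_list)
        assert Counter({c.centroid_umi: c.size for c in clusters}) == want

    def test_permutation_invariance(self, rng):
        """Any permutation of reads with the same UMI multiset gives identical
        clusters, thanks to the abundance-then-lexicographic ordering."""
        base = [(f"r{i}", u) for i, u in enumerate(
            ["AAAA"] * 4 + ["AAAT"] * 2 + ["TTTT"] * 3 + ["TTAT"] * 1
        )]
        reference = greedy_cluster(base, 1)
        for _ in range(5):
            perm = [base[i] for i in rng.permutation(len(base))]
            got = greedy_cluster(perm, 1)
            assert [c.centroid_umi for c in got] == [c.centroid_umi for c in reference]
            assert [sorted(c.member_read_ids) for c in got] == [
                sorted(c.member_read_ids) for c in reference
            ]

    def test_members_disjoint(self):
        umis = [(f"r{i}", u) for i, u in enumerate(["AAAA", "AAAT", "AATT", "TTTT"])]
        clusters = greedy_cluster(umis, 1)
        all_ids = [r for c in clusters for r in c.member_read_ids]
        assert len(all_ids) == len(set(all_ids)) == 4


class TestConsensusUmi:
    def test_majority_vote(self):
        assert consensus_umi(["AAAA", "AAAT", "AAAA"], "AAAA") == "AAAA"

    def test_tie_keeps_centroid_base(self):
        assert consensus_umi(["AAAA", "AAAT"], "AAAT") == "AAAT"


class TestTwoStepCluster:
    def test_satellite_merged_in_step2(self, design):
        """Step-1 clusters whose consensus UMIs are within the step-2
        threshold are merged with member sets unioned."""
        config = make_sim(design, n_molecules=6, reads_per_molecule=12, seed=21)
        reads, truth = simulate_run(config)
        passed, _ = filter_reads(reads, design)
        exts = [e for _, e in passed]
        params = ClusterParams(min_reads_per_cluster=2)
        merged = two_step_cluster(exts, None, design, params)
        assert len(merged) == len(truth.molecules)
        for c in merged:
            assert c.step == "merged"
            assert c.parent_ids  # provenance recorded
            assert c.size >= params.min_reads_per_cluster

    def test_single_cluster_passthrough(self, design):
        exts_like = [(f"r{i}", "A" * 36) for i in range(5)]
        from umiamp.extraction import UmiExtraction

        exts = [UmiExtraction(read_id=r, canonical_umi=u, status="pass") for r, u in exts_like]
        merged = two_step_cluster(exts, None, design, ClusterParams(min_reads_per_cluster=2))
        assert len(merged) == 1
        assert merged[0].step == "merged"
        assert merged[0].parent_ids == ["c00000"]
        assert merged[0].size == 5

    def test_cluster_recovery_simulated(self, design):
        """With per-read UMI errors and well-separated true UMIs, merged
        clusters reproduce the molecule partition (ARI ~ 1)."""
        from sklearn.metrics import adjusted_rand_score

        config = make_sim(design, n_molecules=30, reads_per_molecule=20,
                          sub_rate=0.02, ins_rate=0.01, del_rate=0.01, seed=31)
        reads, truth = simulate_run(config)
        passed, _ = filter_reads(reads, design)
        exts = [e for _, e in passed]
        merged = two_step_cluster(exts, None, design, ClusterParams())
        read2mol = {rid: mid for rid, (mid, _, _) in truth.reads.items()}
        labels_true, labels_pred = [], []
        for idx, c in enumerate(merged):
            for rid in c.member_read_ids:
                labels_pred.append(idx)
                labels_true.append(read2mol[rid])
        assert adjusted_rand_score(labels_true, labels_pred) >= 0.99

    def test_zero_error_counts_match_molecules(self, design):
        """Collision-free UMIs, no read errors: passing merged clusters
        correspond 1:1 to molecules with enough surviving reads."""
        config = make_sim(design, n_molecules=25, reads_per_molecule=11, seed=41)
        reads, truth = simulate_run(config)
        passed, _ = filter_reads(reads, design)
        exts = [e for _, e in passed]
        params = ClusterParams(min_reads_per_cluster=10)
        merged = two_step_cluster(exts, None, design, params)
        surviving = Counter(
            truth.reads[e.read_id][0] for e in exts
        )
        want = sum(1 for n in surviving.values() if n >= params.min_reads_per_cluster)
        assert len(merged) == want == 25


class TestSubsample:
    def test_identity_below_cap(self):
        c = UmiCluster("c1", "AAAA", [f"r{i}" for i in range(10)])
        assert subsample_cluster(c, 20, seed=1) is c

    def test_deterministic(self):
        c = UmiCluster("c1", "AAAA", [f"r{i}" for i in range(100)])
        a = subsample_cluster(c, 50, seed=7)
        b = subsample_cluster(c, 50, seed=7)
        assert a.member_read_ids == b.member_read_ids
        assert len(a.member_read_ids) == 50
        assert set(a.member_read_ids) <= set(c.member_read_ids)

    def test_seed_and_cluster_sensitivity(self):
        c1 = UmiCluster("c1", "AAAA", [f"r{i}" for i in range(100)])
        c2 = UmiCluster("c2", "AAAA", [f"r{i}" for i in range(100)])
        assert (
            subsample_cluster(c1, 50, seed=7).member_read_ids
            != subsample_cluster(c2, 50, seed=7).member_read_ids
        )

    def test_max_one(self):
        c = UmiCluster("c1", "AAAA", ["r1", "r2", "r3"])
        assert subsample_cluster(c, 1, seed=0).size == 1


class TestBatching:
    @pytest.mark.parametrize(
        "n, per, sizes",
        [(10, 4, [4, 4, 2]), (3, 10, [3]), (0, 5, []), (8, 4, [4, 4])],
    )
    def test_partition(self, n, per, sizes):
        clusters = [UmiCluster(f"c{i}", "AAAA", ["r"]) for i in range(n)]
        batches = batch_clusters(clusters, per)
        assert [len(b) for b in batches] == sizes
        flat = [c.cluster_id for b in batches for c in b]
        assert flat == [c.cluster_id for c in clusters]
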