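from __future__ import annotations

import edlib
import numpy as np
import pytest

from oracles import enumerate_heaviest_path
from umiamp.clustering import ClusterParams, two_step_cluster
from umiamp.consensus import (
    PoaGraph,
    heaviest_path,
    poa_align,
    poa_consensus,
    reference_consensus,
    support_to_phred,
)
from umiamp.extraction import filter_reads
from umiamp.simulate import simulate_run
from umiamp.variants import call_variants

from conftest import make_sim


class TestPoaAlign:
    def test_first_read_builds_linear_path(self):
        g = poa_align(PoaGraph(), "ACGT")
        assert len(g) == 4
        assert [g.bases[n] for n in range(2, 6)] == list("ACGT")
        assert all(g.node_weight[n] == 1 for n in range(2, 6))

    def test_identical_read_fuses(self):
        g = poa_align(poa_align(PoaGraph(), "ACGT"), "ACGT")
        assert len(g) == 4
        assert all(g.node_weight[n] == 2 for n in range(2, 6))

    def test_mismatch_branches_and_majority_wins(self):
        g = PoaGraph()
        for read in ["ACGT", "ACGT", "AGGT"]:
            poa_align(g, read)
        assert "".join(g.bases[n] for n in heaviest_path(g)) == "ACGT"

    def test_graph_stays_acyclic(self):
        g = PoaGraph()
        for read in ["ACGTACGT", "ACTACGT", "ACGGTACG", "TTACGT"]:
            poa_align(g, read)
        g.topological_order()  # raises on a cycle


class TestPoaConsensus:
    def test_identical_reads(self):
        rec = poa_consensus(["ACGTACG"] * 5)
        assert rec.sequence == "ACGTACG"
        assert rec.per_base_support == [1.0] * 7
        assert rec.n_reads == 5

    def test_single_read(self):
        rec = poa_consensus(["GATTACA"])
        assert rec.sequence == "GATTACA"
        assert rec.per_base_support == [1.0] * 7

    def test_majority_substitution(self):
        rec = poa_consensus(["ACGT", "ACGT", "ACGT", "ACGA"])
        assert rec.sequence == "ACGT"

    def test_empty_cluster_errors(self):
        with pytest.raises(ValueError):
            poa_consensus([])

    def test_matches_path_enumeration_oracle(self, rng):
        """On small random clusters the DP consensus equals exhaustive
        enumeration of all start-to-end paths of the same graph."""
        bases = np.array(list("ACGT"))
        for _ in range(200):
            n_reads = int(rng.integers(1, 5))
            length = int(rng.integers(1, 9))
            template = "".join(rng.choice(bases, size=length))
            reads = []
            for _ in range(n_reads):
                read = list(template)
                if rng.random() < 0.5 and length > 1:  # one random edit
                    pos = int(rng.integers(0, length))
                    op = rng.random()
                    if op < 0.4:
                        read[pos] = str(rng.choice(bases))
                    elif op < 0.7:
                        read.insert(pos, str(rng.choice(bases)))
                    else:
                        del read[pos]
                reads.append("".join(read) or "A")
            rec = poa_consensus(reads)
            ordered = sorted(reads, key=lambda s: (-len(s), s))
            g = PoaGraph()
            for r in ordered:
                poa_align(g, r)
            assert rec.sequence == enumerate_heaviest_path(g)

    def test_error_free_cluster_recovers_molecule(self, perfect_run, design):
        reads, truth, _ = perfect_run
        passed, _ = filter_reads(reads, design)
        by_id = {r.read_id: r for r, _ in passed}
        clusters = two_step_cluster(
            [e for _, e in passed], None, design, ClusterParams(min_reads_per_cluster=2)
        )
        umi2mol = {m.canonical_umi: m for m in truth.molecules}
        for c in clusters[:5]:
            seqs = [by_id[r].sequence for r in c.member_read_ids]
            rec = poa_consensus(seqs, cluster_id=c.cluster_id)
            assert rec.sequence == umi2mol[c.centroid_umi].insert


class TestReferenceConsensus:
    def test_reads_equal_reference(self):
        ref = "ACGTACGTAA"
        rec = reference_consensus([ref] * 4, ref)
        assert rec.sequence == ref
        assert rec.per_base_support == [1.0] * len(ref)
        assert rec.strategy == "reference"

    def test_unanimous_substitution(self):
        ref = "ACGTACGTAA"
        read = ref[:7] + "T" + ref[8:]
        rec = reference_consensus([read] * 3, ref)
        assert rec.sequence == read

    def test_tie_keeps_reference_base(self):
        ref = "ACGTACGTAA"
        alt = ref[:4] + "T" + ref[5:]
        rec = reference_consensus([ref, alt], ref)
        assert rec.sequence == ref

    def test_majority_deletion(self):
        ref = "ACGTACGTAA"
        dele = ref[:4] + ref[5:]
        rec = reference_consensus([dele, dele, ref], ref)
        assert rec.sequence == dele

    def test_insertion_needs_strict_majority(self):
        ref = "ACGTACGTAA"
        ins = ref[:5] + "G" + ref[5:]
        # 2 of 4: no strict majority, insertion suppressed
        assert reference_consensus([ins, ins, ref, ref], ref).sequence == ref
        # 3 of 4: emitted
        assert reference_consensus([ins, ins, ins, ref], ref).sequence == ins

    def test_permutation_invariant(self, rng):
        ref = "ACGTACGTACGTACGT"
        reads = [ref, ref[:3] + "A" + ref[4:], ref[:9] + ref[10:], ref, ref[:12] + "TT" + ref[12:]]
        want = reference_consensus(reads, ref).sequence
        for _ in range(5):
            perm = [reads[i] for i in rng.permutation(len(reads))]
            assert reference_consensus(perm, ref).sequence == want

    def test_error_free_cluster_recovers_molecule(self, perfect_run, design):
        reads, truth, _ = perfect_run
        passed, _ = filter_reads(reads, design)
        by_id = {r.read_id: r for r, _ in passed}
        clusters = two_step_cluster(
            [e for _, e in passed], None, design, ClusterParams(min_reads_per_cluster=2)
        )
        umi2mol = {m.canonical_umi: m for m in truth.molecules}
        for c in clusters:
            seqs = [by_id[r].sequence for r in c.member_read_ids]
            rec = reference_consensus(seqs, truth.reference, cluster_id=c.cluster_id)
            assert rec.sequence == umi2mol[c.centroid_umi].insert

    def test_empty_inputs_error(self):
        with pytest.raises(ValueError):
            reference_consensus([], "ACGT")
        with pytest.raises(ValueError):
            reference_consensus(["ACGT"], "")


class TestSupportToPhred:
    @pytest.mark.parametrize(
        "support, n_reads, expected",
        [(1.0, 9, 10), (0.5, 1000, 3), (1.0, 10**7, 60), (0.0, 10, 0), (1.0, 99, 20)],
    )
    def test_closed_form(self, support, n_reads, expected):
        assert support_to_phred(support, n_reads) == expected

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            support_to_phred(1.5, 10)


class TestAccuracyProperties:
    def test_error_rate_non_increasing_with_cluster_size(self, design):
        """Paired seeds: consensus error with 20 reads vs 60 reads per
        cluster; more reads never hurt on average."""
        errs = {}
        for n_reads in (20, 60):
            config = make_sim(design, n_molecules=8, reference_length=300,
                              reads_per_molecule=n_reads,
                              sub_rate=0.025, ins_rate=0.0125, del_rate=0.0125,
                              seed=77)
            reads, truth = simulate_run(config)
            passed, _ = filter_reads(reads, design)
            by_id = {r.read_id: r for r, _ in passed}
            clusters = two_step_cluster([e for _, e in passed], None, design, ClusterParams())
            umi2mol = {m.canonical_umi: m for m in truth.molecules}
            total = 0
            for c in clusters:
                seqs = [by_id[r].sequence for r in c.member_read_ids][:60]
                rec = reference_consensus(seqs, truth.reference)
                mol = min(
                    truth.molecules,
                    key=lambda m: edlib.align(c.centroid_umi, m.canonical_umi, mode="NW")["editDistance"],
                )
                total += edlib.align(rec.sequence, mol.insert, mode="NW")["editDistance"]
            errs[n_reads] = total / len(clusters)
        assert errs[60] <= errs[20]

    def test_strategy_agreement_on_variants(self, design):
        """POA and reference polishing give identical downstream variant
        calls when the true reference is supplied."""
        from umiamp.simulate import Haplotype, random_dna

        reference = random_dna(200, np.random.default_rng(99))
        alt = lambda pos: "ACGT"[("ACGT".index(reference[pos]) + 1) % 4]
        hap = Haplotype("h1", (("sub", 40, alt(40)), ("sub", 120, alt(120))), 0.4)
        config = make_sim(design, n_molecules=12, reference=reference,
                          reads_per_molecule=25,
                          sub_rate=0.02, ins_rate=0.01, del_rate=0.01,
                          haplotypes=(hap,), seed=55)
        reads, truth = simulate_run(config)
        passed, _ = filter_reads(reads, design)
        by_id = {r.read_id: r for r, _ in passed}
        clusters = two_step_cluster([e for _, e in passed], None, design, ClusterParams())
        poa_recs, ref_recs = [], []
        for c in clusters:
            seqs = [by_id[r].sequence for r in c.member_read_ids][:60]
            poa_recs.append(poa_consensus(seqs, cluster_id=c.cluster_id))
            ref_recs.append(reference_consensus(seqs, truth.reference, cluster_id=c.cluster_id))
        va = call_variants(poa_recs, truth.reference, min_level=0.05, min_alt_count=2)
        vb = call_variants(ref_recs, truth.reference, min_level=0.05, min_alt_count=2)
        assert [(c.pos, c.ref_allele, c.alt_allele, c.alt_count) for c in va] == [
            (c.pos, c.ref_allele, c.alt_allele, c.alt_count) for c in vb
        ]
        assert len(va) == 2
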