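"""Fragment statistics (relbit, percent overlap), decisions, and fusion."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from panfix.defrag import (
    apply_fusions,
    call_fragments,
    find_duplicate_clusters,
    fuse_sequences,
    fusion_decision,
    order_fragments,
    percent_overlap,
    relbit,
    relbit_from_means,
)
from panfix.model import (
    AA_ORDER,
    FragmentPair,
    GeneCall,
    GenomeRecord,
    InputError,
    Msa,
    PangenomeState,
    StageError,
)

from .oracles import percent_overlap_oracle, relbit_oracle


def _mask_row(occupied, width):
    return "".join("A" if i in occupied else "-" for i in range(width))


class TestRelbit:
    def test_equal_means_give_one(self):
        assert relbit_from_means(50.0, 50.0, 50.0) == pytest.approx(1.0)

    def test_printed_arithmetic_example(self):
        # bit(A,B)=20 with mean_A=100 and mean_B=80 -> max(0.20, 0.25)
        assert relbit_from_means(20.0, 100.0, 80.0) == pytest.approx(0.25)

    def test_cluster_of_focal_pair_only_is_unevaluable(self, params):
        a = GeneCall("a", "g1", 0, 30, "+", "MKTAYIAKQR")
        b = GeneCall("b", "g1", 100, 130, "+", "WWPPGGHHEE")
        assert relbit(a, b, [a, b], params) is None

    def test_matches_direct_summation_oracle(self, params):
        rng = np.random.default_rng(41)
        for _ in range(15):
            n = int(rng.integers(3, 8))
            base = "".join(AA_ORDER[c] for c in rng.integers(0, 20, 25))
            members = []
            for i in range(n):
                s = list(base)
                for k in rng.integers(0, 25, 6):
                    s[k] = AA_ORDER[rng.integers(0, 20)]
                members.append(GeneCall(f"m{i}", f"g{i}", 0, 75, "+", "".join(s)))
            a, b = members[0], members[1]
            want = relbit_oracle(
                a.aa_seq, b.aa_seq, [m.aa_seq for m in members[2:]],
                params.matrix, params.gap_open, params.gap_extend,
                params.karlin_lambda, params.karlin_k,
            )
            got = relbit(a, b, members, params)
            assert got == pytest.approx(want, abs=1e-12)


class TestPercentOverlap:
    def test_identical_pattern_is_one(self):
        msa = Msa("c", [("a", "MK-TA"), ("b", "LW-DE")])
        assert percent_overlap(msa, "a", "b") == 1.0

    def test_disjoint_patterns_give_zero(self):
        msa = Msa("c", [("a", "MKT----"), ("b", "----LWD")])
        assert percent_overlap(msa, "a", "b") == 0.0

    def test_printed_overlap_example(self):
        # a occupies columns 0-99, b occupies 80-159 -> 20/160
        msa = Msa("c", [
            ("a", _mask_row(set(range(0, 100)), 160)),
            ("b", _mask_row(set(range(80, 160)), 160)),
        ])
        assert percent_overlap(msa, "a", "b") == pytest.approx(0.125)

    def test_missing_row_is_error(self):
        msa = Msa("c", [("a", "MKT")])
        with pytest.raises(KeyError):
            percent_overlap(msa, "a", "zz")

    @given(
        occ_a=st.lists(st.booleans(), min_size=1, max_size=60),
        occ_b=st.lists(st.booleans(), min_size=1, max_size=60),
    )
    def test_symmetric_bounded_and_matches_oracle(self, occ_a, occ_b):
        width = max(len(occ_a), len(occ_b))
        occ_a += [False] * (width - len(occ_a))
        occ_b += [False] * (width - len(occ_b))
        row_a = "".join("A" if o else "-" for o in occ_a)
        row_b = "".join("C" if o else "-" for o in occ_b)
        msa = Msa("c", [("a", row_a), ("b", row_b)])
        po = percent_overlap(msa, "a", "b")
        assert po == percent_overlap(msa, "b", "a")
        assert 0.0 <= po <= 1.0
        assert po == pytest.approx(percent_overlap_oracle(row_a, row_b))
        if any(occ_a) or any(occ_b):
            assert (po == 1.0) == (occ_a == occ_b)
            assert (po == 0.0) == (not any(x and y for x, y in zip(occ_a, occ_b)))


class TestDecision:
    def test_below_both_thresholds_fuses(self):
        assert fusion_decision(0.20, 0.10) == "fused"

    def test_high_relbit_rejects(self):
        assert fusion_decision(0.50, 0.10) == "rejected"

    def test_boundary_values_are_rejected(self):
        assert fusion_decision(0.25, 0.10) == "rejected"
        assert fusion_decision(0.10, 0.25) == "rejected"

    def test_unevaluable_sentinel(self):
        assert fusion_decision(None, 0.0) == "unevaluable"


class TestOrderFragments:
    def test_disjoint_spans(self):
        msa = Msa("c", [
            ("a", _mask_row(set(range(0, 50)), 120)),
            ("b", _mask_row(set(range(60, 120)), 120)),
        ])
        assert order_fragments(msa, "a", "b") == ("a", "b")
        assert order_fragments(msa, "b", "a") == ("a", "b")

    def test_overlapping_spans_use_median(self):
        # medians 40 vs 80 -> the first is N-terminal
        msa = Msa("c", [
            ("a", _mask_row(set(range(0, 81)), 121)),
            ("b", _mask_row(set(range(40, 121)), 121)),
        ])
        assert order_fragments(msa, "a", "b")[0] == "a"


class TestFindDuplicates:
    def test_single_copy_everywhere_is_empty(self):
        state = PangenomeState()
        state.calls = {
            "a": GeneCall("a", "g1", 0, 30, "+", "MKT"),
            "b": GeneCall("b", "g2", 0, 30, "+", "MKT"),
        }
        state.clusters = {"c1": {"a", "b"}}
        assert find_duplicate_clusters(state) == []

    def test_same_genome_pair_is_flagged(self):
        state = PangenomeState()
        state.calls = {
            "a": GeneCall("a", "g1", 0, 30, "+", "MKT"),
            "b": GeneCall("b", "g1", 90, 120, "+", "LLW"),
        }
        state.clusters = {"c1": {"a", "b"}}
        assert find_duplicate_clusters(state) == ["c1"]

    def test_planted_duplicates_match_manifest(self, small_state):
        from panfix.pipeline import PipelineOptions, align_missing

        state, manifest = small_state
        align_missing(state, PipelineOptions())
        flagged = set(find_duplicate_clusters(state))
        expected = {f.family for f in manifest.fragments if f.round == 1}
        expected |= {fam for fam, _, _ in manifest.decoys}
        assert flagged == expected


class TestFusion:
    def test_two_part_fusion_inserts_single_x(self):
        a = GeneCall("a", "g1", 0, 9, "+", "MKT")
        b = GeneCall("b", "g1", 30, 39, "+", "LLW")
        fused = fuse_sequences([a, b])
        assert fused.aa_seq == "MKTXLLW"
        assert fused.provenance == ["a", "b"]
        assert len(fused) == len(a) + len(b) + 1

    def test_three_part_chain_has_two_junctions(self):
        parts = [
            GeneCall("a", "g1", 0, 9, "+", "MKT"),
            GeneCall("b", "g1", 20, 29, "+", "LLW"),
            GeneCall("c", "g1", 40, 49, "+", "GHE"),
        ]
        fused = fuse_sequences(parts)
        assert fused.aa_seq == "MKTXLLWXGHE"
        assert len(fused) == 9 + 2

    def test_residue_multiset_is_conserved(self):
        from collections import Counter

        a = GeneCall("a", "g1", 0, 30, "+", "MKTAYIAKQR")
        b = GeneCall("b", "g1", 60, 90, "+", "LLWDEAGHKR")
        fused = fuse_sequences([a, b])
        merged = Counter(fused.aa_seq.replace("X", "", fused.aa_seq.count("X")))
        assert merged == Counter(a.aa_seq) + Counter(b.aa_seq)

    def test_cross_genome_fusion_is_error(self):
        a = GeneCall("a", "g1", 0, 9, "+", "MKT")
        b = GeneCall("b", "g2", 0, 9, "+", "LLW")
        with pytest.raises(InputError):
            fuse_sequences([a, b])

    def test_call_in_two_clusters_is_error(self):
        state = PangenomeState()
        for cid, g in (("a", "g1"), ("b", "g1"), ("c", "g1")):
            state.calls[cid] = GeneCall(cid, g, 0, 9, "+", "MKT")
        state.clusters = {"c1": {"a", "b"}, "c2": {"c"}}
        pairs = [
            FragmentPair("c1", "a", "b", 0.1, 0.1, "a", "fused", 1),
            FragmentPair("c2", "a", "c", 0.1, 0.1, "a", "fused", 1),
        ]
        with pytest.raises(StageError):
            apply_fusions(state, pairs)


def test_paralog_duplicates_in_tight_clusters_are_never_fused(params):
    """True duplicates at >=80% identity have high relbit and full overlap:
    they must never satisfy the fusion rule."""
    rng = np.random.default_rng(43)
    for trial in range(8):
        base = "".join(AA_ORDER[c] for c in rng.integers(0, 20, 60))

        def variant(i):
            s = list(base)
            for k in rng.integers(0, 60, 8):  # ~87% identity
                s[k] = AA_ORDER[rng.integers(0, 20)]
            return "".join(s)

        state = PangenomeState()
        seqs = [variant(i) for i in range(5)]
        genomes = ["g0", "g0", "g1", "g2", "g3"]  # g0 carries a duplicate
        for i, (s, g) in enumerate(zip(seqs, genomes)):
            state.calls[f"m{i}"] = GeneCall(f"m{i}", g, 100 * i, 100 * i + 180, "+", s)
        state.clusters = {"c1": set(state.calls)}
        state.genomes = {g: GenomeRecord(g, 10000, []) for g in set(genomes)}
        from panfix.aligner import align_cluster

        state.msas["c1"] = align_cluster(state.calls.values(), params, "c1")
        pairs = call_fragments(state, "c1", params=params)
        assert len(pairs) == 1
        assert pairs[0].decision == "rejected"
        assert pairs[0].relbit > 0.25
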