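"""Cluster profiles, selfbit thresholds, hit edges and component merging."""

import numpy as np
import pytest

from panfix.merge import (
    HitEdge,
    build_hit_edgelist,
    build_profile,
    compute_selfbit,
    merge_components,
    score_profile,
    score_profile_batch,
)
from panfix.model import AA_ORDER, GeneCall, InputError, Msa
from panfix.scoring import BLOSUM62_BACKGROUND

from .oracles import emissions_oracle, partition_oracle


def _call(i, seq):
    return GeneCall(f"m{i}", f"g{i}", 0, 3 * len(seq), "+", seq)


class TestBuildProfile:
    def test_identical_rows_put_observed_residue_on_top(self):
        msa = Msa("c", [(f"r{i}", "MKTAY") for i in range(4)])
        profile = build_profile(msa)
        for j, residue in enumerate("MKTAY"):
            top = AA_ORDER[int(np.argmax(profile.emissions[j, :20]))]
            assert top == residue

    def test_gappy_column_is_excluded(self):
        msa = Msa("c", [("r0", "M-KT"), ("r1", "M-KT"), ("r2", "MWKT")])
        profile = build_profile(msa)
        assert profile.match_columns == [0, 2, 3]

    def test_emissions_match_count_oracle(self):
        rng = np.random.default_rng(17)
        rows = []
        for i in range(6):
            row = "".join(
                "-" if rng.random() < 0.15 else AA_ORDER[rng.integers(0, 20)]
                for _ in range(30)
            )
            rows.append((f"r{i}", row))
        msa = Msa("c", rows)
        profile = build_profile(msa, pseudocount=0.1)
        want = emissions_oracle(
            [r for _, r in rows], 0.1, BLOSUM62_BACKGROUND, AA_ORDER
        )
        expect_cols = [j for j, (gf, _) in enumerate(want) if gf <= 0.5]
        assert profile.match_columns == expect_cols
        for k, j in enumerate(profile.match_columns):
            assert profile.emissions[k, :20] == pytest.approx(want[j][1], abs=1e-10)

    def test_all_gap_msa_is_error(self):
        msa = Msa("c", [("r0", "--"), ("r1", "--"), ("r2", "M-")])
        with pytest.raises(InputError, match="'c'"):
            build_profile(msa)


@pytest.fixture(scope="module")
def family():
    rng = np.random.default_rng(23)
    base = "".join(AA_ORDER[c] for c in rng.integers(0, 20, 60))
    members = []
    for i in range(6):
        s = list(base)
        for k in rng.integers(0, 60, 10):
            s[k] = AA_ORDER[rng.integers(0, 20)]
        members.append(_call(i, "".join(s)))
    from panfix.aligner import align_cluster

    msa = align_cluster(members, cluster_id="fam")
    return members, build_profile(msa)


class TestScoreProfile:
    def test_members_score_positive(self, family):
        members, profile = family
        for m in members:
            assert score_profile(m, profile) > 0

    def test_random_decoys_score_below_every_member(self, family):
        members, profile = family
        rng = np.random.default_rng(29)
        member_scores = [score_profile(m, profile) for m in members]
        for i in range(10):
            decoy = _call(100 + i, "".join(AA_ORDER[c] for c in rng.integers(0, 20, 60)))
            assert score_profile(decoy, profile) < min(member_scores)

    def test_flanking_residues_never_decrease_score(self, family):
        members, profile = family
        rng = np.random.default_rng(31)
        flank = "".join(AA_ORDER[c] for c in rng.integers(0, 20, 15))
        for m in members[:3]:
            plain = score_profile(m, profile)
            extended = _call(200, flank + m.aa_seq + flank)
            assert score_profile(extended, profile) >= plain - 1e-6

    def test_batch_equals_scalar(self, family):
        members, profile = family
        batch = score_profile_batch([m.aa_seq for m in members], profile)
        singles = [score_profile(m, profile) for m in members]
        assert batch == pytest.approx(singles)


class TestSelfbit:
    def test_selfbit_is_minimum_member_score(self):
        msa = Msa("c", [(f"m{i}", s) for i, s in enumerate(
            ["MKTAYIAKQR", "MKTAYIAKQR", "MKTWYIAKQR"]
        )])
        profile = build_profile(msa)
        members = [
            _call(0, "MKTAYIAKQR"), _call(1, "MKTAYIAKQR"), _call(2, "MKTWYIAKQR")
        ]
        profile = compute_selfbit(profile, members)
        scores = [score_profile(m, profile) for m in members]
        assert profile.selfbit == pytest.approx(min(scores))

    def test_singleton_selfbit_is_own_score(self):
        msa = Msa("c", [("m0", "MKTAYIAKQR")])
        profile = compute_selfbit(build_profile(msa), [_call(0, "MKTAYIAKQR")])
        assert profile.selfbit == pytest.approx(
            score_profile(_call(0, "MKTAYIAKQR"), profile)
        )

    def test_empty_member_set_is_error(self):
        profile = build_profile(Msa("c", [("m0", "MKTAY")]))
        with pytest.raises(InputError):
            compute_selfbit(profile, [])


class TestEdgelist:
    def _setup(self):
        msa = Msa("c1", [(f"m{i}", "MKTAYIAKQRQISFVKSHFS") for i in range(3)])
        profile = build_profile(msa)
        members = [_call(i, "MKTAYIAKQRQISFVKSHFS") for i in range(3)]
        profile = compute_selfbit(profile, members)
        return profile, members

    def test_boundary_score_equal_to_selfbit_makes_edge(self):
        profile, members = self._setup()
        # a foreign call identical to the weakest member scores == selfbit
        foreign = GeneCall("f0", "gx", 0, 60, "+", "MKTAYIAKQRQISFVKSHFS")
        assignment = {m.id: "c1" for m in members} | {"f0": "c2"}
        edges = build_hit_edgelist(members + [foreign], [profile], assignment)
        assert HitEdge("f0", "c1", pytest.approx(profile.selfbit)) in edges
        # strict mode drops the boundary hit
        edges = build_hit_edgelist(
            members + [foreign], [profile], assignment, strict_selfbit=True
        )
        assert not edges

    def test_score_below_thresholds_makes_no_edge(self):
        profile, members = self._setup()
        foreign = GeneCall("f0", "gx", 0, 60, "+", "WWPPGGHHEEDDNNCCIILL")
        assignment = {m.id: "c1" for m in members} | {"f0": "c2"}
        assert build_hit_edgelist(members + [foreign], [profile], assignment) == []

    def test_infinite_absolute_floor_empties_edgelist(self):
        profile, members = self._setup()
        foreign = GeneCall("f0", "gx", 0, 60, "+", "MKTAYIAKQRQISFVKSHFS")
        assignment = {m.id: "c1" for m in members} | {"f0": "c2"}
        edges = build_hit_edgelist(
            members + [foreign], [profile], assignment, abs_min_bit=float("inf")
        )
        assert edges == []

    def test_self_hits_never_create_edges(self):
        profile, members = self._setup()
        assignment = {m.id: "c1" for m in members}
        assert build_hit_edgelist(members, [profile], assignment) == []


class TestMergeComponents:
    def test_no_edges_is_identity(self):
        partition = merge_components(["c1", "c2"], [], {})
        assert partition == {"c1": "c1", "c2": "c2"}

    def test_transitive_chain_merges(self):
        assignment = {"a": "c1", "b": "c2"}
        edges = [HitEdge("a", "c2", 50.0), HitEdge("b", "c3", 50.0)]
        partition = merge_components(["c1", "c2", "c3"], edges, assignment)
        assert partition == {"c1": "c1", "c2": "c1", "c3": "c1"}

    def test_random_edge_sets_match_union_find_oracle(self):
        rng = np.random.default_rng(37)
        for _ in range(40):
            n = int(rng.integers(2, 50))
            clusters = [f"c{i:02d}" for i in range(n)]
            assignment = {f"gene{i:02d}": clusters[i] for i in range(n)}
            edges, raw_edges = [], []
            for _ in range(int(rng.integers(0, n * 2))):
                gi, cj = int(rng.integers(0, n)), int(rng.integers(0, n))
                edges.append(HitEdge(f"gene{gi:02d}", clusters[cj], 10.0))
                if clusters[gi] != clusters[cj]:
                    raw_edges.append((clusters[gi], clusters[cj]))
            assert merge_components(clusters, edges, assignment) == partition_oracle(
                clusters, raw_edges
            )

    def test_absolute_floor_only_refines_partition(self, small_state, params):
        from panfix.pipeline import PipelineOptions, align_missing, evaluate_merge

        state, _ = small_state
        options = PipelineOptions()
        align_missing(state, options)
        previous = None
        for floor in (None, 50.0, 150.0, 1e9):
            options.abs_min_bit = floor
            partition, _ = evaluate_merge(state, options)
            if previous is not None:
                # every pair merged now was merged with the lower floor too
                for c1 in partition:
                    for c2 in partition:
                        if partition[c1] == partition[c2]:
                            assert previous[c1] == previous[c2]
            previous = partition
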