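import pytest

from memclust.cluster_engine import (
    ClusteringParams,
    RepresentativeSet,
    assign_or_promote,
    cluster_all,
    cluster_block,
    partition_blocks,
)
from memclust.io_fasta import SequenceRecord, filter_and_sort
from memclust.synth_data import make_benchmark, random_genome

from conftest import make_records


def sorted_records(bench, min_keep=21):
    return filter_and_sort(list(bench.records), min_keep)


class TestPartitionBlocks:
    def test_greedy_fill_by_hand(self):
        recs = make_records(["A" * 5, "C" * 4, "G" * 3, "T" * 2])
        blocks = partition_blocks(recs, 8e-6)  # 8 bp budget
        assert [[r.length for r in b] for b in blocks] == [[5], [4, 3], [2]]

    def test_single_block_when_budget_large(self):
        recs = make_records(["A" * 5, "C" * 4])
        assert len(partition_blocks(recs, 1.0)) == 1

    def test_oversized_record_gets_own_block(self):
        recs = make_records(["A" * 50, "C" * 2, "G" * 2])
        blocks = partition_blocks(recs, 4e-6)
        assert [[r.length for r in b] for b in blocks] == [[50], [2, 2]]

    def test_empty_input(self):
        assert partition_blocks([], 1.0) == []


class TestAssignOrPromote:
    def test_exact_substring_is_redundant_at_identity_one(self):
        rep = SequenceRecord("rep", random_genome(500, 0), 0)
        query = SequenceRecord("q", rep.seq[100:350], 1)
        params = ClusteringParams()
        repset = RepresentativeSet(params)
        repset.add(rep)
        status, hit = assign_or_promote(query, repset, params)
        assert status == "redundant"
        assert hit == ("rep", 1.0, "+")

    def test_unrelated_query_is_promoted(self):
        params = ClusteringParams()
        repset = RepresentativeSet(params)
        repset.add(SequenceRecord("rep", random_genome(500, 1), 0))
        query = SequenceRecord("q", random_genome(400, 2), 1)
        status, hit = assign_or_promote(query, repset, params)
        assert status == "representative" and hit is None
        assert len(repset) == 2

    def test_first_matching_representative_wins_not_best(self):
        base = random_genome(600, 3)
        # both representatives contain the query; discovery order decides
        rep1 = SequenceRecord("first", base, 0)
        rep2 = SequenceRecord("second", base + random_genome(50, 4), 1)
        query = SequenceRecord("q", base[50:550], 2)
        params = ClusteringParams()
        repset = RepresentativeSet(params)
        repset.add(rep2)  # longer, discovered first (sorted long-to-short)
        repset.add(rep1)
        assert repset.match(query)[0] == "second"

    def test_equal_length_exact_duplicate_clusters(self):
        seq = random_genome(300, 5)
        recs = [SequenceRecord("a", seq, 0), SequenceRecord("b", seq, 1)]
        cs = cluster_all(recs, ClusteringParams(memiden=100.0))
        assert cs.n_clusters == 1
        assert cs.clusters[0].members[0][:2] == ("b", 1.0)


class TestClusterBlock:
    def test_prefix_copies_join_their_source(self):
        base = random_genome(2000, 6)
        recs = make_records([base] + [base[:1800]] * 3)
        recs = filter_and_sort(recs, 21)
        assignments, repset = cluster_block(recs, None, ClusteringParams())
        assert len(repset) == 1
        assert set(assignments) == {"s1", "s2", "s3"}
        assert all(hit[0] == "s0" and hit[1] == 1.0 for hit in assignments.values())

    def test_unrelated_sequences_all_promoted(self):
        recs = make_records([random_genome(400 - 10 * i, 100 + i) for i in range(5)])
        assignments, repset = cluster_block(recs, None, ClusteringParams())
        assert assignments == {} and len(repset) == 5

    def test_deterministic_across_runs(self):
        bench = make_benchmark(n_groups=4, copies_per_group=2, n_singletons=3, seed=8)
        recs = sorted_records(bench)
        a1, _ = cluster_block(recs, None, ClusteringParams())
        a2, _ = cluster_block(recs, None, ClusteringParams())
        assert a1 == a2


@pytest.fixture(scope="module")
def bench():
    return make_benchmark(n_groups=6, copies_per_group=3, n_singletons=6, seed=9)


class TestClusterAll:
    def test_partition_covers_every_sequence_once(self, bench):
        recs = sorted_records(bench)
        cs = cluster_all(recs, ClusteringParams())
        membership = cs.membership()
        assert set(membership) == {r.id for r in recs}
        assert sum(c.size for c in cs.clusters) == len(recs)

    def test_truth_partition_recovered(self, bench):
        recs = sorted_records(bench)
        cs = cluster_all(recs, ClusteringParams())
        assert cs.n_clusters == bench.n_groups
        membership = cs.membership()
        for seq_id, rep_id in membership.items():
            assert bench.truth[seq_id] == bench.truth[rep_id]

    def test_block_partition_invariance(self, bench):
        recs = sorted_records(bench)
        one = cluster_all(recs, ClusteringParams(chunk_mb=1000.0))
        many = cluster_all(recs, ClusteringParams(chunk_mb=0.008))
        assert len(partition_blocks(recs, 0.008)) > 1
        assert one.clusters == many.clusters

    def test_rebuild_schedule_does_not_change_result(self, bench):
        recs = sorted_records(bench)
        a = cluster_all(recs, ClusteringParams(rebuild=True, rebuild_interval=2))
        b = cluster_all(recs, ClusteringParams(rebuild=False))
        assert a.clusters == b.clusters

    def test_member_identity_meets_threshold(self, bench):
        recs = sorted_records(bench)
        params = ClusteringParams(memiden=90.0)
        cs = cluster_all(recs, params)
        for c in cs.clusters:
            for _, identity, _ in c.members:
                assert identity * 100.0 >= params.memiden - 1e-9

    def test_representatives_not_shorter_than_members(self, bench):
        recs = sorted_records(bench)
        cs = cluster_all(recs, ClusteringParams())
        length = {r.id: r.length for r in recs}
        for c in cs.clusters:
            for member_id, _, _ in c.members:
                assert length[c.representative] >= length[member_id]

    def test_unsorted_input_rejected(self):
        recs = make_records(["AAA" * 10, "CCC" * 20])  # short before long
        with pytest.raises(ValueError, match="sorted"):
            cluster_all(recs, ClusteringParams())


class TestParamValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(memiden=0),
            dict(memiden=101),
            dict(minlen=0),
            dict(sparse_k=0),
            dict(minlen=2, sparse_k=3),
            dict(chunk_mb=0),
            dict(threads=0),
        ],
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            ClusteringParams(**kw)
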