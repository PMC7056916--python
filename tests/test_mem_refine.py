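import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from memclust.mem_finder import MEM
from memclust.mem_refine import (
    ScoreScheme,
    compute_ememi,
    extend_matches,
    refine_and_extend,
    remove_contained,
    trim_overlaps,
)
from memclust.suffix_index import build_index
from memclust.synth_data import random_genome

from conftest import make_records


def mem(rs, qs, ln):
    return MEM("rep", rs, qs, ln, "+")


def spans(mems, axis):
    if axis == "ref":
        return sorted((m.ref_start, m.ref_end) for m in mems)
    return sorted((m.query_start, m.query_end) for m in mems)


def pairwise_disjoint(intervals):
    intervals = sorted(intervals)
    return all(a[1] <= b[0] for a, b in zip(intervals, intervals[1:]))


# strategy: small random MEM sets sharing one (rep, query, +) triple
mem_sets = st.lists(
    st.tuples(st.integers(0, 60), st.integers(0, 60), st.integers(1, 25)),
    min_size=0,
    max_size=10,
).map(lambda triples: [mem(*t) for t in triples])


class TestRemoveContained:
    def test_contained_in_single_larger_mem(self):
        a, b = mem(0, 0, 30), mem(10, 10, 10)
        assert remove_contained([a, b]) == [a]

    def test_contained_in_single_larger_mem_spec_geometry(self):
        # ref spans [0,20), [8,16), [12,30): the middle one is inside the
        # first alone, so the single-containment rule already removes it
        a, b, c = mem(0, 0, 20), mem(8, 40, 8), mem(12, 60, 18)
        assert remove_contained([a, b, c]) == [a, c]

    def test_contained_in_union_of_neighbors(self):
        # [8,24) is inside neither [0,20) nor [12,30) alone, only their union
        a, b, c = mem(0, 0, 20), mem(8, 40, 16), mem(12, 60, 18)
        assert remove_contained([a, b, c]) == [a, c]

    def test_query_side_containment_also_removes(self):
        a = mem(0, 0, 30)
        b = mem(100, 5, 10)  # ref-disjoint but query span inside a's
        assert remove_contained([a, b]) == [a]

    def test_disjoint_input_unchanged(self):
        ms = [mem(0, 0, 10), mem(20, 20, 10), mem(40, 40, 10)]
        assert remove_contained(ms) == ms


class TestTrimOverlaps:
    def test_partial_ref_overlap_shifts_both_starts(self):
        a, b = mem(0, 100, 20), mem(15, 200, 20)
        out = trim_overlaps([a, b])
        assert out[0] == a
        assert out[1] == mem(20, 205, 15)

    def test_query_only_overlap_trims_by_query_amount(self):
        a, b = mem(0, 0, 20), mem(50, 15, 20)  # ref disjoint, query overlap 5
        out = trim_overlaps([a, b])
        assert out[1] == mem(55, 20, 15)

    def test_disjoint_input_unchanged(self):
        ms = [mem(0, 0, 10), mem(20, 20, 10)]
        assert trim_overlaps(ms) == ms

    def test_fully_shadowed_equal_span_collapses(self):
        # identical ref spans of equal length survive containment removal
        # (neither is larger) but the trim sweep reduces one to nothing
        a, b = mem(0, 0, 10), mem(0, 50, 10)
        out = trim_overlaps(remove_contained([a, b]))
        assert len(out) == 1

    @given(mem_sets)
    def test_projections_pairwise_disjoint_after_refinement(self, ms):
        out = trim_overlaps(remove_contained(ms))
        assert pairwise_disjoint(spans(out, "ref"))
        assert pairwise_disjoint(spans(out, "query"))

    @given(mem_sets)
    def test_refinement_never_grows_coverage(self, ms):
        def union_len(intervals):
            total, last = 0, -1
            for s, e in sorted(intervals):
                s = max(s, last)
                total += max(0, e - s)
                last = max(last, e)
            return total

        out = trim_overlaps(remove_contained(ms))
        if ms:
            assert union_len(spans(out, "query")) <= union_len(spans(ms, "query"))
            assert union_len(spans(out, "ref")) <= union_len(spans(ms, "ref"))


def xdrop_prefix_oracle(flank, match, mismatch, xdrop):
    """Exhaustive best-scoring-prefix scan with the x-drop stopping rule.

    ``flank`` is a string of M (match) and X (mismatch).  Ties in score
    prefer the longer prefix.  Returns (steps, n_match).
    """
    score, best, best_t, best_n, n = 0, 0, 0, 0, 0
    for t, c in enumerate(flank, start=1):
        if c == "M":
            score += match
            n += 1
        else:
            score += mismatch
        if score >= best:
            best, best_t, best_n = score, t, n
        elif best - score >= xdrop:
            break
    return best_t, best_n


def build_flank_pair(pattern, rng):
    """(rep_flank, query_flank) realizing a given match/mismatch pattern."""
    bases = "ACGT"
    rep, qry = [], []
    for c in pattern:
        a = bases[rng.integers(0, 4)]
        rep.append(a)
        qry.append(a if c == "M" else bases[(bases.index(a) + 2) % 4])
    return "".join(rep), "".join(qry)


class TestExtension:
    def test_all_match_flanks_extend_fully(self):
        core = random_genome(10, 0)
        flank = random_genome(5, 1)
        rep = flank + core + flank
        qry = flank + core + flank
        (ext,) = extend_matches([mem(5, 5, 10)], rep, qry, ScoreScheme())
        assert ext.ext_ref_span == (0, 20)
        assert ext.ext_query_span == (0, 20)
        assert ext.n_match == 20

    def test_immediate_mismatch_wall_stops_extension(self):
        scheme = ScoreScheme(xdrop=2)
        rep = "G" * 6 + "ACGTACGTAC" + "G" * 6
        qry = "T" * 6 + "ACGTACGTAC" + "T" * 6
        (ext,) = extend_matches([mem(6, 6, 10)], rep, qry, scheme)
        assert ext.ext_ref_span == (6, 16)
        assert ext.n_match == 10

    def test_mmxmxxx_flank_matches_prefix_oracle(self, rng):
        pattern = "MMXMXXX"
        scheme = ScoreScheme(match=1, mismatch=-1, xdrop=2)
        rep_f, qry_f = build_flank_pair(pattern, rng)
        core = random_genome(10, 5)
        rep, qry = core + rep_f, core + qry_f
        (ext,) = extend_matches([mem(0, 0, 10)], rep, qry, scheme)
        steps, nm = xdrop_prefix_oracle(pattern, 1, -1, 2)
        assert (steps, nm) == (4, 3)  # frozen from the oracle
        assert ext.ext_ref_span == (0, 10 + steps)
        assert ext.n_match == 10 + nm

    @given(st.text(alphabet="MX", max_size=40), st.integers(1, 3), st.integers(1, 8))
    def test_random_flanks_match_prefix_oracle(self, pattern, mismatch_mag, xdrop):
        rng = np.random.default_rng(abs(hash(pattern)) % (2**31))
        scheme = ScoreScheme(match=1, mismatch=-mismatch_mag, xdrop=xdrop)
        rep_f, qry_f = build_flank_pair(pattern, rng)
        core = random_genome(8, 9)
        (ext,) = extend_matches([mem(0, 0, 8)], core + rep_f, core + qry_f, scheme)
        steps, nm = xdrop_prefix_oracle(pattern, 1, -mismatch_mag, xdrop)
        assert ext.ext_ref_span[1] - 8 == steps
        assert ext.n_match - 8 == nm

    def test_extension_clipped_at_neighbor_midpoint(self):
        core = random_genome(30, 2)
        rep = qry = core  # two seeds inside one identical sequence
        ms = [mem(0, 0, 10), mem(20, 20, 10)]
        exts = extend_matches(ms, rep, qry, ScoreScheme())
        assert exts[0].ext_ref_span[1] <= exts[1].ext_ref_span[0]
        assert exts[0].ext_query_span[1] <= exts[1].ext_query_span[0]

    def test_gapped_bridges_single_indel_and_never_loses_matches(self, rng):
        # rep and query identical except one deleted base in the right flank
        left = random_genome(12, 3)
        right = random_genome(30, 4)
        rep = left + right
        qry = left + right[:10] + right[11:]
        seed = mem(0, 0, 12)
        ungapped = extend_matches([seed], rep, qry, ScoreScheme(gapped=False))[0]
        gapped = extend_matches([seed], rep, qry, ScoreScheme(gapped=True))[0]
        assert gapped.n_match >= ungapped.n_match
        assert gapped.n_match >= 12 + 10 + 10  # crosses the indel

    @given(st.integers(0, 2**31 - 1))
    def test_gapped_never_below_ungapped(self, seed):
        rng = np.random.default_rng(seed)
        rep = random_genome(60, rng)
        qry = rep[:20] + random_genome(40, rng)
        seed_mem = mem(0, 0, 20)
        for scheme_kw in ({"xdrop": 3}, {"xdrop": 8, "mismatch": -2}):
            u = extend_matches([seed_mem], rep, qry, ScoreScheme(gapped=False, **scheme_kw))[0]
            g = extend_matches([seed_mem], rep, qry, ScoreScheme(gapped=True, **scheme_kw))[0]
            assert g.n_match >= u.n_match


class TestIdentity:
    def test_direct_ratio(self):
        ext = extend_matches([mem(0, 0, 90)], "A" * 90, "A" * 90, ScoreScheme())
        res = compute_ememi(ext, 100)
        assert res.ememi == pytest.approx(0.90)
        assert res.n_match_total == 90

    def test_empty_extension_is_zero(self):
        assert compute_ememi([], 50).ememi == 0.0

    @pytest.mark.parametrize("L", [5, 21, 40])
    def test_exact_substring_query_scores_one(self, L):
        rep = random_genome(200, 6)
        query = rep[37:117]
        idx = build_index(make_records([rep]), 1)
        from memclust.mem_finder import find_mems

        mems = [MEM(m.ref_id, m.ref_start, m.query_start, m.length, "+")
                for m in find_mems(idx, query, L)]
        ext = refine_and_extend(mems, rep, query, ScoreScheme())
        assert compute_ememi(ext, len(query)).ememi == 1.0

    def test_l_query_validation(self):
        with pytest.raises(ValueError):
            compute_ememi([], 0)


class TestScoreScheme:
    @pytest.mark.parametrize(
        "kw",
        [dict(match=0), dict(mismatch=1), dict(xdrop=0), dict(gap_open=1), dict(gap_extend=1)],
    )
    def test_invalid_schemes_rejected(self, kw):
        with pytest.raises(ValueError):
            ScoreScheme(**kw)
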