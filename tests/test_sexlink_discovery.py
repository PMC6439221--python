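"""Hit filtering, scaffold specificity, RAD-tag association, repeat fractions."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lineasig.sexlink_discovery import (
    AlignmentHit,
    HitFilterConfig,
    TagPresenceMatrix,
    classify_tag_hits,
    filter_hits,
    genome_specific_scaffolds,
    masked_fraction,
    paralog_candidates,
    sex_associated_tags,
)


def hit(q="q", t="t", match=150, mismatch=3, qsize=1000, **kw):
    return AlignmentHit(q, t, match, mismatch, qsize, **kw)


class TestFilterHits:
    @pytest.mark.parametrize(
        "match, mismatch, qsize, kept",
        [
            (150, 3, 1000, True),    # rate 2%, coverage 15%
            (150, 6, 1000, False),   # rate 4%
            (90, 0, 200, False),     # match not greater than 100
            (100, 0, 200, False),    # match exactly 100: strict >
            (101, 0, 1000, True),    # boundary: 101 > 100, coverage 10.1%
        ],
    )
    def test_threshold_combinations(self, match, mismatch, qsize, kept):
        got = filter_hits([hit(match=match, mismatch=mismatch, qsize=qsize)])
        assert bool(got) is kept

    def test_coverage_boundary_is_strict(self):
        assert not filter_hits([hit(match=200, mismatch=0, qsize=2000)])  # exactly 10%

    def test_order_preserved_and_idempotent(self):
        hits = [hit(q=f"q{i}", match=150 + i, mismatch=i % 3) for i in range(20)]
        kept = filter_hits(hits)
        assert [h.query_id for h in kept] == [
            h.query_id for h in hits if h in kept
        ]
        assert filter_hits(kept) == kept

    def test_zero_match_hit_discarded_with_warning(self):
        with pytest.warns(UserWarning, match="zero match"):
            out = filter_hits([AlignmentHit("q", "t", 0, 5, 100)])
        assert out == []

    def test_literal_rate_reading_rejects_normal_hits(self):
        # match/mismatch = 50 is nowhere near < 0.03
        assert not filter_hits([hit(match=150, mismatch=3)], literal_rate=True)


class TestGenomeSpecificScaffolds:
    def test_scaffold_without_hits_is_specific(self):
        spec = genome_specific_scaffolds({"s1": 500, "s2": 500},
                                         [hit(t="s2")], "male")
        assert spec.scaffold_ids == {"s1"}

    def test_scaffold_whose_hits_all_failed_filter_is_specific(self):
        raw = [hit(t="s1", match=50)]  # fails match-length filter
        retained = filter_hits(raw)
        spec = genome_specific_scaffolds({"s1": 500}, retained, "male")
        assert spec.scaffold_ids == {"s1"}

    def test_no_specific_scaffold_is_a_retained_hit_target(self):
        hits = [hit(t=f"s{i}") for i in range(5)]
        retained = filter_hits(hits)
        spec = genome_specific_scaffolds(
            {f"s{i}": 500 for i in range(8)}, retained, "male"
        )
        assert spec.scaffold_ids.isdisjoint({h.target_id for h in retained})
        assert spec.scaffold_ids == {"s5", "s6", "s7"}

    def test_positional_coverage_variant(self):
        # one 200 bp hit on a 1000 bp scaffold: 20% covered
        h = hit(t="s1", t_start=0, t_end=200)
        spec = genome_specific_scaffolds(
            {"s1": 1000}, [h], "male", min_covered_fraction=0.5
        )
        assert spec.scaffold_ids == {"s1"}
        spec = genome_specific_scaffolds(
            {"s1": 1000}, [h], "male", min_covered_fraction=0.1
        )
        assert spec.scaffold_ids == set()


def tag_matrix(presence, n_males, n_females):
    presence = np.asarray(presence, dtype=bool)
    tags = tuple(f"t{i}" for i in range(presence.shape[0]))
    samples = tuple(
        [(f"m{i}", "male") for i in range(n_males)]
        + [(f"f{i}", "female") for i in range(n_females)]
    )
    return TagPresenceMatrix(tags, samples, presence)


def fisher_enumeration(k_in, n_in, k_out, n_out):
    """One-sided hypergeometric enumeration of the 2x2 presence table."""
    K = k_in + k_out  # total presences
    N = n_in + n_out
    p = 0.0
    for x in range(k_in, min(K, n_in) + 1):
        p += (
            math.comb(n_in, x) * math.comb(n_out, K - x) / math.comb(N, K)
        )
    return p


class TestSexAssociatedTags:
    def test_mostly_male_tag_is_male_associated(self):
        row = [True] * 24 + [False] + [False] * 24 + [True]  # 24/25 m, 1/25 f
        m = tag_matrix([row], 25, 25)
        got = sex_associated_tags(m, min_in=20, max_out=2)
        assert [(t, s) for t, s, _ in got] == [("t0", "male")]

    def test_tag_present_in_everyone_is_not_associated(self):
        m = tag_matrix([[True] * 50], 25, 25)
        assert sex_associated_tags(m, min_in=20, max_out=2) == []

    def test_female_association_is_symmetric(self):
        row = [False] * 25 + [True] * 25
        m = tag_matrix([row], 25, 25)
        got = sex_associated_tags(m, min_in=20, max_out=2)
        assert [(t, s) for t, s, _ in got] == [("t0", "female")]

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        row = [True] * 24 + [False] + [False] * 24 + [True]
        m = tag_matrix([row], 25, 25)
        (_, _, p), = sex_associated_tags(m, min_in=20, max_out=2, test=True)
        assert p == pytest.approx(fisher_enumeration(24, 25, 1, 25), rel=1e-9)

    def test_default_thresholds_behave_like_a_25_25_design(self):
        # 20/25 males, 2/25 females passes; 19/25 males does not
        passing = [True] * 20 + [False] * 5 + [True] * 2 + [False] * 23
        failing = [True] * 19 + [False] * 6 + [True] * 2 + [False] * 23
        m = tag_matrix([passing, failing], 25, 25)
        got = sex_associated_tags(m)
        assert [t for t, _, _ in got] == ["t0"]

    def test_threshold_exceeding_sample_count_rejected(self):
        m = tag_matrix([[True] * 4], 2, 2)
        with pytest.raises(ValueError, match="exceeds"):
            sex_associated_tags(m, min_in=3, max_out=0)


class TestClassifyTagHits:
    def test_five_way_classification(self):
        ms, fs = {"Y1", "Y2"}, {"W1"}
        hits = {
            "a": {"Y1"},
            "b": {"Y1", "auto1"},
            "c": {"auto1", "auto2"},
            "d": {"W1"},
            "e": set(),
        }
        cats, counts = classify_tag_hits(hits, ms, fs)
        assert cats == {
            "a": "male_specific_only",
            "b": "male_specific_and_shared",
            "c": "shared_only",
            "d": "female_specific_only",
            "e": "no_hit",
        }
        assert sum(counts.values()) == 5 and counts["male_specific_only"] == 1


class TestParalogCandidates:
    def test_best_scoring_target_kept_per_query(self):
        hits = [hit(q="Y1", t="a", match=150), hit(q="Y1", t="b", match=180)]
        pairs, targets = paralog_candidates(hits)
        assert pairs == [("Y1", "b", 180)]
        assert targets == ["b"]

    def test_query_without_hits_absent(self):
        pairs, targets = paralog_candidates([hit(q="Y1", t="a")])
        assert all(q == "Y1" for q, _, _ in pairs)

    def test_shared_best_target_deduplicated(self):
        hits = [hit(q="Y1", t="a"), hit(q="Y2", t="a")]
        pairs, targets = paralog_candidates(hits)
        assert len(pairs) == 2 and targets == ["a"]

    def test_score_ties_broken_by_ascending_target_id(self):
        hits = [hit(q="Y1", t="b", match=150), hit(q="Y1", t="a", match=150)]
        pairs, _ = paralog_candidates(hits)
        assert pairs == [("Y1", "a", 150)]


class TestMaskedFraction:
    def test_half_masked_scaffold(self):
        assert masked_fraction({"s": [(0, 50)]}, {"s": 100}, ["s"]) == 50.0

    def test_overlapping_intervals_unioned_not_summed(self):
        got = masked_fraction({"s": [(0, 30), (20, 50)]}, {"s": 100}, ["s"])
        assert got == 50.0

    def test_empty_intervals_give_zero(self):
        assert masked_fraction({}, {"s": 100}, ["s"]) == 0.0

    def test_out_of_bounds_interval_rejected(self):
        with pytest.raises(ValueError, match="out of bounds"):
            masked_fraction({"s": [(50, 150)]}, {"s": 100}, ["s"])

    def test_matches_boolean_mask_oracle(self, rng):
        lengths = {f"s{i}": int(rng.integers(50, 300)) for i in range(5)}
        intervals = {}
        masked_bases = total = 0
        for s, L in lengths.items():
            iv = []
            mask = np.zeros(L, dtype=bool)
            for _ in range(rng.integers(0, 8)):
                a = int(rng.integers(0, L))
                b = int(rng.integers(a, L + 1))
                iv.append((a, b))
                mask[a:b] = True
            intervals[s] = iv
            masked_bases += mask.sum()
            total += L
        got = masked_fraction(intervals, lengths, list(lengths))
        assert got == pytest.approx(100 * masked_bases / total, rel=1e-12)

    @given(st.integers(1, 99), st.integers(0, 2**31 - 1))
    def test_invariant_under_splitting_intervals(self, cut, seed):
        r = np.random.default_rng(seed)
        a, b = sorted(r.integers(0, 100, size=2))
        b = max(b, a + 1)
        whole = masked_fraction({"s": [(a, b)]}, {"s": 100}, ["s"])
        mid = min(max(cut, a), b)
        split = masked_fraction({"s": [(a, mid), (mid, b)]}, {"s": 100}, ["s"])
        assert whole == pytest.approx(split, rel=1e-12)
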