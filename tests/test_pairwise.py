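from itertools import product

import numpy as np
import pytest

from spacerphy import (
    AlignScores,
    CostScheme,
    CRISPRArray,
    align_arrays,
    annotate_events,
    classify_modules,
    infer_ancestor,
)
from spacerphy.pairwise import (
    GAP,
    PairwiseCache,
    _pair_cost,
    alignment_score,
)

from helpers import nw_oracle_score, order_consistent, random_spacer_pair


def arr(aid, *spacers):
    return CRISPRArray(aid, tuple(str(s) for s in spacers))


class TestAlignment:
    def test_identical_arrays_all_match(self):
        a = arr("A", *"abcde")
        aln = align_arrays(a, a)
        assert aln.score == 500
        assert GAP not in aln.seq_a and GAP not in aln.seq_b

    def test_leader_gap_example(self):
        aln = align_arrays(arr("A", "a", "b", "c"), arr("B", "b", "c"))
        assert aln.seq_a == ("a", "b", "c")
        assert aln.seq_b == (GAP, "b", "c")
        assert aln.score == 198

    def test_score_matches_recursive_oracle(self, rng):
        for _ in range(200):
            a, b = random_spacer_pair(rng)
            aln = align_arrays(arr("A", *a), arr("B", *b))
            expected = nw_oracle_score(a, b)
            assert aln.score == expected
            assert alignment_score(a, b) == expected

    def test_shared_spacers_occupy_match_columns(self, rng):
        checked = 0
        while checked < 60:
            a, b = random_spacer_pair(rng)
            if not order_consistent(a, b) or not set(a) & set(b):
                continue
            checked += 1
            aln = align_arrays(arr("A", *a), arr("B", *b))
            matched = {x for x, y in zip(aln.seq_a, aln.seq_b) if x == y}
            assert set(a) & set(b) <= matched

    def test_gap_removal_recovers_inputs(self, rng):
        for _ in range(50):
            a, b = random_spacer_pair(rng)
            aln = align_arrays(arr("A", *a), arr("B", *b))
            assert tuple(s for s in aln.seq_a if s != GAP) == a
            assert tuple(s for s in aln.seq_b if s != GAP) == b
            assert not any(x == GAP and y == GAP
                           for x, y in zip(aln.seq_a, aln.seq_b))

    def test_empty_array_rejected(self):
        with pytest.raises(ValueError):
            align_arrays((), ("a",))


class TestClassifyModules:
    def test_leader_acquisition_then_shared(self):
        aln = align_arrays(arr("A", "a", "b", "c", "d"), arr("B", "c", "d"))
        mods = classify_modules(aln)
        assert [(m.kind, m.spacers_a, m.spacers_b) for m in mods] == [
            ("leader_acquisition", ("a", "b"), ()),
            ("shared", ("c", "d"), ("c", "d")),
        ]

    def test_internal_indel_between_shared(self):
        aln = align_arrays(arr("A", "a", "b", "c", "d", "e"),
                           arr("B", "a", "d", "e"))
        mods = classify_modules(aln)
        assert [m.kind for m in mods] == ["shared", "internal_indel",
                                          "shared"]
        assert mods[1].spacers_a == ("b", "c")

    def test_identical_arrays_single_shared_module(self):
        aln = align_arrays(arr("A", "x", "y"), arr("B", "x", "y"))
        mods = classify_modules(aln)
        assert len(mods) == 1 and mods[0].kind == "shared"

    def test_duplicate_copy_classified_as_duplication(self):
        aln = align_arrays(arr("A", "a", "b", "b", "c"),
                           arr("B", "a", "b", "c"))
        kinds = {m.kind for m in classify_modules(aln)}
        assert "duplication" in kinds

    def test_modules_tile_alignment_without_overlap(self, rng):
        for _ in range(60):
            a, b = random_spacer_pair(rng)
            aln = align_arrays(arr("A", *a), arr("B", *b))
            mods = classify_modules(aln)
            spans = [(m.start, m.end) for m in mods]
            assert spans[0][0] == 0 and spans[-1][1] == len(aln)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 == s2
            assert all(s < e for s, e in spans)


class TestInferAncestor:
    def test_mutually_exclusive_leaders_excluded(self):
        anc = infer_ancestor(arr("A", "a", "b", "c", "d"),
                             arr("B", "e", "f", "c", "d"))
        assert anc.spacers == ("c", "d")

    def test_identical_arrays_are_their_own_ancestor(self):
        a = arr("A", "x", "y", "z")
        assert infer_ancestor(a, a).spacers == a.spacers

    def test_internal_deletion_kept_in_ancestor(self):
        # keeping {c,d} costs one deletion (10) in the short child,
        # dropping them would cost an insertion (30) in the long child
        anc = infer_ancestor(arr("A", "a", "b", "c", "d", "e"),
                             arr("B", "a", "b", "e"))
        assert anc.spacers == ("a", "b", "c", "d", "e")

    def test_trailer_spacers_kept(self):
        anc = infer_ancestor(arr("A", "a", "b", "c", "d"), arr("B", "a", "b"))
        assert anc.spacers == ("a", "b", "c", "d")

    def test_duplication_reduced_to_single_copy(self):
        anc = infer_ancestor(arr("A", "a", "b", "b", "c"),
                             arr("B", "a", "b", "c"))
        assert anc.spacers == ("a", "b", "c")

    def test_disjoint_arrays_have_no_ancestor(self):
        with pytest.raises(ValueError, match="share no ancestral"):
            infer_ancestor(arr("A", "p", "q"), arr("B", "r", "s"))

    def test_minimal_over_column_subsequence_candidates(self, rng):
        """Exhaustive oracle: every gap-free subsequence of the alignment
        columns, costed with both children's events plus the independent-
        acquisition surcharge for spacers gained on both branches."""
        costs, scores = CostScheme(), AlignScores()
        cache = PairwiseCache()
        checked = 0
        while checked < 120:
            a, b = random_spacer_pair(rng, alphabet_size=10, max_len=5)
            if not order_consistent(a, b):
                continue
            aln = align_arrays(arr("A", *a), arr("B", *b))
            if len(aln) > 6:
                continue
            checked += 1
            opts = []
            for x, y in zip(aln.seq_a, aln.seq_b):
                col = {None}
                if x != GAP:
                    col.add(x)
                if y != GAP:
                    col.add(y)
                opts.append(sorted(col, key=str))
            best = min(
                _pair_cost(a, b, tuple(c for c in combo if c), costs, scores)
                for combo in product(*opts))
            anc = cache.ancestor(a, b)
            ours = _pair_cost(a, b, anc, costs, scores)
            assert ours == pytest.approx(best), (a, b, anc)


class TestAnnotateEvents:
    def test_identical_descendant_has_no_events(self):
        a = arr("A", "x", "y")
        ev = annotate_events(a, a)
        assert len(ev) == 0 and ev.total_cost == 0

    @pytest.mark.parametrize("descendant,ancestor,kinds,cost", [
        # trailer truncation: one loss per spacer
        (("a", "b", "c"), ("a", "b", "c", "d", "e"),
         ["trailer_loss", "trailer_loss"], 2),
        # internal contiguous deletion: one event regardless of width
        (("a", "e"), ("a", "b", "c", "d", "e"), ["deletion"], 10),
        # leader gain: one acquisition per spacer
        (("x", "y", "a", "b"), ("a", "b"),
         ["acquisition", "acquisition"], 2),
        # duplication of an existing spacer
        (("a", "b", "b", "c"), ("a", "b", "c"), ["duplication"], 1),
        # spacers present only in the descendant, internally: one insertion
        (("a", "x", "y", "b"), ("a", "b"), ["insertion"], 30),
    ])
    def test_module_to_event_mapping(self, descendant, ancestor, kinds, cost):
        ev = annotate_events(arr("D", *descendant), arr("A", *ancestor))
        assert sorted(e.kind for e in ev) == sorted(kinds)
        assert ev.total_cost == cost

    def test_two_separate_deletions_cost_twice(self):
        ev = annotate_events(arr("D", "a", "c", "e"),
                             arr("A", "a", "b", "c", "d", "e"))
        assert sorted(e.kind for e in ev) == ["deletion", "deletion"]
        assert ev.total_cost == 20

    def test_cost_zero_iff_equal(self, rng):
        for _ in range(40):
            a, b = random_spacer_pair(rng, max_len=5)
            cost = annotate_events(arr("D", *a), arr("A", *b)).total_cost
            assert (cost == 0) == (a == b)

    def test_costs_follow_user_scheme(self):
        cheap = CostScheme(deletion=3)
        ev = annotate_events(arr("D", "a", "e"),
                             arr("A", "a", "b", "c", "d", "e"), costs=cheap)
        assert ev.total_cost == 3
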