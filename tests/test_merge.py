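"""Merge/refine stages: grouping, order statistics, unions, refinement, e2e."""

import numpy as np
import pytest

from rapidibd.engine import RapidQueryEngine
from rapidibd.merge import (
    fragmented_ibds,
    group_by_end,
    merge_candidates,
    refine,
)
from rapidibd.pbwt import PBWTIndex
from rapidibd.query import long_match_query
from rapidibd.synthetic import (
    PlantSpec,
    add_genotyping_error,
    worked_example_fixture,
    generate_panel,
    plant_ibd,
)
from rapidibd.types import LengthThreshold, Match

from conftest import random_panel


class TestGroupByEnd:
    def test_direct_grouping(self):
        table = group_by_end([Match(1, 0, 9), Match(1, 2, 9), Match(1, 0, 5)])
        assert sorted(table.buckets[9][1]) == [0, 2]
        assert table.buckets[5][1] == [0]
        assert table.n_matches == 3

    def test_empty_input(self):
        assert group_by_end([]).buckets == {}

    def test_distinct_haps_keep_distinct_keys(self):
        table = group_by_end([Match(1, 0, 9), Match(2, 3, 9)])
        assert set(table.buckets[9]) == {1, 2}
        assert table.buckets[9][1] == [0] and table.buckets[9][2] == [3]


class TestFragmentedIbds:
    def test_cth_smallest_start(self):
        table = group_by_end([Match(0, 4, 20), Match(0, 7, 20), Match(0, 9, 20)])
        assert fragmented_ibds(table, 2) == [Match(0, 7, 20)]

    def test_small_group_discarded(self):
        table = group_by_end([Match(0, 4, 20)])
        assert fragmented_ibds(table, 2) == []

    def test_c1_keeps_smallest(self):
        table = group_by_end(
            [Match(0, 4, 20), Match(0, 7, 20), Match(1, 5, 20), Match(0, 2, 8)]
        )
        assert set(fragmented_ibds(table, 1)) == {
            Match(0, 4, 20),
            Match(1, 5, 20),
            Match(0, 2, 8),
        }

    def test_duplicate_starts_count_with_multiplicity(self):
        table = group_by_end([Match(0, 4, 20), Match(0, 4, 20), Match(0, 9, 20)])
        assert fragmented_ibds(table, 2) == [Match(0, 4, 20)]

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            fragmented_ibds(group_by_end([]), 0)


class TestMergeCandidates:
    def test_overlapping_fragments_union(self):
        table = merge_candidates([Match(0, 10, 20), Match(0, 15, 30)])
        assert table.intervals[0] == [(10, 30)]

    def test_disjoint_fragments_stay_separate(self):
        table = merge_candidates([Match(0, 10, 20), Match(0, 25, 30)])
        assert table.intervals[0] == [(10, 20), (25, 30)]

    def test_single_fragment_identity(self):
        assert merge_candidates([Match(3, 5, 9)]).intervals[3] == [(5, 9)]

    def test_haps_do_not_mix(self):
        table = merge_candidates([Match(0, 10, 20), Match(1, 15, 30)])
        assert table.intervals[0] == [(10, 20)]
        assert table.intervals[1] == [(15, 30)]


class TestRefine:
    cm = np.arange(2000) * 0.01  # 0.01 cM per site

    def test_stitching_across_small_gap(self):
        cands = merge_candidates([Match(0, 10, 30)])
        finals = refine(
            cands,
            [Match(0, 8, 18), Match(0, 21, 29)],
            self.cm,
            gmax_cm=2.0,
            l_final_cm=0.1,
            min_markers=1,
        )
        assert finals == [Match(0, 8, 29)]

    def test_candidate_without_exact_support_dropped(self):
        cands = merge_candidates([Match(0, 10, 30)])
        assert (
            refine(cands, [Match(0, 500, 600)], self.cm, 2.0, 0.1, 1) == []
        )

    def test_exact_match_without_candidate_discarded(self):
        cands = merge_candidates([Match(0, 10, 30)])
        finals = refine(
            cands,
            [Match(0, 5, 40), Match(0, 1000, 1500)],
            self.cm,
            gmax_cm=0.5,
            l_final_cm=0.1,
            min_markers=1,
        )
        assert finals == [Match(0, 5, 40)]

    def test_length_filters_apply(self):
        cands = merge_candidates([Match(0, 10, 30)])
        finals = refine(cands, [Match(0, 10, 30)], self.cm, 2.0, 5.0, 1)
        assert finals == []  # 0.2 cM < 5 cM
        finals = refine(cands, [Match(0, 10, 30)], self.cm, 2.0, 0.1, 100)
        assert finals == []  # 21 markers < 100

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            refine(merge_candidates([]), [], self.cm, -1.0, 1.0, 1)


class TestWorkedExample:
    def test_narrated_stage_counts(self):
        fx = worked_example_fixture()
        table = group_by_end(fx.low_matches)
        assert len(table.buckets) == 6
        fragments = fragmented_ibds(table, fx.params.c)
        assert len(fragments) == 5
        candidates = merge_candidates(fragments)
        assert candidates.n_candidates == 3
        finals = refine(
            candidates,
            fx.exact_full,
            fx.site_cm,
            fx.params.gmax_cm,
            fx.params.l_final_cm,
            fx.params.min_markers,
        )
        assert len(finals) == 2

    def test_final_boundaries(self):
        """First final stitches the two left candidates via the bridging exact
        match; second is trimmed on both ends to the inner exact match."""
        fx = worked_example_fixture()
        table = group_by_end(fx.low_matches)
        candidates = merge_candidates(fragmented_ibds(table, fx.params.c))
        finals = refine(
            candidates,
            fx.exact_full,
            fx.site_cm,
            fx.params.gmax_cm,
            fx.params.l_final_cm,
            fx.params.min_markers,
        )
        assert finals[0] == Match(fx.hap, *fx.exact_full[0][1:])
        trimmed = finals[1]
        merged_cand = candidates.intervals[fx.hap][-1]
        assert merged_cand[0] < trimmed.start and trimmed.end < merged_cand[1]
        assert trimmed == Match(fx.hap, *fx.exact_full[1][1:])


class TestRapidQueryEndToEnd:
    def test_duplicate_query_yields_full_chromosome_call(self, rng):
        panel = random_panel(rng, 30, 400, span_cm=20.0)
        engine = RapidQueryEngine(
            min_cm=5.0, min_markers=10, refine_cm=0.5, window=5, seed=0
        ).fit(panel)
        segs = engine.query(panel.alleles[7], query_id="q")
        own = [s for s in segs if s.panel_hap == "h7"]
        assert len(own) == 1
        assert own[0].start_site == 0 and own[0].end_site == 399

    def test_unrelated_panel_is_silent(self, rng):
        panel = random_panel(rng, 40, 600, span_cm=30.0)
        engine = RapidQueryEngine(
            min_cm=7.0, min_markers=10, refine_cm=1.0, window=5, seed=1
        ).fit(panel)
        q = (rng.random(600) < 0.5).astype(np.uint8)
        assert engine.query(q) == []

    def test_planted_segment_recovered_under_error(self):
        panel = generate_panel(60, 3000, seed=5, span_cm=15.0)
        panel, truth = plant_ibd(panel, PlantSpec(1, min_cm=10.0, max_cm=10.0, seed=6))
        panel = add_genotyping_error(panel, 0.0004, seed=7)
        engine = RapidQueryEngine(
            min_cm=5.0, min_markers=50, refine_cm=0.5, seed=8
        ).fit(panel)
        tr = truth[0]
        qi = panel.hap_ids.index(tr.query_hap)
        segs = engine.query(panel.alleles[qi], query_id=tr.query_hap, exclude=(qi,))
        hits = [s for s in segs if s.panel_hap == tr.panel_hap]
        assert hits, "planted segment not recovered"
        hit = max(hits, key=lambda s: s.cm_len)
        slack = engine.window_ * 2  # one window plus refinement slop, in sites
        assert abs(hit.start_site - tr.start_site) <= slack
        assert abs(hit.end_site - tr.end_site) <= slack

    def test_deterministic_given_seed(self, rng):
        panel = random_panel(rng, 20, 300, span_cm=15.0)
        q = panel.alleles[3]
        a = RapidQueryEngine(min_cm=4.0, min_markers=5, window=5, seed=3).fit(panel)
        b = RapidQueryEngine(min_cm=4.0, min_markers=5, window=5, seed=3).fit(panel)
        assert a.query(q) == b.query(q)

    def test_fragment_count_monotone_in_c(self, rng):
        matches = [
            Match(int(rng.integers(3)), int(s), int(s) + int(rng.integers(5, 20)))
            for s in rng.integers(0, 50, size=60)
        ]
        table = group_by_end(matches)
        counts = [len(fragmented_ibds(table, c)) for c in range(1, 6)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_exact_match_count_monotone_in_refine_cutoff(self, rng):
        panel = random_panel(rng, 20, 200, span_cm=10.0)
        idx = PBWTIndex.from_panel(panel)
        q = panel.alleles[0]
        sizes = [
            len(
                long_match_query(
                    idx, q, LengthThreshold("cM", L), site_cm=panel.site_cm
                )
            )
            for L in (0.25, 0.5, 1.0, 2.0)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
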