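"""Merge and refine projection-run matches into final IBD calls.

Pipeline (all in memory, deterministic):

1.  group rescaled matches by end position (and panel haplotype);
2.  in each (end, haplotype) group keep the match with the c-th smallest
    start — the *fragmented IBD* — discarding groups with fewer than c
    matches (a fragment is therefore completely overlapped by at least c
    run matches);
3.  union overlapping fragments of the same haplotype, sweeping in ascending
    end order, into disjoint *candidate IBDs*;
4.  refine candidates against the exact matches found on the full-resolution
    panel at a short cM cutoff: a candidate's surviving form is the union of
    the exact matches overlapping it (candidates touched by no exact match
    are dropped, exact matches touching no candidate are discarded), refined
    pieces of the same haplotype separated by a genetic gap ≤ gmax are
    stitched into one segment, and final segments must reach the minimum
    genetic length and marker count.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .pbwt import PBWTIndex
from .projection import ProjectionScheme, run_projection_queries
from .query import long_match_query
from .types import IBDSegment, LengthThreshold, Match, segment_from_sites

__all__ = [
    "EndGroupTable",
    "CandidateTable",
    "RapidQueryParams",
    "group_by_end",
    "fragmented_ibds",
    "merge_candidates",
    "refine",
    "rapid_query",
]


@dataclass
class EndGroupTable:
    """Matches bucketed by end site; within a bucket, start multisets per haplotype."""

    buckets: dict[int, dict[int, list[int]]] = field(default_factory=dict)

    def add(self, match: Match) -> None:
        self.buckets.setdefault(match.end, {}).setdefault(match.hap, []).append(
            match.start
        )

    @property
    def n_matches(self) -> int:
        return sum(
            len(starts) for bucket in self.buckets.values() for starts in bucket.values()
        )


@dataclass
class CandidateTable:
    """Per panel haplotype, an ordered list of disjoint candidate intervals."""

    intervals: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def n_candidates(self) -> int:
        return sum(len(v) for v in self.intervals.values())


def group_by_end(matches: Iterable[Match | tuple[int, Match]]) -> EndGroupTable:
    """Group matches (possibly run-tagged) by end position and haplotype."""
    table = EndGroupTable()
    for item in matches:
        table.add(item if isinstance(item, Match) else item[1])
    return table


def fragmented_ibds(table: EndGroupTable, c: int) -> list[Match]:
    """The c-th-smallest-start match of every (end, haplotype) group with ≥ c starts."""
    if c < 1:
        raise ValueError("count threshold c must be >= 1")
    out: list[Match] = []
    for end in sorted(table.buckets):
        for hap in sorted(table.buckets[end]):
            starts = sorted(table.buckets[end][hap])
            if len(starts) >= c:
                out.append(Match(hap, starts[c - 1], end))
    return out


def merge_candidates(fragments: Sequence[Match]) -> CandidateTable:
    """Union overlapping fragments per haplotype, sweeping in ascending end order.

    Two fragments overlap when they share at least one site; abutting but
    non-overlapping fragments stay separate candidates.
    """
    per_hap: dict[int, list[Match]] = defaultdict(list)
    for frag in fragments:
        per_hap[frag.hap].append(frag)
    table = CandidateTable()
    for hap, frags in per_hap.items():
        frags.sort(key=lambda fr: (fr.end, fr.start))
        merged: list[tuple[int, int]] = []
        for frag in frags:
            s, e = frag.start, frag.end
            while merged and s <= merged[-1][1]:
                ps, pe = merged.pop()
                s, e = min(s, ps), max(e, pe)
            merged.append((s, e))
        table.intervals[hap] = merged
    return table


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    intervals.sort()
    merged: list[tuple[int, int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def refine(
    candidates: CandidateTable,
    exact_full: Sequence[Match],
    site_cm: np.ndarray,
    gmax_cm: float,
    l_final_cm: float,
    min_markers: int,
) -> list[Match]:
    """Refine candidate IBDs with full-resolution exact matches (see module docs).

    Returns final segments as site-interval matches; the caller attaches
    physical coordinates and identifiers.
    """
    if gmax_cm < 0:
        raise ValueError("gmax must be non-negative")
    exact_per_hap: dict[int, list[Match]] = defaultdict(list)
    for match in exact_full:
        exact_per_hap[match.hap].append(match)
    out: list[Match] = []
    for hap, cand_ivs in candidates.intervals.items():
        exacts = exact_per_hap.get(hap)
        if not exacts:
            continue
        supported = [
            (ex.start, ex.end)
            for ex in exacts
            if any(ex.start <= ce and cs <= ex.end for cs, ce in cand_ivs)
        ]
        if not supported:
            continue
        pieces = _merge_intervals(supported)
        # stitch refined pieces across genetic gaps <= gmax
        stitched: list[tuple[int, int]] = [pieces[0]]
        for s, e in pieces[1:]:
            ps, pe = stitched[-1]
            if site_cm[s] - site_cm[pe] <= gmax_cm:
                stitched[-1] = (ps, e)
            else:
                stitched.append((s, e))
        for s, e in stitched:
            if site_cm[e] - site_cm[s] >= l_final_cm and e - s + 1 >= min_markers:
                out.append(Match(hap, s, e))
    out.sort(key=lambda mt: (mt.hap, mt.start))
    return out


@dataclass(frozen=True)
class RapidQueryParams:
    """Tuning parameters of the merge/refine search."""

    l_final_cm: float = 7.0  # minimum reported IBD genetic length
    min_markers: int = 700  # minimum reported IBD marker count
    refine_cm: float = 0.5  # cM cutoff of the full-resolution exact-match run
    c: int = 2  # projection runs that must support a fragment
    gmax_cm: float = 2.0  # maximum genetic gap stitched over
    l_lowres: int = 10  # low-resolution threshold, in windows


def rapid_query(
    index: PBWTIndex,
    sub_indexes: list[PBWTIndex],
    scheme: ProjectionScheme,
    query: np.ndarray,
    params: RapidQueryParams,
    site_bp: np.ndarray,
    site_cm: np.ndarray,
    hap_ids: Sequence[str],
    query_id: str = "q0",
    exclude: Sequence[int] = (),
) -> list[IBDSegment]:
    """Full error-tolerant IBD search of one query haplotype against the panel.

    Composition of projection queries → end grouping → c-th-smallest-start
    fragments → candidate merging → full-resolution exact query at the refine
    cutoff → boundary refinement/stitching/length filter.  ``exclude`` lists
    panel haplotype indices to ignore (e.g. the query itself for in-panel
    evaluation runs).
    """
    excluded = set(int(i) for i in exclude)
    tagged = run_projection_queries(sub_indexes, query, scheme, params.l_lowres)
    if excluded:
        tagged = [(run, mt) for run, mt in tagged if mt.hap not in excluded]
    table = group_by_end(tagged)
    fragments = fragmented_ibds(table, params.c)
    candidates = merge_candidates(fragments)
    exact_full = long_match_query(
        index, query, LengthThreshold("cM", params.refine_cm), site_cm=site_cm
    )
    if excluded:
        exact_full = [mt for mt in exact_full if mt.hap not in excluded]
    finals = refine(
        candidates,
        exact_full,
        site_cm,
        params.gmax_cm,
        params.l_final_cm,
        params.min_markers,
    )
    return [
        segment_from_sites(
            query_id, hap_ids[mt.hap], mt.start, mt.end, site_bp, site_cm
        )
        for mt in finals
    ]
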