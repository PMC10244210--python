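"""Accuracy metrics for IBD calls against a planted or simulated truth set.

False negative rate: the average, over true segments, of the fraction of a
true segment's sites not covered by any reported segment of the same
haplotype pair.  False positive rate is the mirror image (reported segments
against truth).  Coverage is evaluated at site granularity on end-inclusive
intervals.  Binned variants assign segments to genetic-length bins and apply
a minimum length floor to the opposing set (reported ≥ 2 cM when scoring
truth, true ≥ 1.5 cM when scoring calls, by default).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import IBDSegment

__all__ = [
    "false_negative_rate",
    "false_positive_rate",
    "binned_rates",
    "length_discrepancy_rms",
    "DEFAULT_BINS",
]

DEFAULT_BINS: tuple[float, ...] = (2.0, 5.0, 7.0, 9.0, 12.0, 15.0, 18.0, float("inf"))


def _pair_key(
    seg: IBDSegment, hap_to_ind: Mapping[str, str] | None
) -> tuple[str, str]:
    a, b = seg.query_hap, seg.panel_hap
    if hap_to_ind is not None:
        a, b = hap_to_ind[a], hap_to_ind[b]
    return (a, b) if a <= b else (b, a)


def _intervals_by_pair(
    segments: Sequence[IBDSegment], hap_to_ind: Mapping[str, str] | None
) -> dict[tuple[str, str], list[tuple[int, int]]]:
    table: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    for seg in segments:
        table[_pair_key(seg, hap_to_ind)].append((seg.start_site, seg.end_site))
    for ivs in table.values():
        ivs.sort()
    return table


def _uncovered_fraction(
    seg: IBDSegment, cover: dict[tuple[str, str], list[tuple[int, int]]],
    hap_to_ind: Mapping[str, str] | None,
) -> float:
    length = seg.end_site - seg.start_site + 1
    # merge the (sorted) covering intervals on the fly so overlaps among the
    # covering set are not double-counted
    covered = 0
    cur_s = cur_e = None
    for s, e in cover.get(_pair_key(seg, hap_to_ind), ()):
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                covered += _overlap(cur_s, cur_e, seg)
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += _overlap(cur_s, cur_e, seg)
    return 1.0 - covered / length


def _overlap(s: int, e: int, seg: IBDSegment) -> int:
    lo = max(s, seg.start_site)
    hi = min(e, seg.end_site)
    return hi - lo + 1 if lo <= hi else 0


def false_negative_rate(
    truth: Sequence[IBDSegment],
    reported: Sequence[IBDSegment],
    hap_to_ind: Mapping[str, str] | None = None,
) -> float:
    """Mean uncovered-site fraction of true segments (0 = every truth site called).

    ``hap_to_ind`` switches pair matching from haplotype level (default) to
    individual level.
    """
    if len(truth) == 0:
        raise ValueError("false negative rate is undefined for an empty truth set")
    cover = _intervals_by_pair(reported, hap_to_ind)
    return float(
        np.mean([_uncovered_fraction(seg, cover, hap_to_ind) for seg in truth])
    )


def false_positive_rate(
    reported: Sequence[IBDSegment],
    truth: Sequence[IBDSegment],
    hap_to_ind: Mapping[str, str] | None = None,
) -> float:
    """Mean uncovered-site fraction of reported segments (0 = all calls inside truth)."""
    if len(reported) == 0:
        raise ValueError("false positive rate is undefined for an empty reported set")
    cover = _intervals_by_pair(truth, hap_to_ind)
    return float(
        np.mean([_uncovered_fraction(seg, cover, hap_to_ind) for seg in reported])
    )


def binned_rates(
    truth: Sequence[IBDSegment],
    reported: Sequence[IBDSegment],
    bins: Sequence[float] = DEFAULT_BINS,
    min_len_rep: float = 2.0,
    min_len_true: float = 1.5,
    hap_to_ind: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-genetic-length-bin FNR and FPR.

    A segment is assigned to a bin by its own cM length.  FNR in a bin uses
    only reported segments of length ≥ ``min_len_rep`` as cover; FPR uses only
    true segments ≥ ``min_len_true``.  Empty bins yield NaN.
    """
    edges = list(bins)
    if any(b >= a for b, a in zip(edges, edges[1:])) and edges != sorted(edges):
        raise ValueError("bin edges must be ascending")
    rep_cover = _intervals_by_pair(
        [s for s in reported if s.cm_len >= min_len_rep], hap_to_ind
    )
    true_cover = _intervals_by_pair(
        [s for s in truth if s.cm_len >= min_len_true], hap_to_ind
    )
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin_t = [s for s in truth if lo <= s.cm_len < hi]
        in_bin_r = [s for s in reported if lo <= s.cm_len < hi]
        fnr = (
            float(np.mean([_uncovered_fraction(s, rep_cover, hap_to_ind) for s in in_bin_t]))
            if in_bin_t
            else float("nan")
        )
        fpr = (
            float(np.mean([_uncovered_fraction(s, true_cover, hap_to_ind) for s in in_bin_r]))
            if in_bin_r
            else float("nan")
        )
        rows.append(
            {
                "bin_lo_cm": lo,
                "bin_hi_cm": hi,
                "n_true": len(in_bin_t),
                "n_reported": len(in_bin_r),
                "fnr": fnr,
                "fpr": fpr,
            }
        )
    return pd.DataFrame(rows)


def length_discrepancy_rms(
    reported: Sequence[IBDSegment],
    truth: Sequence[IBDSegment],
    hap_to_ind: Mapping[str, str] | None = None,
) -> float:
    """Root-mean-square genetic length difference between calls and truth.

    Each reported segment is paired with the same-pair true segment of maximal
    site overlap; a reported segment overlapping no true segment contributes
    its full length as discrepancy.
    """
    if len(reported) == 0:
        raise ValueError("length discrepancy is undefined for an empty reported set")
    truth_by_pair: dict[tuple[str, str], list[IBDSegment]] = defaultdict(list)
    for seg in truth:
        truth_by_pair[_pair_key(seg, hap_to_ind)].append(seg)
    deltas = []
    for rep in reported:
        best = None
        best_ov = 0
        for tr in truth_by_pair.get(_pair_key(rep, hap_to_ind), ()):
            ov = _overlap(tr.start_site, tr.end_site, rep)
            if ov > best_ov:
                best, best_ov = tr, ov
        if best is None:
            deltas.append(rep.cm_len)
        else:
            deltas.append(rep.cm_len - best.cm_len)
    return float(np.sqrt(np.mean(np.square(deltas))))
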