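"""Sum-of-IBD-length relatedness analysis.

Familial relatedness is inferred from the total genetic length of IBD
segments shared by an individual pair, aggregated over the four haplotype
pairings.  Separation between adjacent degrees of relatedness is quantified
as the AUC of the total length used as a score for the closer degree
(rank/Mann–Whitney statistic, ties counted half).

Also provides exact pedigree kinship coefficients (tabular method) and the
conventional kinship-coefficient ranges mapping a pair to a degree class —
first degree (0.177, 0.354], halving per degree down to fourth
(0.0221, 0.0442]; at or below 0.0221 a pair is treated as unrelated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .types import IBDSegment

__all__ = [
    "PairSummary",
    "pair_totals",
    "degree_auc",
    "kinship_matrix",
    "degree_from_kinship",
    "DEGREE_KINSHIP_EDGES",
]

# KING-style kinship ranges; index d covers (2^-(d+3/2), 2^-(d+1/2)]
DEGREE_KINSHIP_EDGES: dict[str, tuple[float, float]] = {
    "1": (0.177, 0.354),
    "2": (0.0884, 0.177),
    "3": (0.0442, 0.0884),
    "4": (0.0221, 0.0442),
}


@dataclass(frozen=True)
class PairSummary:
    """Total shared IBD length of one individual pair."""

    ind_a: str
    ind_b: str
    total_cm: float
    n_segments: int
    degree_label: str | None = None


def pair_totals(
    segments: Sequence[IBDSegment],
    hap_to_ind: Mapping[str, str],
    labels: Mapping[tuple[str, str], str] | None = None,
) -> list[PairSummary]:
    """Aggregate segment genetic lengths per individual pair.

    Duplicate rows (same haplotype pair and same site interval, e.g. a
    segment reported from both sides' queries) are counted once.  Self pairs
    and within-individual haplotype matches are excluded.  Raises on a
    haplotype id missing from ``hap_to_ind``.
    """
    seen: set[tuple] = set()
    totals: dict[tuple[str, str], list[float]] = {}
    for seg in segments:
        for hap in (seg.query_hap, seg.panel_hap):
            if hap not in hap_to_ind:
                raise KeyError(f"haplotype id {hap!r} has no individual mapping")
        a, b = hap_to_ind[seg.query_hap], hap_to_ind[seg.panel_hap]
        if a == b:
            continue
        hap_pair = tuple(sorted((seg.query_hap, seg.panel_hap)))
        key = (*hap_pair, seg.start_site, seg.end_site)
        if key in seen:
            continue
        seen.add(key)
        pair = (a, b) if a <= b else (b, a)
        totals.setdefault(pair, []).append(seg.cm_len)
    out = []
    for pair in sorted(totals):
        lens = totals[pair]
        label = labels.get(pair) if labels is not None else None
        out.append(
            PairSummary(pair[0], pair[1], float(sum(lens)), len(lens), label)
        )
    return out


def degree_auc(
    summaries: Sequence[PairSummary], degree_a: str, degree_b: str
) -> float:
    """AUC of total_cm separating ``degree_a`` (closer, positives) from ``degree_b``.

    Computed from the rank statistic; ties count one half.  Both classes must
    be present.
    """
    pos = [s.total_cm for s in summaries if s.degree_label == degree_a]
    neg = [s.total_cm for s in summaries if s.degree_label == degree_b]
    if not pos or not neg:
        raise ValueError(
            f"both degree classes needed: {degree_a!r} n={len(pos)}, "
            f"{degree_b!r} n={len(neg)}"
        )
    scores = np.concatenate([pos, neg])
    ranks = rankdata(scores)
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def kinship_matrix(fathers: Sequence[int], mothers: Sequence[int]) -> np.ndarray:
    """Pedigree kinship coefficients by the tabular method.

    ``fathers[i]``/``mothers[i]`` give parent indices of individual ``i``
    (−1 = founder parent, unknown and unrelated); parents must precede
    children in index order.  Returns the symmetric (N × N) kinship matrix
    including self-kinship on the diagonal.
    """
    n = len(fathers)
    phi = np.zeros((n, n), dtype=np.float32)
    for i in range(n):
        f, m = fathers[i], mothers[i]
        if f >= i or m >= i:
            raise ValueError("parents must precede children in index order")
        if f >= 0 and m >= 0:
            row = 0.5 * (phi[f, :i] + phi[m, :i])
            phi_self = 0.5 * (1.0 + phi[f, m])
        elif f >= 0 or m >= 0:
            parent = max(f, m)
            row = 0.5 * phi[parent, :i]
            phi_self = 0.5
        else:
            row = np.zeros(i, dtype=np.float32)
            phi_self = 0.5
        phi[i, :i] = row
        phi[:i, i] = row
        phi[i, i] = phi_self
    return phi


def degree_from_kinship(phi: float) -> str:
    """Degree class label for a kinship coefficient (\"unrelated\" below 4th degree)."""
    for label, (lo, hi) in DEGREE_KINSHIP_EDGES.items():
        if lo < phi <= hi:
            return label
    if phi > DEGREE_KINSHIP_EDGES["1"][1]:
        return "0"  # duplicate/monozygotic
    return "unrelated"
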