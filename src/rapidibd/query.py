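"""Long-match query of one haplotype against a PBWT-indexed panel.

Finds every maximal exact match between an out-of-panel query haplotype and
each panel haplotype whose length reaches a threshold given either as a site
count or as a genetic length in cM.  The sweep keeps a virtual insertion
index for the query in the sorted order at each site boundary, plus the
match-start positions of the query against its two sorted neighbours; the
long-match block around the insertion point is walked outward only while the
accumulated match start still satisfies the threshold, so the scan cost is
O(n + output) in the typical case and O(n·m) in the worst case.

For cM thresholds the per-end start bound is the site distance track index
``max{ i ≤ e : cm[e] − cm[i] ≥ L }``, which moves monotonically with the
scanned end site.
"""

from __future__ import annotations

import numpy as np

from .pbwt import PBWTIndex
from .types import HaplotypePanel, LengthThreshold, Match

__all__ = [
    "site_distance_index",
    "site_distance_indices",
    "long_match_query",
    "brute_force_long_matches",
]


def site_distance_index(site_cm: np.ndarray, k: int, L: float) -> int | None:
    """Largest site ``i ≤ k`` with ``site_cm[k] − site_cm[i] ≥ L``, or ``None``.

    Maintained implicitly by a monotone pointer during an ascending scan; this
    standalone form computes it directly for one position.
    """
    if L < 0:
        raise ValueError("distance L must be non-negative")
    site_cm = np.asarray(site_cm, dtype=np.float64)
    if not 0 <= k < site_cm.size:
        raise ValueError("site index out of range")
    i = int(np.searchsorted(site_cm, site_cm[k] - L, side="right")) - 1
    if i < 0:
        return None
    return min(i, k)


def site_distance_indices(site_cm: np.ndarray, L: float) -> np.ndarray:
    """Vector of site distance track indices for every end site (−1 = none)."""
    if L < 0:
        raise ValueError("distance L must be non-negative")
    site_cm = np.asarray(site_cm, dtype=np.float64)
    idx = np.searchsorted(site_cm, site_cm - L, side="right") - 1
    return np.minimum(idx, np.arange(site_cm.size)).astype(np.int64)


def _max_start_per_end(
    n: int, threshold: LengthThreshold, site_cm: np.ndarray | None
) -> np.ndarray:
    """For each end site e, the largest admissible match start (−1 = none)."""
    if threshold.kind == "sites":
        L = int(np.ceil(threshold.value))
        return np.arange(n, dtype=np.int64) - (L - 1)
    if site_cm is None:
        raise ValueError("cM threshold requires panel genetic positions")
    return site_distance_indices(site_cm, threshold.value)


def long_match_query(
    index: PBWTIndex,
    query: np.ndarray,
    threshold: LengthThreshold,
    site_cm: np.ndarray | None = None,
) -> list[Match]:
    """All maximal exact query↔panel matches meeting ``threshold``.

    ``site_cm`` overrides the genetic positions stored on the index (needed
    only for ``kind='cM'`` thresholds).
    """
    z = np.asarray(query, dtype=np.uint8)
    n, m = index.n_sites, index.n_haps
    if z.shape != (n,):
        raise ValueError(f"query length {z.shape} does not match panel sites {n}")
    if not np.isin(z, (0, 1)).all():
        raise ValueError("query alleles must be 0/1")
    cm = site_cm if site_cm is not None else index.site_cm
    smax = _max_start_per_end(n, threshold, cm)

    p, d, u, y, c = index.p, index.d, index.u, index.y, index.c
    out: list[Match] = []
    t = 0  # virtual insertion index of the query in the sorted order
    dz_up = 0  # match start of query vs sorted neighbour above (position t-1)
    dz_down = 0  # match start of query vs sorted neighbour below (position t)

    for k in range(n + 1):
        if k >= 1 and smax[k - 1] >= 0:
            s_bound = smax[k - 1]
            dk = d[k]
            pk = p[k]
            yk = y[k] if k < n else None
            zk = int(z[k]) if k < n else -1
            # walk up: positions t-1, t-2, ... while the match start qualifies
            start = dz_up
            i = t - 1
            while i >= 0 and start <= s_bound:
                if yk is None or yk[i] != zk:
                    out.append(Match(int(pk[i]), int(start), k - 1))
                start = max(start, int(dk[i]))
                i -= 1
            # walk down: positions t, t+1, ...
            start = dz_down
            i = t
            while i < m and start <= s_bound:
                if yk is None or yk[i] != zk:
                    out.append(Match(int(pk[i]), int(start), k - 1))
                i += 1
                if i < m:
                    start = max(start, int(dk[i]))
        if k == n:
            break
        # advance the insertion point through site k
        a = int(z[k])
        uk = u[k]
        dk = d[k]
        yk = y[k]
        t_next = int(uk[t]) if a == 0 else int(c[k]) + t - int(uk[t])
        cur = dz_up
        i = t - 1
        while i >= 0 and yk[i] != a:
            cur = max(cur, int(dk[i]))
            i -= 1
        dz_up = cur if i >= 0 else k + 1
        cur = dz_down
        i = t
        while i < m and yk[i] != a:
            i += 1
            if i < m:
                cur = max(cur, int(dk[i]))
        dz_down = cur if i < m else k + 1
        t = t_next
    return out


def brute_force_long_matches(
    panel: HaplotypePanel | np.ndarray,
    query: np.ndarray,
    threshold: LengthThreshold,
    site_cm: np.ndarray | None = None,
) -> list[Match]:
    """Reference O(n·m) enumeration of maximal matches meeting ``threshold``.

    Defines ground truth for :func:`long_match_query`; kept deliberately
    independent of the PBWT machinery.
    """
    if isinstance(panel, HaplotypePanel):
        alleles = panel.alleles
        if site_cm is None:
            site_cm = panel.site_cm
    else:
        alleles = np.asarray(panel, dtype=np.uint8)
    z = np.asarray(query, dtype=np.uint8)
    m, n = alleles.shape
    if z.shape != (n,):
        raise ValueError("query length does not match panel sites")
    out: list[Match] = []
    eq = alleles == z[None, :]
    for h in range(m):
        row = eq[h]
        # maximal runs of agreement
        padded = np.concatenate(([False], row, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1) - 1
        for s, e in zip(starts, ends):
            if threshold.qualifies(int(s), int(e), site_cm):
                out.append(Match(h, int(s), int(e)))
    return out
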