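"""Random projection of a panel onto low-resolution sub-panels.

The ``n`` sites are divided into ``⌈n/w⌉`` windows of ``w`` sites (the last
window may be shorter).  For each of ``r`` projection runs, one site per
window is drawn with probability proportional to its minor allele frequency
(uniformly if every MAF in the window is zero).  A low-resolution panel keeps
one column per window, so a mismatch inside a window is skipped by a run
whenever the run's sampled site avoids it — this is what makes the exact
long-match query error-tolerant once several runs are combined.

Low-resolution match coordinates (window indices) are rescaled back to full
resolution as ``[w·h', w·(t'+1)−1]``, clipped to the last site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pbwt import PBWTIndex
from .query import long_match_query
from .types import HaplotypePanel, LengthThreshold, Match

__all__ = [
    "ProjectionScheme",
    "make_projection",
    "project",
    "rescale_match",
    "run_projection_queries",
]


@dataclass(frozen=True)
class ProjectionScheme:
    """r MAF-weighted sub-index vectors over windows of ``window`` sites."""

    window: int
    n_sites: int
    sub_indices: np.ndarray  # (r, n_windows) full-resolution site indices
    seed: int

    @property
    def r(self) -> int:
        return self.sub_indices.shape[0]

    @property
    def n_windows(self) -> int:
        return self.sub_indices.shape[1]


def make_projection(
    panel: HaplotypePanel, w: int, r: int, seed: int
) -> ProjectionScheme:
    """Draw ``r`` independent MAF-weighted sub-indices, one site per window.

    Runs use independent child streams of one seeded RNG, so extending ``r``
    leaves earlier runs unchanged.
    """
    n = panel.n_sites
    if not 1 <= w <= n:
        raise ValueError(f"window size {w} must be in [1, {n}]")
    if r < 1:
        raise ValueError("number of runs r must be >= 1")
    n_windows = -(-n // w)
    starts = np.arange(n_windows) * w
    stops = np.minimum(starts + w, n)
    maf = np.asarray(panel.maf, dtype=np.float64)
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(r)]
    sub = np.empty((r, n_windows), dtype=np.int64)
    for j, rng in enumerate(streams):
        for s_idx in range(n_windows):
            lo, hi = int(starts[s_idx]), int(stops[s_idx])
            weights = maf[lo:hi]
            total = weights.sum()
            if total > 0:
                probs = weights / total
                sub[j, s_idx] = lo + rng.choice(hi - lo, p=probs)
            else:
                sub[j, s_idx] = lo + rng.integers(hi - lo)
    return ProjectionScheme(window=w, n_sites=n, sub_indices=sub, seed=seed)


def project(
    panel_or_query: HaplotypePanel | np.ndarray, sub_index: np.ndarray
) -> HaplotypePanel | np.ndarray:
    """Column subset of a panel (or allele vector) in sub-index order."""
    sub_index = np.asarray(sub_index, dtype=np.int64)
    if isinstance(panel_or_query, HaplotypePanel):
        if sub_index.size and sub_index.max() >= panel_or_query.n_sites:
            raise ValueError("sub-index exceeds panel site count")
        return panel_or_query.subset_sites(sub_index)
    vec = np.asarray(panel_or_query)
    if sub_index.size and sub_index.max() >= vec.shape[-1]:
        raise ValueError("sub-index exceeds query length")
    return vec[sub_index]


def rescale_match(match: Match, w: int, n_sites: int | None = None) -> Match:
    """Rescale a low-resolution match ``(id, [h', t'])`` to ``(id, [w·h', w·(t'+1)−1])``.

    The tail is clipped to ``n_sites − 1`` when the final window is partial.
    """
    if match.start < 0 or match.end < match.start:
        raise ValueError("match coordinates must be non-negative and ordered")
    start = w * match.start
    end = w * (match.end + 1) - 1
    if n_sites is not None:
        end = min(end, n_sites - 1)
    return Match(match.hap, start, end)


def run_projection_queries(
    sub_indexes: list[PBWTIndex],
    query: np.ndarray,
    scheme: ProjectionScheme,
    l_lowres: int,
) -> list[tuple[int, Match]]:
    """Run the exact long-match query on every low-resolution panel.

    Returns the union over runs, with multiplicity, of full-resolution
    rescaled matches tagged ``(run, match)``.  ``l_lowres`` is the window-count
    threshold (typically ``round(L*/w)`` for a full-resolution minimum of
    ``L*`` sites).
    """
    if len(sub_indexes) != scheme.r:
        raise ValueError(
            f"{len(sub_indexes)} sub-panel indexes given for r={scheme.r} scheme"
        )
    z = np.asarray(query, dtype=np.uint8)
    if z.shape != (scheme.n_sites,):
        raise ValueError("query length does not match the projection scheme")
    threshold = LengthThreshold("sites", l_lowres)
    out: list[tuple[int, Match]] = []
    for run, (idx, sub_index) in enumerate(zip(sub_indexes, scheme.sub_indices)):
        if idx.n_sites != sub_index.size:
            raise ValueError("sub-panel index does not match the scheme")
        z_sub = z[sub_index]
        for match in long_match_query(idx, z_sub, threshold):
            out.append((run, rescale_match(match, scheme.window, scheme.n_sites)))
    return out
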