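"""Positional Burrows–Wheeler transform (PBWT) index construction.

The index stores, for every site boundary ``k`` (0..n), the prefix array
``p[k]`` — the permutation that sorts haplotypes by their reversed prefixes
over sites ``[0, k)`` — and the divergence array ``d[k]`` — for each sorted
position ``i``, the smallest site ``j`` such that haplotypes ``p[k][i]`` and
``p[k][i-1]`` agree on all of ``[j, k)`` (``d[k][0] = k`` by convention:
the top haplotype has no predecessor).

Per site ``k`` it additionally stores the cumulative 0-allele counts
``u[k][i]`` (number of 0 alleles at site ``k`` among the first ``i`` sorted
haplotypes) and the sorted allele row ``y[k]``.  The 1-allele complement is
``v[k][i] = i - u[k][i]`` and ``c[k] = u[k][m]`` is the total 0 count.  These
support interval extension: the haplotypes of a sorted interval ``[f, g)``
that carry allele ``a`` at site ``k`` occupy the sorted interval
``[extend(f, a), extend(g, a))`` at boundary ``k+1``.

Construction is a single left-to-right sweep, O(m·n) time and memory.
"""

from __future__ import annotations

import numpy as np

from .types import HaplotypePanel

__all__ = ["PBWTIndex", "build_pbwt_index"]


class PBWTIndex:
    """PBWT arrays of one haplotype panel (see module docstring)."""

    def __init__(
        self,
        p: np.ndarray,
        d: np.ndarray,
        u: np.ndarray,
        y: np.ndarray,
        site_cm: np.ndarray | None = None,
    ) -> None:
        self.p = p  # (n+1, m) prefix arrays
        self.d = d  # (n+1, m) divergence arrays
        self.u = u  # (n, m+1) cumulative 0 counts
        self.y = y  # (n, m) alleles in sorted order
        self.c = u[:, -1].copy() if u.shape[0] else np.zeros(0, dtype=u.dtype)
        self.n_sites = y.shape[0]
        self.n_haps = p.shape[1]
        self.site_cm = None if site_cm is None else np.asarray(site_cm, float)

    @classmethod
    def from_alleles(
        cls, alleles: np.ndarray, site_cm: np.ndarray | None = None
    ) -> "PBWTIndex":
        alleles = np.asarray(alleles, dtype=np.uint8)
        if alleles.ndim != 2 or alleles.size == 0:
            raise ValueError("cannot build a PBWT index from an empty panel")
        m, n = alleles.shape
        p = np.empty((n + 1, m), dtype=np.int32)
        d = np.empty((n + 1, m), dtype=np.int32)
        u = np.empty((n, m + 1), dtype=np.int32)
        y = np.empty((n, m), dtype=np.uint8)
        p[0] = np.arange(m, dtype=np.int32)
        d[0] = 0
        for k in range(n):
            pk = p[k]
            dk = d[k]
            yk = alleles[pk, k]
            y[k] = yk
            zero = yk == 0
            np.cumsum(zero, out=u[k, 1:])
            u[k, 0] = 0
            idx0 = np.flatnonzero(zero)
            idx1 = np.flatnonzero(~zero)
            p[k + 1, : idx0.size] = pk[idx0]
            p[k + 1, idx0.size :] = pk[idx1]
            d[k + 1, : idx0.size] = _group_divergence(dk, idx0, k)
            d[k + 1, idx0.size :] = _group_divergence(dk, idx1, k)
        return cls(p, d, u, y, site_cm=site_cm)

    @classmethod
    def from_panel(cls, panel: HaplotypePanel) -> "PBWTIndex":
        return cls.from_alleles(panel.alleles, site_cm=panel.site_cm)

    def v(self, k: int, i: int) -> int:
        """Number of 1-alleles at site ``k`` among the first ``i`` sorted haplotypes."""
        return int(i - self.u[k, i])

    def extend_interval(self, k: int, f: int, g: int, a: int) -> tuple[int, int]:
        """Map sorted interval ``[f, g)`` at boundary ``k`` through allele ``a`` at site ``k``.

        Returns the boundary-``k+1`` sorted interval of the haplotypes that were
        in ``[f, g)`` and carry ``a`` at site ``k``.  An empty input interval
        yields an empty interval.
        """
        if not (0 <= f <= g <= self.n_haps):
            raise ValueError(f"interval [{f}, {g}) out of range for m={self.n_haps}")
        if not 0 <= k < self.n_sites:
            raise ValueError(f"site {k} out of range")
        uk = self.u[k]
        if a == 0:
            return int(uk[f]), int(uk[g])
        c = int(self.c[k])
        return c + int(f - uk[f]), c + int(g - uk[g])


def _group_divergence(dk: np.ndarray, idx: np.ndarray, k: int) -> np.ndarray:
    """Divergence values at boundary k+1 for one allele group.

    For the j-th group member at old sorted position ``idx[j]`` the new
    divergence is ``max(dk[idx[j-1]+1 .. idx[j]])`` — the largest divergence
    crossed since the previous member of the same group — and the group head
    gets the sentinel ``k+1``.
    """
    if idx.size == 0:
        return np.empty(0, dtype=dk.dtype)
    seg_starts = np.empty(idx.size, dtype=np.int64)
    seg_starts[0] = 0
    seg_starts[1:] = idx[:-1] + 1
    out = np.maximum.reduceat(dk[: idx[-1] + 1], seg_starts)
    out[0] = k + 1
    return out.astype(dk.dtype, copy=False)


def build_pbwt_index(panel: HaplotypePanel) -> PBWTIndex:
    """Build the PBWT index of ``panel`` (thin wrapper over :class:`PBWTIndex`)."""
    return PBWTIndex.from_panel(panel)
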