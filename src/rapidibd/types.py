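"""Core data containers: haplotype panels, genetic maps, matches and IBD calls.

A haplotype panel holds ``m`` phased bi-allelic haplotypes over ``n`` sites,
together with each site's physical position (bp), genetic position (cM) and
minor allele frequency.  Site indices are 0-based throughout; reported match
and segment intervals are end-inclusive site indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "GeneticMap",
    "HaplotypePanel",
    "Match",
    "LengthThreshold",
    "IBDSegment",
]


@dataclass(frozen=True)
class GeneticMap:
    """Monotone physical → genetic coordinate map for one chromosome.

    ``bp`` must be strictly increasing and ``cm`` non-decreasing.  Positions
    inside the mapped range are linearly interpolated; positions outside it
    take the boundary value (constant extrapolation).
    """

    bp: np.ndarray
    cm: np.ndarray

    def __post_init__(self) -> None:
        bp = np.asarray(self.bp, dtype=np.int64)
        cm = np.asarray(self.cm, dtype=np.float64)
        if bp.size == 0:
            raise ValueError("genetic map is empty")
        if bp.shape != cm.shape or bp.ndim != 1:
            raise ValueError("bp and cm must be 1-D arrays of equal length")
        if bp.size > 1 and np.any(np.diff(bp) <= 0):
            raise ValueError("map bp positions must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise ValueError("map cM positions must be non-decreasing")
        object.__setattr__(self, "bp", bp)
        object.__setattr__(self, "cm", cm)

    def interpolate(self, bp: np.ndarray | Sequence[int] | int) -> np.ndarray | float:
        """Genetic position(s) in cM at physical position(s) ``bp``."""
        res = np.interp(np.asarray(bp, dtype=np.float64), self.bp, self.cm)
        if np.isscalar(bp) or np.asarray(bp).ndim == 0:
            return float(res)
        return res


def minor_allele_frequencies(alleles: np.ndarray) -> np.ndarray:
    """Per-site MAF of a 0/1 haplotype matrix (haplotypes × sites)."""
    freq1 = alleles.mean(axis=0)
    return np.minimum(freq1, 1.0 - freq1)


@dataclass
class HaplotypePanel:
    """Phased bi-allelic panel: ``alleles`` is (m haplotypes × n sites) in {0,1}."""

    alleles: np.ndarray
    site_bp: np.ndarray
    site_cm: np.ndarray
    hap_ids: list[str] = field(default_factory=list)
    maf: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2 or self.alleles.size == 0:
            raise ValueError("alleles must be a non-empty 2-D matrix")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be 0/1 (bi-allelic)")
        self.site_bp = np.asarray(self.site_bp, dtype=np.int64)
        self.site_cm = np.asarray(self.site_cm, dtype=np.float64)
        n = self.alleles.shape[1]
        if self.site_bp.shape != (n,) or self.site_cm.shape != (n,):
            raise ValueError("site_bp/site_cm length must equal the site count")
        if n > 1 and np.any(np.diff(self.site_bp) <= 0):
            raise ValueError("site_bp must be strictly increasing")
        if np.any(np.diff(self.site_cm) < 0):
            raise ValueError("site_cm must be non-decreasing")
        if not self.hap_ids:
            self.hap_ids = [f"h{i}" for i in range(self.alleles.shape[0])]
        if len(self.hap_ids) != self.alleles.shape[0]:
            raise ValueError("hap_ids length must equal the haplotype count")
        if self.maf is None:
            self.maf = minor_allele_frequencies(self.alleles)
        else:
            self.maf = np.asarray(self.maf, dtype=np.float64)
            if self.maf.shape != (n,):
                raise ValueError("maf length must equal the site count")

    @property
    def n_haps(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def span_cm(self) -> float:
        return float(self.site_cm[-1] - self.site_cm[0])

    def subset_sites(self, idx: np.ndarray) -> "HaplotypePanel":
        """Panel restricted to the site indices ``idx`` (in the given order)."""
        idx = np.asarray(idx, dtype=np.int64)
        return HaplotypePanel(
            alleles=self.alleles[:, idx],
            site_bp=self.site_bp[idx],
            site_cm=self.site_cm[idx],
            hap_ids=list(self.hap_ids),
            maf=np.asarray(self.maf)[idx],
        )

    def with_alleles(self, alleles: np.ndarray) -> "HaplotypePanel":
        """Copy of the panel with a new allele matrix (MAF recomputed)."""
        return replace(self, alleles=alleles, maf=None)


class Match(NamedTuple):
    """Maximal exact match between the query and one panel haplotype.

    ``hap`` is the panel haplotype index; ``start``/``end`` are inclusive
    site indices in the coordinate system of the panel the match was found in.
    """

    hap: int
    start: int
    end: int

    @property
    def n_sites(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class LengthThreshold:
    """Minimum match length, either in sites or in centiMorgans."""

    kind: str  # "sites" | "cM"
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("sites", "cM"):
            raise ValueError(f"unknown threshold kind {self.kind!r}")
        if self.value <= 0:
            raise ValueError("threshold value must be positive")

    def qualifies(self, start: int, end: int, site_cm: np.ndarray | None) -> bool:
        if self.kind == "sites":
            return end - start + 1 >= self.value
        if site_cm is None:
            raise ValueError("cM threshold requires site_cm")
        return site_cm[end] - site_cm[start] >= self.value


@dataclass(frozen=True)
class IBDSegment:
    """A reported (or ground-truth) IBD segment between two haplotypes."""

    query_hap: str
    panel_hap: str
    start_site: int
    end_site: int
    start_bp: int
    end_bp: int
    cm_len: float
    n_markers: int

    @property
    def pair(self) -> tuple[str, str]:
        """Unordered haplotype pair key."""
        return tuple(sorted((self.query_hap, self.panel_hap)))  # type: ignore[return-value]


def segment_from_sites(
    query_hap: str,
    panel_hap: str,
    start: int,
    end: int,
    site_bp: np.ndarray,
    site_cm: np.ndarray,
) -> IBDSegment:
    """Build an :class:`IBDSegment` from inclusive site indices and panel coords."""
    return IBDSegment(
        query_hap=query_hap,
        panel_hap=panel_hap,
        start_site=int(start),
        end_site=int(end),
        start_bp=int(site_bp[start]),
        end_bp=int(site_bp[end]),
        cm_len=float(site_cm[end] - site_cm[start]),
        n_markers=int(end - start + 1),
    )
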