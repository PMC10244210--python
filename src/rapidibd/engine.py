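"""High-level search engine: pre-process a panel once, query many haplotypes.

`RapidQueryEngine` follows the fit/query idiom of scikit-learn neighbour
searches: `fit(panel)` builds the full-resolution PBWT index, the projection
scheme and the r low-resolution sub-panel indexes; `query` (or `predict` for
a batch) runs the error-tolerant IBD search for out-of-panel haplotypes.
All randomness is confined to the seeded projection scheme, so fitted engines
are deterministic end to end.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .merge import RapidQueryParams, rapid_query
from .pbwt import PBWTIndex
from .projection import make_projection, project
from .query import long_match_query
from .types import HaplotypePanel, IBDSegment, LengthThreshold, Match, segment_from_sites

__all__ = ["RapidQueryEngine"]


class RapidQueryEngine:
    """One-versus-all error-tolerant IBD search over a pre-indexed panel.

    Parameters
    ----------
    min_cm : minimum genetic length of a reported IBD segment (cM).
    min_markers : minimum marker count of a reported segment.
    refine_cm : cM cutoff of the full-resolution exact-match refinement run;
        0.5 suits sequencing-density panels, 1–2 sparser array panels.
    r : number of random projection runs.
    c : projection runs that must support a fragment (count threshold).
    window : projection window size in sites; ``None`` chooses
        ``round(min_cm · site_density / windows_per_cutoff)``.
    windows_per_cutoff : target number of windows spanned by a minimum-length
        segment when ``window`` is auto-selected.
    gmax_cm : maximum genetic gap stitched over during refinement.
    seed : RNG seed of the projection scheme.
    """

    def __init__(
        self,
        min_cm: float = 7.0,
        min_markers: int = 700,
        refine_cm: float = 0.5,
        r: int = 10,
        c: int = 2,
        window: int | None = None,
        windows_per_cutoff: int = 10,
        gmax_cm: float = 2.0,
        seed: int = 0,
    ) -> None:
        self.min_cm = min_cm
        self.min_markers = min_markers
        self.refine_cm = refine_cm
        self.r = r
        self.c = c
        self.window = window
        self.windows_per_cutoff = windows_per_cutoff
        self.gmax_cm = gmax_cm
        self.seed = seed

    _param_names = (
        "min_cm",
        "min_markers",
        "refine_cm",
        "r",
        "c",
        "window",
        "windows_per_cutoff",
        "gmax_cm",
        "seed",
    )

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **params) -> "RapidQueryEngine":
        for key, value in params.items():
            if key not in self._param_names:
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # ------------------------------------------------------------------

    def fit(self, panel: HaplotypePanel) -> "RapidQueryEngine":
        """Pre-process ``panel``: PBWT index, projection scheme, sub-indexes."""
        n = panel.n_sites
        span = panel.span_cm
        density = n / span if span > 0 else float(n)
        l_sites = max(1.0, self.min_cm * density)
        w = self.window
        if w is None:
            w = int(round(l_sites / self.windows_per_cutoff))
        w = int(np.clip(w, 1, n))
        l_lowres = max(1, int(round(l_sites / w)))
        self.panel_ = panel
        self.window_ = w
        self.l_lowres_ = l_lowres
        self.index_ = PBWTIndex.from_panel(panel)
        self.scheme_ = make_projection(panel, w, self.r, self.seed)
        self.sub_indexes_ = [
            PBWTIndex.from_panel(project(panel, sub))
            for sub in self.scheme_.sub_indices
        ]
        self.params_ = RapidQueryParams(
            l_final_cm=self.min_cm,
            min_markers=self.min_markers,
            refine_cm=self.refine_cm,
            c=self.c,
            gmax_cm=self.gmax_cm,
            l_lowres=l_lowres,
        )
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "index_"):
            raise RuntimeError("engine is not fitted; call fit(panel) first")

    def query(
        self,
        haplotype: np.ndarray,
        query_id: str = "q0",
        exclude: Sequence[int] = (),
    ) -> list[IBDSegment]:
        """Error-tolerant IBD segments of one query haplotype vs the panel."""
        self._check_fitted()
        panel = self.panel_
        return rapid_query(
            self.index_,
            self.sub_indexes_,
            self.scheme_,
            np.asarray(haplotype, dtype=np.uint8),
            self.params_,
            panel.site_bp,
            panel.site_cm,
            panel.hap_ids,
            query_id=query_id,
            exclude=exclude,
        )

    def query_exact(
        self,
        haplotype: np.ndarray,
        query_id: str = "q0",
        exclude: Sequence[int] = (),
    ) -> list[IBDSegment]:
        """Mismatch-free long-match query at the engine's min_cm cutoff."""
        self._check_fitted()
        panel = self.panel_
        excluded = set(int(i) for i in exclude)
        matches: list[Match] = long_match_query(
            self.index_,
            np.asarray(haplotype, dtype=np.uint8),
            LengthThreshold("cM", self.min_cm),
            site_cm=panel.site_cm,
        )
        return [
            segment_from_sites(
                query_id, panel.hap_ids[mt.hap], mt.start, mt.end,
                panel.site_bp, panel.site_cm,
            )
            for mt in matches
            if mt.hap not in excluded and mt.n_sites >= self.min_markers
        ]

    def predict(
        self, haplotypes: np.ndarray, query_ids: Sequence[str] | None = None
    ) -> list[IBDSegment]:
        """Batch query: rows of ``haplotypes`` are independent query haplotypes."""
        haplotypes = np.atleast_2d(np.asarray(haplotypes, dtype=np.uint8))
        if query_ids is None:
            query_ids = [f"q{i}" for i in range(haplotypes.shape[0])]
        out: list[IBDSegment] = []
        for qid, hap in zip(query_ids, haplotypes):
            out.extend(self.query(hap, query_id=qid))
        return out
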