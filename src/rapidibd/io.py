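"""Readers and writers for the formats the tool touches.

Phased VCF panels (via cyvcf2), HapMap-style and PLINK-style genetic maps,
and the tab-separated IBD call table.  Panels are single-chromosome; a
diploid sample contributes two haplotypes named ``<sample>_0``/``<sample>_1``.
Missing genotypes are unsupported (complete phased panels are assumed).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import GeneticMap, HaplotypePanel, IBDSegment

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_genetic_map",
    "write_genetic_map",
    "write_ibd",
    "read_ibd",
]

IBD_COLUMNS = [
    "query_hap",
    "panel_hap",
    "start_site",
    "end_site",
    "start_bp",
    "end_bp",
    "cm_length",
    "n_markers",
]


def read_vcf(
    path: str | Path,
    genetic_map: GeneticMap | None = None,
    maf_threshold: float = 0.01,
) -> HaplotypePanel:
    """Read a phased single-chromosome VCF into a haplotype panel.

    Multi-allelic sites and sites with MAF ≤ ``maf_threshold`` are removed.
    Genetic positions come from ``genetic_map`` interpolation (zeros if no
    map is given).  Raises on unphased or missing genotypes, naming the
    offending record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    bps: list[int] = []
    chroms: set[str] = set()
    for variant in vcf:
        label = f"{variant.CHROM}:{variant.POS}"
        chroms.add(variant.CHROM)
        if len(chroms) > 1:
            raise ValueError("multi-chromosome VCFs are not supported in one call")
        if len(variant.ALT) != 1:
            raise ValueError(f"multi-allelic record at {label}")
        gts = variant.genotypes  # [allele0, allele1, phased] per sample
        site = np.empty(2 * len(samples), dtype=np.int16)
        for i, (a0, a1, phased) in enumerate(gts):
            if a0 < 0 or a1 < 0:
                raise ValueError(f"missing genotype at {label}, sample {samples[i]}")
            if not phased:
                raise ValueError(f"unphased genotype at {label}, sample {samples[i]}")
            if a0 > 1 or a1 > 1:
                raise ValueError(f"multi-allelic genotype at {label}, sample {samples[i]}")
            site[2 * i] = a0
            site[2 * i + 1] = a1
        rows.append(site)
        bps.append(variant.POS)
    if not rows:
        raise ValueError(f"no usable records in {path}")
    alleles = np.asarray(rows, dtype=np.uint8).T  # haplotypes × sites
    site_bp = np.asarray(bps, dtype=np.int64)
    freq1 = alleles.mean(axis=0)
    maf = np.minimum(freq1, 1 - freq1)
    keep = maf > maf_threshold
    alleles, site_bp = alleles[:, keep], site_bp[keep]
    if alleles.shape[1] == 0:
        raise ValueError("no sites left after the MAF filter")
    site_cm = (
        np.asarray(genetic_map.interpolate(site_bp), dtype=np.float64)
        if genetic_map is not None
        else np.zeros(site_bp.size)
    )
    hap_ids = [f"{s}_{w}" for s in samples for w in (0, 1)]
    return HaplotypePanel(
        alleles=alleles, site_bp=site_bp, site_cm=site_cm, hap_ids=hap_ids
    )


def write_vcf(panel: HaplotypePanel, path: str | Path, chrom: str = "1") -> None:
    """Write a panel as an uncompressed phased VCF (haps 2i, 2i+1 per sample)."""
    if panel.n_haps % 2 != 0:
        raise ValueError("panel must have an even haplotype count to form samples")
    samples = [panel.hap_ids[2 * i].rsplit("_", 1)[0] for i in range(panel.n_haps // 2)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for k in range(panel.n_sites):
            gts = "\t".join(
                f"{panel.alleles[2 * i, k]}|{panel.alleles[2 * i + 1, k]}"
                for i in range(len(samples))
            )
            fh.write(
                f"{chrom}\t{panel.site_bp[k]}\tsite{k}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_genetic_map(path: str | Path, dialect: str = "hapmap") -> GeneticMap:
    """Read a genetic map: HapMap-style (pos/rate/cM) or PLINK .map dialect."""
    if dialect not in ("hapmap", "plink"):
        raise ValueError(f"unknown map dialect {dialect!r}")
    if dialect == "hapmap":
        df = pd.read_csv(path, sep=r"\s+")
        if df.shape[1] < 3:
            raise ValueError("HapMap-style map needs position, rate and cM columns")
        cols = [c.lower() for c in df.columns]
        pos_col = df.columns[
            next(i for i, c in enumerate(cols) if "pos" in c or c == "bp")
        ]
        cm_candidates = [
            i for i, c in enumerate(cols) if ("map" in c or "cm" in c) and "rate" not in c
        ]
        cm_col = df.columns[cm_candidates[-1]]
        bp, cm = df[pos_col].to_numpy(), df[cm_col].to_numpy()
    else:
        df = pd.read_csv(path, sep=r"\s+", header=None)
        if df.shape[1] < 4:
            raise ValueError("PLINK .map needs chrom, id, cM and bp columns")
        bp, cm = df[3].to_numpy(), df[2].to_numpy()
    if len(bp) == 0:
        raise ValueError(f"empty genetic map: {path}")
    order = np.argsort(bp)
    return GeneticMap(np.asarray(bp)[order], np.asarray(cm)[order])


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    """Write a HapMap-style map (position, rate, cM)."""
    rate = np.zeros_like(gmap.cm)
    if gmap.bp.size > 1:
        rate[:-1] = np.diff(gmap.cm) / np.maximum(np.diff(gmap.bp), 1) * 1e6
    pd.DataFrame(
        {
            "Position(bp)": gmap.bp,
            "Rate(cM/Mb)": rate,
            "Map(cM)": gmap.cm,
        }
    ).to_csv(path, sep="\t", index=False)


def write_ibd(segments: Sequence[IBDSegment], path: str | Path) -> None:
    """Write IBD calls as a TSV with end-inclusive site indices."""
    rows = [
        {
            "query_hap": s.query_hap,
            "panel_hap": s.panel_hap,
            "start_site": s.start_site,
            "end_site": s.end_site,
            "start_bp": s.start_bp,
            "end_bp": s.end_bp,
            "cm_length": s.cm_len,
            "n_markers": s.n_markers,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=IBD_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ibd(path: str | Path) -> list[IBDSegment]:
    """Read an IBD call table written by :func:`write_ibd`."""
    df = pd.read_csv(path, sep="\t")
    missing = set(IBD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"IBD table missing columns: {sorted(missing)}")
    return [
        IBDSegment(
            query_hap=str(r.query_hap),
            panel_hap=str(r.panel_hap),
            start_site=int(r.start_site),
            end_site=int(r.end_site),
            start_bp=int(r.start_bp),
            end_bp=int(r.end_bp),
            cm_len=float(r.cm_length),
            n_markers=int(r.n_markers),
        )
        for r in df.itertuples()
    ]
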