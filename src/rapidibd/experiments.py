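"""End-to-end benchmark experiments on synthetic data.

These are the package's self-contained study designs: a planted-IBD accuracy
benchmark (detection power / precision / length fidelity of the full search
pipeline under genotyping error) and a forward-pedigree relatedness-degree
separation study.  Problem sizes are desk-scale versions of biobank-style
panels: large enough for stable rates, small enough to run routinely.

Both tests and the reproduction script call these functions, so reported
numbers always come from the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import RapidQueryEngine
from .evaluation import binned_rates, false_negative_rate, false_positive_rate, length_discrepancy_rms
from .genealogy import PairSummary, degree_auc, pair_totals
from .merge import fragmented_ibds, group_by_end, merge_candidates, refine
from .pbwt import PBWTIndex
from .query import brute_force_long_matches, long_match_query
from .synthetic import (
    PedigreeSpec,
    PlantSpec,
    add_genotyping_error,
    worked_example_fixture,
    generate_panel,
    plant_ibd,
    simulate_pedigree,
)
from .types import LengthThreshold

__all__ = [
    "worked_example_counts",
    "oracle_agreement",
    "planted_accuracy_experiment",
    "pedigree_separation_experiment",
]


def worked_example_counts() -> dict:
    """Run merge/refine on the frozen worked example; return the stage counts."""
    fx = worked_example_fixture()
    table = group_by_end(fx.low_matches)
    fragments = fragmented_ibds(table, fx.params.c)
    candidates = merge_candidates(fragments)
    finals = refine(
        candidates,
        fx.exact_full,
        fx.site_cm,
        fx.params.gmax_cm,
        fx.params.l_final_cm,
        fx.params.min_markers,
    )
    return {
        "n_groups": len(table.buckets),
        "n_fragments": len(fragments),
        "n_candidates": candidates.n_candidates,
        "n_final": len(finals),
        "finals": finals,
    }


def oracle_agreement(
    seed: int,
    n_instances: int = 1000,
    max_m: int = 64,
    max_n: int = 256,
) -> dict:
    """Fraction of random instances where the PBWT long-match query equals brute force.

    Instances randomize panel size, allele frequency, query, threshold kind
    (sites or cM) and threshold value.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        m = int(rng.integers(2, max_m + 1))
        n = int(rng.integers(4, max_n + 1))
        freq = rng.uniform(0.05, 0.95)
        alleles = (rng.random((m, n)) < freq).astype(np.uint8)
        z = (rng.random(n) < freq).astype(np.uint8)
        if rng.random() < 0.3:  # give some instances long shared stretches
            h = int(rng.integers(m))
            s = int(rng.integers(n))
            e = int(rng.integers(s, n))
            z[s : e + 1] = alleles[h, s : e + 1]
        cm = np.cumsum(rng.uniform(0.0, 0.1, size=n))
        cm -= cm[0]
        if rng.random() < 0.5:
            thr = LengthThreshold("sites", int(rng.integers(1, max(2, n // 2))))
        else:
            thr = LengthThreshold("cM", float(rng.uniform(0.05, max(0.1, cm[-1]))))
        idx = PBWTIndex.from_alleles(alleles, site_cm=cm)
        got = set(long_match_query(idx, z, thr))
        want = set(brute_force_long_matches(alleles, z, thr, site_cm=cm))
        agree += got == want
    return {"agreement": agree / n_instances, "n": n_instances}


def planted_accuracy_experiment(
    seed: int,
    m: int = 500,
    n_sites: int = 20_000,
    span_cm: float = 100.0,
    n_segments: int = 200,
    seg_min_cm: float = 3.0,
    seg_max_cm: float = 20.0,
    error_rate: float = 0.0004,
    refine_cm: float = 0.5,
    r: int = 10,
    c: int = 2,
    l_final_cm: float = 3.0,
    min_markers: int = 100,
) -> dict:
    """Planted-IBD benchmark: detection rates of the full pipeline under error.

    Segments of uniform 3–20 cM genetic length are planted on disjoint
    haplotype pairs of an unrelated panel, genotyping error is added, and
    every recipient haplotype is queried against the panel (self excluded).
    Returns overall and binned FNR/FPR plus the RMS genetic-length
    discrepancy of the calls.
    """
    panel = generate_panel(m, n_sites, seed=seed, span_cm=span_cm)
    panel, truth = plant_ibd(
        panel,
        PlantSpec(n_segments, min_cm=seg_min_cm, max_cm=seg_max_cm, seed=seed + 1),
    )
    panel = add_genotyping_error(panel, error_rate, seed=seed + 2)
    engine = RapidQueryEngine(
        min_cm=l_final_cm,
        min_markers=min_markers,
        refine_cm=refine_cm,
        r=r,
        c=c,
        seed=seed + 3,
    ).fit(panel)
    hap_index = {hid: i for i, hid in enumerate(panel.hap_ids)}
    calls = []
    for seg in truth:
        qi = hap_index[seg.query_hap]
        calls.extend(
            engine.query(panel.alleles[qi], query_id=seg.query_hap, exclude=(qi,))
        )
    table = binned_rates(truth, calls)
    return {
        "fnr": false_negative_rate(truth, calls),
        "fpr": false_positive_rate(calls, truth),
        "rms_cm": length_discrepancy_rms(calls, truth),
        "binned": table,
        "truth": truth,
        "calls": calls,
        "n_truth": len(truth),
        "n_calls": len(calls),
        "n_queries": len(truth),
    }


@dataclass
class _PairPick:
    ind_a: int
    ind_b: int
    degree: str


DEGREE_ORDER = ("1", "2", "3", "4", "unrelated")


def pedigree_separation_experiment(
    seed: int,
    founders: int = 1000,
    generations: int = 4,
    pop_size: int = 1000,
    n_chrom: int = 5,
    chrom_cm: float = 200.0,
    sites_per_cm: float = 20.0,
    error_rate: float = 0.0013,
    pairs_per_degree: int = 30,
    refine_cm: float = 2.0,
    min_cm: float = 7.0,
    min_markers: int = 100,
    r: int = 10,
    c: int = 2,
    windows_per_cutoff: int = 20,
) -> dict:
    """Relatedness-degree separation from summed IBD lengths on a forward pedigree.

    Simulates a closed pedigree over several chromosomes, labels pairs of the
    last four generations by exact pedigree kinship, samples pairs of each
    degree class (1st–4th and unrelated), queries one member of each pair
    with the full pipeline and totals the called IBD shared with the other.
    Returns per-degree mean totals and adjacent-degree AUCs.

    ``windows_per_cutoff`` defaults higher than the engine's general default
    because spurious low-resolution matches scale with panel depth
    (≈ m · p_agree^l for an l-window threshold); 20 windows per 7 cM keeps
    the per-run false-match rate controlled on a many-thousand-haplotype
    pedigree panel while a single site error still only voids one of 20
    windows.
    """
    rng = np.random.default_rng(seed)
    n_sites = int(chrom_cm * sites_per_cm)
    founder_panels = [
        generate_panel(2 * founders, n_sites, seed=seed + 100 + i, span_cm=chrom_cm)
        for i in range(n_chrom)
    ]
    sim = simulate_pedigree(
        founder_panels,
        PedigreeSpec(
            founders=founders,
            generations=generations,
            pop_size=pop_size,
            seed=seed + 200,
        ),
    )

    # classify kept pairs by kinship and sample a fixed number per class
    kept = np.asarray(sim.kept)
    phi = sim.kinship[np.ix_(kept, kept)]
    iu, ju = np.triu_indices(len(kept), k=1)
    vals = phi[iu, ju]
    edges = (0.0221, 0.0442, 0.0884, 0.177, 0.354)
    classes = {
        "unrelated": vals <= edges[0],
        "4": (vals > edges[0]) & (vals <= edges[1]),
        "3": (vals > edges[1]) & (vals <= edges[2]),
        "2": (vals > edges[2]) & (vals <= edges[3]),
        "1": (vals > edges[3]) & (vals <= edges[4]),
    }
    picks: list[_PairPick] = []
    for degree in DEGREE_ORDER:
        cand = np.flatnonzero(classes[degree])
        if cand.size < pairs_per_degree:
            raise RuntimeError(
                f"only {cand.size} pairs of degree {degree} in the pedigree"
            )
        chosen = rng.choice(cand, size=pairs_per_degree, replace=False)
        picks.extend(
            _PairPick(int(kept[iu[k]]), int(kept[ju[k]]), degree) for k in chosen
        )

    hap_pos: dict[str, int] = {}
    for i, ind in enumerate(sim.kept):
        hap_pos[f"i{ind}_0"] = 2 * i
        hap_pos[f"i{ind}_1"] = 2 * i + 1

    # query the first member of every picked pair, chromosome by chromosome
    queried = sorted({p.ind_a for p in picks})
    segments = []
    for ci in range(n_chrom):
        panel = add_genotyping_error(sim.panels[ci], error_rate, seed=seed + 300 + ci)
        engine = RapidQueryEngine(
            min_cm=min_cm,
            min_markers=min_markers,
            refine_cm=refine_cm,
            r=r,
            c=c,
            windows_per_cutoff=windows_per_cutoff,
            seed=seed + 400 + ci,
        ).fit(panel)
        for ind in queried:
            own = (hap_pos[f"i{ind}_0"], hap_pos[f"i{ind}_1"])
            for w in (0, 1):
                segs = engine.query(
                    panel.alleles[own[w]], query_id=f"i{ind}_{w}", exclude=own
                )
                # chromosome-disambiguated site coordinates for dedup
                for s in segs:
                    segments.append(
                        type(s)(
                            s.query_hap,
                            s.panel_hap,
                            s.start_site + ci * n_sites,
                            s.end_site + ci * n_sites,
                            s.start_bp,
                            s.end_bp,
                            s.cm_len,
                            s.n_markers,
                        )
                    )

    wanted_pairs = {
        tuple(sorted((f"i{p.ind_a}", f"i{p.ind_b}"))): p.degree for p in picks
    }
    hap_to_ind = sim.hap_to_ind()
    relevant = [
        s
        for s in segments
        if tuple(sorted((hap_to_ind[s.query_hap], hap_to_ind[s.panel_hap])))
        in wanted_pairs
    ]
    summaries = pair_totals(relevant, hap_to_ind, labels=wanted_pairs)
    nonzero = {(s.ind_a, s.ind_b) for s in summaries}
    for pair, degree in wanted_pairs.items():
        if pair not in nonzero:
            summaries.append(PairSummary(pair[0], pair[1], 0.0, 0, degree))

    means = {
        degree: float(
            np.mean([s.total_cm for s in summaries if s.degree_label == degree])
        )
        for degree in DEGREE_ORDER
    }
    aucs = {
        f"{a}_vs_{b}": degree_auc(summaries, a, b)
        for a, b in zip(DEGREE_ORDER, DEGREE_ORDER[1:])
    }
    return {
        "means": means,
        "aucs": aucs,
        "n_pairs": len(summaries),
        "summaries": summaries,
        "genome_cm": chrom_cm * n_chrom,
    }
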