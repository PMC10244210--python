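"""Synthetic inputs: panels with planted IBD truth, error models, pedigrees.

Everything the test-bench needs is generated here programmatically:

* random panels with independent sites drawn from a minor-allele-frequency
  spectrum (no background relatedness, so long spurious matches are
  exponentially rare);
* planted IBD segments — a donor haplotype's alleles copied onto a recipient
  over a genetic interval, recorded as ground truth;
* genotyping error (independent allele flips) and phase error (within-
  individual allele swaps);
* a forward multi-generation pedigree simulator with Poisson crossovers
  (λ = Lt/50 per chromosome of genetic length Lt cM) and founder-ancestry
  tracking, so true IBD intervals and exact pedigree kinship are available;
* the frozen merge/refine worked-example fixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .genealogy import degree_from_kinship, kinship_matrix
from .merge import RapidQueryParams
from .types import GeneticMap, HaplotypePanel, IBDSegment, Match, segment_from_sites

__all__ = [
    "synthetic_map",
    "generate_panel",
    "PlantSpec",
    "plant_ibd",
    "add_genotyping_error",
    "add_phasing_error",
    "PedigreeSpec",
    "PedigreeSim",
    "simulate_pedigree",
    "WorkedExampleFixture",
    "worked_example_fixture",
]


def synthetic_map(
    n_sites: int, span_cm: float, seed: int = 0, start_bp: int = 1_000_000
) -> tuple[np.ndarray, np.ndarray, GeneticMap]:
    """Random marker coordinates: strictly increasing bp, non-decreasing cM.

    Physical gaps are jittered around ~1 kb and the recombination rate varies
    smoothly around 1 cM/Mb so that cM spacing is irregular, as on real maps.
    Returns (site_bp, site_cm, GeneticMap over the same points).
    """
    rng = np.random.default_rng(seed)
    gaps_bp = rng.integers(200, 2000, size=n_sites)
    site_bp = start_bp + np.cumsum(gaps_bp)
    rate = np.clip(rng.gamma(shape=4.0, scale=0.25, size=n_sites), 0.0, None)
    cm_gaps = rate * gaps_bp
    site_cm = np.cumsum(cm_gaps)
    total = site_cm[-1] - site_cm[0]
    if total > 0:
        site_cm = (site_cm - site_cm[0]) * (span_cm / total)
    else:  # single site: a point map
        site_cm = np.zeros(n_sites)
    return site_bp, site_cm, GeneticMap(site_bp, site_cm)


def _default_maf_sampler(rng: np.random.Generator, n: int) -> np.ndarray:
    """~1/f allele-frequency spectrum truncated below at 1% (post-filter panels)."""
    lo, hi = 0.011, 0.5
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))


def generate_panel(
    m: int,
    n: int,
    maf_sampler: Callable[[np.random.Generator, int], np.ndarray] | float | None = None,
    site_bp: np.ndarray | None = None,
    site_cm: np.ndarray | None = None,
    seed: int = 0,
    span_cm: float | None = None,
    hap_prefix: str = "h",
) -> HaplotypePanel:
    """Panel of ``m`` haplotypes × ``n`` independent sites.

    Allele 1 at each site is drawn with the site's target frequency (a fixed
    float, a sampler callable, or the default spectrum).  Coordinates default
    to a fresh synthetic map spanning ``span_cm`` (or ~n/200 cM).
    """
    if m < 1 or n < 1:
        raise ValueError("panel dimensions must be positive")
    rng = np.random.default_rng(seed)
    if site_bp is None or site_cm is None:
        site_bp, site_cm, _ = synthetic_map(
            n, span_cm if span_cm is not None else max(1.0, n / 200.0), seed=seed + 1
        )
    if maf_sampler is None:
        freqs = _default_maf_sampler(rng, n)
    elif callable(maf_sampler):
        freqs = np.asarray(maf_sampler(rng, n), dtype=np.float64)
    else:
        freqs = np.full(n, float(maf_sampler))
    if np.any(freqs < 0) or np.any(freqs > 1):
        raise ValueError("allele frequencies must be in [0, 1]")
    alleles = (rng.random((m, n)) < freqs[None, :]).astype(np.uint8)
    return HaplotypePanel(
        alleles=alleles,
        site_bp=site_bp,
        site_cm=site_cm,
        hap_ids=[f"{hap_prefix}{i}" for i in range(m)],
    )


@dataclass(frozen=True)
class PlantSpec:
    """How many IBD segments to plant and how long (uniform cM range)."""

    n_segments: int
    min_cm: float = 3.0
    max_cm: float = 20.0
    seed: int = 0
    disjoint_pairs: bool = True  # each hap participates in at most one pair
    max_retries: int = 200


def plant_ibd(
    panel: HaplotypePanel, spec: PlantSpec
) -> tuple[HaplotypePanel, list[IBDSegment]]:
    """Copy donor alleles onto recipients over cM-defined intervals.

    Segment boundaries snap to sites; the recorded truth uses the snapped
    interval.  Overlapping plants on one recipient are never produced; with
    ``disjoint_pairs`` every haplotype is used by at most one donor/recipient
    pair (one planted segment per pair).
    """
    if spec.max_cm > panel.span_cm:
        raise ValueError("planted lengths must fit inside the panel map span")
    rng = np.random.default_rng(spec.seed)
    m = panel.n_haps
    if spec.disjoint_pairs and 2 * spec.n_segments > m:
        raise ValueError("not enough haplotypes for disjoint donor/recipient pairs")
    alleles = panel.alleles.copy()
    cm = panel.site_cm
    truth: list[IBDSegment] = []
    if spec.disjoint_pairs:
        order = rng.permutation(m)
        pairs = [
            (int(order[2 * i]), int(order[2 * i + 1])) for i in range(spec.n_segments)
        ]
    else:
        pairs = [
            tuple(rng.choice(m, size=2, replace=False)) for _ in range(spec.n_segments)
        ]
    occupied: dict[int, list[tuple[int, int]]] = {}
    for donor, recipient in pairs:
        length = rng.uniform(spec.min_cm, spec.max_cm)
        placed = False
        for _ in range(spec.max_retries):
            start_cm = rng.uniform(cm[0], cm[-1] - length)
            s = int(np.searchsorted(cm, start_cm, side="left"))
            e = int(np.searchsorted(cm, start_cm + length, side="left"))
            e = min(e, panel.n_sites - 1)
            if cm[e] - cm[s] < length * 0.5:
                continue
            if any(s <= oe and os_ <= e for os_, oe in occupied.get(recipient, ())):
                continue
            occupied.setdefault(recipient, []).append((s, e))
            alleles[recipient, s : e + 1] = alleles[donor, s : e + 1]
            truth.append(
                segment_from_sites(
                    panel.hap_ids[recipient],
                    panel.hap_ids[donor],
                    s,
                    e,
                    panel.site_bp,
                    panel.site_cm,
                )
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place a {length:.2f} cM segment after "
                f"{spec.max_retries} retries"
            )
    return panel.with_alleles(alleles), truth


def add_genotyping_error(
    panel: HaplotypePanel, rate: float, seed: int = 0
) -> HaplotypePanel:
    """Flip each allele independently with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("error rate must be in [0, 1]")
    if rate == 0.0:
        return panel
    rng = np.random.default_rng(seed)
    flips = rng.random(panel.alleles.shape) < rate
    return panel.with_alleles(np.where(flips, 1 - panel.alleles, panel.alleles))


def add_phasing_error(
    panel: HaplotypePanel, rate: float, seed: int = 0
) -> HaplotypePanel:
    """Swap the two haplotypes of each individual at random sites (rate per site).

    Haplotypes 2i and 2i+1 are assumed to belong to individual i.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("error rate must be in [0, 1]")
    if rate == 0.0 or panel.n_haps < 2:
        return panel
    rng = np.random.default_rng(seed)
    alleles = panel.alleles.copy()
    n_ind = panel.n_haps // 2
    swaps = rng.random((n_ind, panel.n_sites)) < rate
    for i in range(n_ind):
        cols = np.flatnonzero(swaps[i])
        if cols.size:
            a = alleles[2 * i, cols].copy()
            alleles[2 * i, cols] = alleles[2 * i + 1, cols]
            alleles[2 * i + 1, cols] = a
    return panel.with_alleles(alleles)


# ---------------------------------------------------------------------------
# forward pedigree simulation


@dataclass(frozen=True)
class PedigreeSpec:
    """Forward-in-time mating design over a fixed founder population."""

    founders: int  # founder individuals (generation 0)
    generations: int  # descendant generations simulated
    pop_size: int | None = None  # individuals per descendant generation (default founders)
    max_couples: int = 500
    extra_pair_prob: float = 0.2  # chance a child's father is another male of the generation
    keep_generations: int = 4  # trailing generations whose data is extracted
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.extra_pair_prob <= 1.0:
            raise ValueError("extra_pair_prob must be in [0, 1]")
        if self.founders < 2 or self.generations < 0:
            raise ValueError("need at least 2 founders and >= 0 generations")


@dataclass
class PedigreeSim:
    """Output of :func:`simulate_pedigree` (see attribute docs in code)."""

    panels: list[HaplotypePanel]  # one per chromosome, kept individuals only
    pedigree: pd.DataFrame  # id, father, mother, sex, generation (all individuals)
    kept: list[int]  # individual ids present in the panels
    ancestry: list[dict[tuple[int, int], tuple[np.ndarray, np.ndarray]]]
    # per chromosome: (individual, hap) -> (run start sites, founder hap ids)
    kinship: np.ndarray  # pedigree kinship matrix over all individuals

    def hap_to_ind(self) -> dict[str, str]:
        mapping = {}
        for ind in self.kept:
            for which in (0, 1):
                mapping[f"i{ind}_{which}"] = f"i{ind}"
        return mapping

    def degree_label(self, ind_a: int, ind_b: int) -> str:
        return degree_from_kinship(float(self.kinship[ind_a, ind_b]))

    def pair_labels(self) -> dict[tuple[str, str], str]:
        """Degree labels for every kept individual pair."""
        out = {}
        for i, a in enumerate(self.kept):
            for b in self.kept[i + 1 :]:
                key = tuple(sorted((f"i{a}", f"i{b}")))
                out[key] = self.degree_label(a, b)
        return out

    def true_ibd(
        self, chrom: int, ind_a: int, ind_b: int, min_cm: float = 1.0
    ) -> list[IBDSegment]:
        """Ground-truth IBD between two individuals on one chromosome.

        Intervals where two haplotypes carry the same founder haplotype,
        reported per haplotype pairing, at genetic length ≥ ``min_cm``.
        """
        panel = self.panels[chrom]
        anc = self.ancestry[chrom]
        out = []
        for wa in (0, 1):
            for wb in (0, 1):
                runs_a = anc[(ind_a, wa)]
                runs_b = anc[(ind_b, wb)]
                for s, e in _shared_intervals(runs_a, runs_b, panel.n_sites):
                    if panel.site_cm[e] - panel.site_cm[s] >= min_cm:
                        out.append(
                            segment_from_sites(
                                f"i{ind_a}_{wa}",
                                f"i{ind_b}_{wb}",
                                s,
                                e,
                                panel.site_bp,
                                panel.site_cm,
                            )
                        )
        return out


def _shared_intervals(
    runs_a: tuple[np.ndarray, np.ndarray],
    runs_b: tuple[np.ndarray, np.ndarray],
    n_sites: int,
) -> list[tuple[int, int]]:
    """Site intervals on which two ancestry mosaics carry the same founder hap."""
    starts_a, src_a = runs_a
    starts_b, src_b = runs_b
    bounds = np.union1d(starts_a, starts_b)
    out: list[tuple[int, int]] = []
    cur_start = None
    cur_src = None
    for i, b in enumerate(bounds):
        end = int(bounds[i + 1]) - 1 if i + 1 < bounds.size else n_sites - 1
        sa = src_a[np.searchsorted(starts_a, b, side="right") - 1]
        sb = src_b[np.searchsorted(starts_b, b, side="right") - 1]
        if sa == sb:
            if cur_start is not None and cur_src == sa:
                out[-1] = (out[-1][0], end)
            else:
                out.append((int(b), end))
                cur_start, cur_src = int(b), sa
        else:
            cur_start, cur_src = None, None
    return out


def _gamete(
    hap0: tuple[np.ndarray, np.ndarray],
    hap1: tuple[np.ndarray, np.ndarray],
    alleles0: np.ndarray,
    alleles1: np.ndarray,
    site_cm: np.ndarray,
    lt_cm: float,
    rng: np.random.Generator,
) -> tuple[tuple[np.ndarray, np.ndarray], np.ndarray]:
    """One recombinant gamete: Poisson(Lt/50) crossovers uniform in cM."""
    n = site_cm.size
    n_x = rng.poisson(lt_cm / 50.0)
    if n_x:
        pos_cm = np.sort(rng.uniform(site_cm[0], site_cm[-1], size=n_x))
        cuts = np.unique(np.searchsorted(site_cm, pos_cm, side="left"))
        cuts = cuts[(cuts > 0) & (cuts < n)]
    else:
        cuts = np.empty(0, dtype=np.int64)
    first = int(rng.integers(2))
    seg_starts = np.concatenate([[0], cuts])
    seg_ends = np.concatenate([cuts, [n]])
    alleles = np.empty(n, dtype=np.uint8)
    run_starts: list[int] = []
    run_srcs: list[int] = []
    for j, (s, e) in enumerate(zip(seg_starts, seg_ends)):
        use0 = (j + first) % 2 == 0
        src_runs = hap0 if use0 else hap1
        alleles[s:e] = (alleles0 if use0 else alleles1)[s:e]
        starts, srcs = src_runs
        k0 = int(np.searchsorted(starts, s, side="right") - 1)
        for k in range(k0, starts.size):
            rs = max(int(starts[k]), int(s))
            if rs >= e:
                break
            if run_srcs and run_srcs[-1] == int(srcs[k]) and run_starts[-1] <= rs:
                continue  # contiguous same-source run
            run_starts.append(rs)
            run_srcs.append(int(srcs[k]))
    return (np.asarray(run_starts), np.asarray(run_srcs)), alleles


def simulate_pedigree(
    founder_panels: Sequence[HaplotypePanel], spec: PedigreeSpec
) -> PedigreeSim:
    """Forward-simulate a closed pedigree over one or more chromosomes.

    Each descendant generation pairs up to ``max_couples`` non-overlapping
    couples from the previous generation; every child draws a couple, and with
    probability ``extra_pair_prob`` its father is replaced by a different male
    of the same generation.  Gametes recombine with Poisson(Lt/50) crossovers
    placed uniformly in cM.  Founder ancestry is tracked exactly, so true IBD
    and pedigree kinship are available for the extracted last
    ``keep_generations`` generations.
    """
    for panel in founder_panels:
        if panel.n_haps != 2 * spec.founders:
            raise ValueError("founder panels must have 2 haplotypes per founder")
    rng = np.random.default_rng(spec.seed)
    pop = spec.pop_size if spec.pop_size is not None else spec.founders

    # --- pedigree structure (shared by all chromosomes)
    sexes = list(rng.integers(2, size=spec.founders))
    fathers = [-1] * spec.founders
    mothers = [-1] * spec.founders
    gen_of = [0] * spec.founders
    gen_members = [list(range(spec.founders))]
    next_id = spec.founders
    for g in range(1, spec.generations + 1):
        prev = gen_members[-1]
        males = [i for i in prev if sexes[i] == 1]
        females = [i for i in prev if sexes[i] == 0]
        n_c = min(spec.max_couples, len(males), len(females))
        if n_c < 1:
            raise ValueError("generation has no possible couple")
        couple_m = list(rng.permutation(males)[:n_c])
        couple_f = list(rng.permutation(females)[:n_c])
        members = []
        for _ in range(pop):
            ci = int(rng.integers(n_c))
            mother, father = couple_f[ci], couple_m[ci]
            if len(males) > 1 and rng.random() < spec.extra_pair_prob:
                while True:
                    alt = males[int(rng.integers(len(males)))]
                    if alt != couple_m[ci]:
                        father = alt
                        break
            sexes.append(int(rng.integers(2)))
            fathers.append(father)
            mothers.append(mother)
            gen_of.append(g)
            members.append(next_id)
            next_id += 1
        gen_members.append(members)

    keep_gens = range(
        max(0, spec.generations - spec.keep_generations + 1), spec.generations + 1
    )
    kept = [i for g in keep_gens for i in gen_members[g]]

    # --- per-chromosome transmission
    panels: list[HaplotypePanel] = []
    ancestry_all: list[dict[tuple[int, int], tuple[np.ndarray, np.ndarray]]] = []
    for panel in founder_panels:
        n = panel.n_sites
        lt = panel.span_cm
        alleles = {
            (i, w): panel.alleles[2 * i + w]
            for i in range(spec.founders)
            for w in (0, 1)
        }
        anc: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {
            (i, w): (np.array([0]), np.array([2 * i + w]))
            for i in range(spec.founders)
            for w in (0, 1)
        }
        for ind in range(spec.founders, next_id):
            for w, parent in ((0, fathers[ind]), (1, mothers[ind])):
                runs, al = _gamete(
                    anc[(parent, 0)],
                    anc[(parent, 1)],
                    alleles[(parent, 0)],
                    alleles[(parent, 1)],
                    panel.site_cm,
                    lt,
                    rng,
                )
                anc[(ind, w)] = runs
                alleles[(ind, w)] = al
        mat = np.vstack([alleles[(i, w)] for i in kept for w in (0, 1)])
        panels.append(
            HaplotypePanel(
                alleles=mat,
                site_bp=panel.site_bp,
                site_cm=panel.site_cm,
                hap_ids=[f"i{i}_{w}" for i in kept for w in (0, 1)],
            )
        )
        ancestry_all.append({key: anc[key] for key in anc if key[0] in set(kept)})

    pedigree = pd.DataFrame(
        {
            "id": np.arange(next_id),
            "father": fathers,
            "mother": mothers,
            "sex": sexes,
            "generation": gen_of,
        }
    )
    phi = kinship_matrix(fathers, mothers)
    return PedigreeSim(
        panels=panels,
        pedigree=pedigree,
        kept=kept,
        ancestry=ancestry_all,
        kinship=phi,
    )


# ---------------------------------------------------------------------------
# frozen merge/refine worked example


@dataclass(frozen=True)
class WorkedExampleFixture:
    """Frozen inputs for the merge/refine worked example (single hap pair).

    Six end groups of projection-run matches; one group has a single match
    and is discarded, the other five yield second-smallest-start fragments;
    three of those fragments mutually overlap.  One full-resolution exact
    match bridges the gap between the first two candidates and one lies
    strictly inside the merged candidate.  With c=2 and gmax=2 cM the
    pipeline produces 5 fragments → 3 candidates → 2 final segments.
    """

    low_matches: tuple[tuple[int, Match], ...]
    exact_full: tuple[Match, ...]
    params: RapidQueryParams
    site_bp: np.ndarray
    site_cm: np.ndarray
    hap: int = 7


def worked_example_fixture() -> WorkedExampleFixture:
    n = 2000
    site_cm = np.arange(n) * 0.01  # uniform 0.01 cM per site, 20 cM total
    site_bp = 1_000_000 + np.arange(n) * 1000
    hap = 7
    groups = {
        199: [0, 20, 40],
        399: [240, 260, 280],
        500: [300],
        1399: [1100, 1120],
        1429: [1110, 1130],
        1459: [1140, 1160],
    }
    low: list[tuple[int, Match]] = []
    for end, starts in groups.items():
        for run, start in enumerate(starts):
            low.append((run, Match(hap, start, end)))
    exact = (Match(hap, 10, 410), Match(hap, 1200, 1430))
    params = RapidQueryParams(
        l_final_cm=2.0, min_markers=1, refine_cm=0.5, c=2, gmax_cm=2.0
    )
    return WorkedExampleFixture(
        low_matches=tuple(low),
        exact_full=exact,
        params=params,
        site_bp=site_bp,
        site_cm=site_cm,
        hap=hap,
    )
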