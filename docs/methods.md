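# Methods

## Problem and model

An identity-by-descent (IBD) segment is a chromosomal interval two haplotypes
inherited from a recent common ancestor. On phased bi-allelic data an IBD
segment manifests as a long, *near*-exact match: genotyping error, gene
conversion and recent mutation scatter isolated mismatches through an
otherwise identical stretch. `rapidibd` searches one query haplotype against
a pre-indexed panel of `m` haplotypes over `n` sites and reports IBD segments
above a genetic-length cutoff while tolerating such mismatches.

The search has three layers:

1. **Exact long-match query (PBWT).** The panel is indexed with a positional
   Burrows–Wheeler transform: at each site boundary `k` the haplotypes are
   sorted by their reversed prefixes (prefix array `p[k]`), each sorted
   neighbour pair stores the start of its longest common suffix (divergence
   array `d[k]`), and cumulative allele counts `u[k]`/`v[k]` extend a sorted
   interval through the next site in O(1). The query is *virtually inserted*:
   a single left-to-right sweep maintains the query's insertion position in
   the sorted order plus its match start against the two sorted neighbours.
   All maximal matches of length ≥ L end where the panel haplotype's next
   allele breaks with the query; they occupy a contiguous block around the
   insertion point, walked outward only while the accumulated match start
   still satisfies the threshold. Cost is O(n + output) typically, O(nm)
   worst case. The length threshold may be a site count or a genetic length;
   for the latter a *site distance track index*
   `i(e) = max{ i ≤ e : cm[e] − cm[i] ≥ L }` provides the per-end admissible
   start bound and moves monotonically with the scanned end site.

2. **Random projection.** The `n` sites are split into ⌈n/w⌉ windows of `w`
   sites; each of `r` runs samples one site per window with probability
   proportional to its minor allele frequency (uniform when a window's MAFs
   are all zero), giving `r` low-resolution panels on which the exact query
   runs with a window-count threshold `l = round(L·density/w)`. A mismatch is
   skipped by a run whenever its sampled sites avoid the offending site
   (probability ≈ 1 − 1/w per error per window), so errors survive with high
   probability across runs while unrelated haplotypes rarely agree on `l`
   consecutive sampled sites.

3. **Merge and refine.** Rescaled run matches (low-resolution `[h', t']` maps
   to `[w·h', w·(t'+1)−1]`, clipped at the last site) are grouped by end
   position per panel haplotype; each group with at least `c` members yields
   one *fragmented IBD* at the c-th smallest start (it is therefore fully
   overlapped by ≥ c run matches); overlapping fragments merge into
   *candidate IBDs*; a full-resolution exact query at a short refine cutoff
   (0.5–2 cM) then fixes the boundaries: a candidate's surviving form is the
   union of the exact matches overlapping it, refined pieces separated by a
   genetic gap ≤ `gmax` are stitched, and final segments must reach the
   minimum genetic length and marker count. Everything happens in memory and
   is deterministic given the projection seed.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_cm` | 7 cM | minimum reported segment length (genealogical convention) |
| `min_markers` | 700 | minimum marker count (assumes ~100 sites/cM; scale with density) |
| `refine_cm` | 0.5 cM | cutoff of the full-resolution exact run; 0.5 suits sequencing density, 1–2 sparser arrays (smaller = fewer missed sites, larger = fewer over-extensions) |
| `r` / `c` | 10 / 2 | projection runs / runs that must support a fragment |
| `window` | auto | sites per projection window; auto = `min_cm·density / windows_per_cutoff` |
| `windows_per_cutoff` | 10 | windows spanned by a minimum-length segment under auto windowing |
| `gmax_cm` | 2 cM | maximum genetic gap stitched during refinement |
| `seed` | 0 | RNG stream of the projection scheme (runs use child streams, so growing `r` preserves earlier runs) |

Window choice trades power against noise: the probability that two unrelated
haplotypes survive an `l`-window low-resolution threshold is ≈ `p_agree^l`
per position and the expected spurious match load scales with `m`, so deep
panels want more, narrower windows per cutoff (the pedigree study below uses
20), while each error site then voids a larger fraction `1/w` of its window.

## Synthetic data

The generators emulate the study conditions the pipeline is evaluated under:

* **Panels** draw sites independently from a ~1/f MAF spectrum truncated at
  1% (matching a post-MAF-filter panel). Independence means background
  relatedness is exactly zero: long spurious matches are exponentially rare,
  which the false-positive analyses rely on. Real panels carry linkage
  disequilibrium and shared demography; passing tests here therefore bound
  error-model behaviour, not population-structure effects.
* **Planted IBD** copies a donor haplotype onto a recipient over a
  cM-defined interval (boundaries snapped to sites, the snapped interval is
  the recorded truth) on disjoint haplotype pairs, so each truth segment has
  an unambiguous pair.
* **Genotyping error** flips alleles independently (0.04% for
  sequencing-like, 0.13% for array-like panels); **phase error** swaps the
  two haplotypes of an individual at random sites (0.16% available as an
  option).
* **Pedigrees** are simulated forward in time: up to 500 non-overlapping
  couples per generation, each child's father replaced with probability 0.2
  by another male of the same generation, gametes recombining with
  Poisson(Lt/50) crossovers placed uniformly in cM on each chromosome of
  genetic length Lt. Founder ancestry is tracked exactly, so true IBD is
  available by construction and per-child IBD with its two parents tiles the
  chromosome. Degree labels come from exact pedigree kinship (tabular
  method) mapped through the standard kinship ranges (first degree
  (0.177, 0.354] halving per degree; ≤ 0.0221 unrelated), which stays
  correct for multi-path relationships the closed pedigree creates.

## Evaluation metrics

False negative rate: mean over true segments of the fraction of their sites
not covered by any reported segment of the same haplotype pair (end-inclusive
site granularity; an individual-level pairing option unions both phases).
False positive rate is the mirror image. Binned variants assign segments to
genetic-length bins (2–5, 5–7, 7–9, 9–12, 12–15, 15–18, ≥18 cM) by their own
length, with a length floor on the opposing set (reported ≥ 2 cM for FNR,
true ≥ 1.5 cM for FPR); empty bins report NaN rather than 0. Length fidelity
is the RMS difference in cM between each reported segment and the same-pair
true segment of maximal site overlap; a reported segment with no overlapping
truth contributes its full length (the pairing rule is this package's
choice). Degree separation uses the rank-statistic AUC of summed IBD length
(closer degree = positive class; ties count half).

## Benchmark study designs (problem sizes)

* **Planted-IBD accuracy**: 500 haplotypes × 20,000 sites on a 100 cM map
  (200 sites/cM), 200 planted segments uniform on 3–20 cM, genotyping error
  0.04%, search at refine 0.5 / r=10 / c=2 / 3 cM / 100 markers, every
  recipient queried with itself excluded. Reported: overall and binned
  FNR/FPR and RMS length discrepancy.
* **Pedigree degree separation**: 1000 founder individuals, 4 descendant
  generations of 1000, five 200 cM chromosomes at 20 sites/cM (≈1000 cM
  genome — several chromosomes keep per-pair segment-count variance
  representative), genotyping error 0.13%, search at refine 2.0 / 7 cM / 100
  markers / 20 windows per cutoff; 30 pairs sampled per degree class (1st,
  2nd, 3rd, 4th, unrelated), one member of each pair queried. Reported:
  per-degree mean totals and adjacent-degree AUCs.

## Numerical and design choices

* Internal site indices are 0-based; intervals are end-inclusive; bp output
  is 1-based as in VCF. Genetic maps interpolate linearly and extrapolate
  constantly outside their range (the interpolation rule between markers is
  this package's choice).
* `d[k][0] = k` sentinel (no predecessor); `v` is exposed as the exact
  complement `v[k][i] = i − u[k][i]` of the stored `u`.
* The end-grouping key includes the panel haplotype: the c-th-smallest-start
  rule is per (end, haplotype) group, otherwise unrelated haplotypes'
  matches would pool.
* A candidate overlapping no exact match at the refine cutoff is dropped
  (boundaries are defined only by exact matches); stitching applies after
  refinement between refined pieces of the same pair, measured as the
  genetic distance from one piece's end to the next piece's start, and does
  not distinguish pieces descending from one candidate or several.
* Low-resolution thresholds round `L/w` to the nearest integer; the last
  window may be shorter than `w` and rescaled tails clip to `n−1`.
* All-zero-MAF windows sample uniformly (MAF weighting is undefined there).
* Duplicate haplotypes in the panel are reported individually; duplicate
  matches across runs retain multiplicity toward `c` (one run contributes at
  most one match per (haplotype, end, start), which the exact query
  guarantees).
* Missing genotypes are unsupported: panels are assumed complete and phased.

## Known limitations

Single-chromosome panels per call; no BCF/indexed VCF support; no dynamic
panel updates (insertion/deletion); the synthetic panels carry no linkage
disequilibrium or demographic structure, so measured false-positive rates
describe the error model, not confounding by population structure; unphased
(genotype-level) matching is out of scope.
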