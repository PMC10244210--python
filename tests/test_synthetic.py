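"""Synthetic generators: panels, planted IBD, error models, pedigrees."""

import numpy as np
import pytest

from rapidibd.query import brute_force_long_matches
from rapidibd.synthetic import (
    PedigreeSpec,
    PlantSpec,
    add_genotyping_error,
    add_phasing_error,
    generate_panel,
    plant_ibd,
    simulate_pedigree,
    synthetic_map,
)
from rapidibd.types import LengthThreshold


class TestGeneratePanel:
    def test_deterministic_per_seed(self):
        a = generate_panel(10, 50, seed=3)
        b = generate_panel(10, 50, seed=3)
        assert np.array_equal(a.alleles, b.alleles)
        assert np.array_equal(a.site_cm, b.site_cm)

    def test_realized_frequency_tracks_target(self):
        panel = generate_panel(2000, 1, maf_sampler=0.5, seed=1)
        freq = panel.alleles.mean()
        sigma = np.sqrt(0.25 / 2000)
        assert abs(freq - 0.5) <= 3 * sigma

    def test_zero_frequency_all_zero(self):
        panel = generate_panel(5, 20, maf_sampler=0.0, seed=0)
        assert not panel.alleles.any()

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError):
            generate_panel(5, 5, maf_sampler=1.5, seed=0)

    def test_map_is_monotone(self):
        bp, cm, gmap = synthetic_map(500, 25.0, seed=9)
        assert np.all(np.diff(bp) > 0)
        assert np.all(np.diff(cm) >= 0)
        assert cm[-1] == pytest.approx(25.0)
        assert gmap.interpolate(int(bp[0])) == pytest.approx(cm[0])


class TestPlantIbd:
    def test_donor_recipient_identical_on_interval(self):
        panel = generate_panel(40, 2000, seed=2, span_cm=20.0)
        planted, truth = plant_ibd(panel, PlantSpec(5, min_cm=4.0, max_cm=8.0, seed=3))
        assert len(truth) == 5
        for tr in truth:
            r = planted.hap_ids.index(tr.query_hap)
            d = planted.hap_ids.index(tr.panel_hap)
            assert np.array_equal(
                planted.alleles[r, tr.start_site : tr.end_site + 1],
                planted.alleles[d, tr.start_site : tr.end_site + 1],
            )
            assert tr.cm_len >= 2.0

    def test_zero_segments_is_identity(self):
        panel = generate_panel(10, 200, seed=4, span_cm=10.0)
        planted, truth = plant_ibd(panel, PlantSpec(0, seed=0, max_cm=5.0))
        assert truth == []
        assert np.array_equal(planted.alleles, panel.alleles)

    def test_bruteforce_finds_planted_interval(self):
        panel = generate_panel(20, 1500, seed=5, span_cm=15.0)
        planted, truth = plant_ibd(panel, PlantSpec(1, min_cm=6.0, max_cm=6.0, seed=6))
        tr = truth[0]
        r = planted.hap_ids.index(tr.query_hap)
        d = planted.hap_ids.index(tr.panel_hap)
        matches = brute_force_long_matches(
            planted.alleles[[d]], planted.alleles[r], LengthThreshold("cM", tr.cm_len),
            site_cm=planted.site_cm,
        )
        assert any(
            mt.start <= tr.start_site and tr.end_site <= mt.end for mt in matches
        )

    def test_infeasible_length_rejected(self):
        panel = generate_panel(10, 100, seed=7, span_cm=5.0)
        with pytest.raises(ValueError):
            plant_ibd(panel, PlantSpec(1, min_cm=10.0, max_cm=10.0, seed=0))


class TestErrorModels:
    def test_zero_rate_identity(self):
        panel = generate_panel(10, 100, seed=8)
        assert add_genotyping_error(panel, 0.0) is panel

    def test_full_rate_complements(self):
        panel = generate_panel(10, 100, seed=9)
        flipped = add_genotyping_error(panel, 1.0, seed=1)
        assert np.array_equal(flipped.alleles, 1 - panel.alleles)

    def test_flip_count_within_three_sigma(self):
        panel = generate_panel(200, 5000, seed=10)
        rate = 0.0004
        out = add_genotyping_error(panel, rate, seed=2)
        flips = int((out.alleles != panel.alleles).sum())
        mean = panel.n_haps * panel.n_sites * rate
        assert abs(flips - mean) <= 3 * np.sqrt(mean)

    def test_phase_error_preserves_genotypes(self):
        panel = generate_panel(10, 500, seed=11)
        out = add_phasing_error(panel, 0.05, seed=3)
        for i in range(5):
            g_in = panel.alleles[2 * i] + panel.alleles[2 * i + 1]
            g_out = out.alleles[2 * i] + out.alleles[2 * i + 1]
            assert np.array_equal(g_in, g_out)
        assert (out.alleles != panel.alleles).any()


@pytest.fixture(scope="module")
def sim():
    founders = 40
    panels = [generate_panel(2 * founders, 800, seed=20 + i, span_cm=100.0)
              for i in range(2)]
    spec = PedigreeSpec(
        founders=founders, generations=3, pop_size=40, max_couples=20, seed=21
    )
    return simulate_pedigree(panels, spec)


class TestSimulatePedigree:

    def test_crossover_count_mean(self):
        # lambda = Lt/50: a 100 cM chromosome averages two crossovers
        rng = np.random.default_rng(6)
        draws = rng.poisson(100.0 / 50.0, size=10_000)
        assert abs(draws.mean() - 2.0) <= 3 * np.sqrt(2.0 / 10_000)

    def test_parent_offspring_ibd_tiles_chromosome(self, sim):
        child = sim.kept[-1]
        father = int(sim.pedigree.loc[child, "father"])
        panel = sim.panels[0]
        segs = sim.true_ibd(0, child, father, min_cm=0.0)
        paternal = sorted(
            (s.start_site, s.end_site)
            for s in segs
            if s.query_hap == f"i{child}_0"
        )
        covered = 0
        last_end = -1
        for s, e in paternal:
            assert s > last_end, "overlapping transmission runs"
            covered += e - s + 1
            last_end = e
        assert covered == panel.n_sites

    def test_transmitted_alleles_consistent_with_ancestry(self, sim):
        # every true IBD interval implies allele identity on that interval
        panel = sim.panels[1]
        pos = {hid: i for i, hid in enumerate(panel.hap_ids)}
        child = sim.kept[-1]  # last generation, parents are always extracted
        mother = int(sim.pedigree.loc[child, "mother"])
        assert mother in sim.kept
        for s in sim.true_ibd(1, child, mother, min_cm=0.0):
            a = panel.alleles[pos[s.query_hap], s.start_site : s.end_site + 1]
            b = panel.alleles[pos[s.panel_hap], s.start_site : s.end_site + 1]
            assert np.array_equal(a, b)

    def test_zero_generations_keeps_founders(self):
        founders = 6
        panels = [generate_panel(2 * founders, 100, seed=30, span_cm=10.0)]
        sim = simulate_pedigree(
            panels, PedigreeSpec(founders=founders, generations=0, seed=31)
        )
        assert sim.kept == list(range(founders))
        assert np.array_equal(sim.panels[0].alleles, panels[0].alleles)
        assert np.all(sim.kinship[np.triu_indices(founders, 1)] == 0)

    def test_labels_cover_expected_degrees(self, sim):
        labels = {sim.degree_label(a, b) for a in sim.kept[:20] for b in sim.kept[-20:]}
        assert "unrelated" in labels or "4" in labels
        assert any(d in labels for d in ("1", "2"))

    def test_deterministic_per_seed(self):
        founders = 10
        panels = [generate_panel(2 * founders, 200, seed=40, span_cm=50.0)]
        spec = PedigreeSpec(founders=founders, generations=2, pop_size=10, seed=41)
        a = simulate_pedigree(panels, spec)
        b = simulate_pedigree(panels, spec)
        assert np.array_equal(a.panels[0].alleles, b.panels[0].alleles)
        assert a.pedigree.equals(b.pedigree)
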