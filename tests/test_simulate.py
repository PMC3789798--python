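import json
import math

import numpy as np
import pytest

from linkmap.chromatin import cohesin_peak_width, compute_gga
from linkmap.distances import recombinant_fraction_array
from linkmap.io_formats import read_annotation, read_fitness_screens
from linkmap.pipeline import estimate_pair_distances
from linkmap.simulate import (
    SimConfig,
    Simulation,
    build_rate_map,
    pair_true_R,
    simulate_screens,
    simulate_tracks,
    write_simulation,
    yeast_like_genome,
)


class TestRateMap:
    def test_constant_without_features(self):
        cfg = SimConfig(genome=[(300_000, 150_000)], base_rate=1.5)
        rm = build_rate_map(cfg)["chr01"]
        assert np.all(rm.rate == 1.5)
        assert rm.total_cm == pytest.approx(1.5 * 300.0)

    def test_hotspot_fold_applied(self):
        cfg = SimConfig(
            genome=[(300_000, 150_000)], base_rate=1.0,
            hotspots={"chr01": [(50_000, 3.0, 4000)]},
        )
        rm = build_rate_map(cfg)["chr01"]
        assert float(rm.rate_at(50_000)) == pytest.approx(3.0)
        assert float(rm.rate_at(200_000)) == pytest.approx(1.0)

    def test_overlapping_hotspots_merge_by_max(self):
        cfg = SimConfig(
            genome=[(300_000, 150_000)], base_rate=1.0,
            hotspots={"chr01": [(50_000, 3.0, 10_000), (52_000, 5.0, 10_000)]},
        )
        rm = build_rate_map(cfg)["chr01"]
        assert float(rm.rate_at(51_000)) == pytest.approx(5.0)

    def test_size_coupled_suppression_radii(self):
        cfg = SimConfig(
            genome=[(300_000, 150_000), (900_000, 200_000)],
            pericentric_radius_kb=10.0, size_coupling_kb_per_mb=10.0,
            pericentric_residual=0.0,
        )
        sim = Simulation(cfg)
        assert sim.truth.pericentric_radius_kb["chr01"] == pytest.approx(13.0)
        assert sim.truth.pericentric_radius_kb["chr02"] == pytest.approx(19.0)
        rm = sim.rate_maps["chr01"]
        assert float(rm.rate_at(150_000)) == 0.0
        assert float(rm.rate_at(150_000 + 14_000)) > 0.0


class TestPairTrueR:
    def test_zero_distance(self):
        rm = build_rate_map(SimConfig(genome=[(300_000, 150_000)]))["chr01"]
        assert pair_true_R(rm, 50_000, 50_000) == 0.0

    def test_fifty_cm_gives_poisson_value(self):
        cfg = SimConfig(genome=[(300_000, 150_000)], base_rate=1.0)
        rm = build_rate_map(cfg)["chr01"]
        # 50 kb at 1 cM/kb = 50 cM -> m = 1
        assert pair_true_R(rm, 100_000, 150_000) == pytest.approx(
            0.5 * (1 - math.exp(-1)), abs=1e-9
        )

    def test_asymptote_half(self):
        cfg = SimConfig(genome=[(1_500_000, 750_000)], base_rate=2.0)
        rm = build_rate_map(cfg)["chr01"]
        assert pair_true_R(rm, 1000, 1_400_000) == pytest.approx(0.5, abs=1e-9)

    def test_truth_invariant_R_from_m(self):
        sim = Simulation(SimConfig(seed=3, genome=[(400_000, 150_000)], n_genes_per_chromosome=25))
        cm = sim.truth.true_cm["chr01"]
        R = sim.truth.true_R["chr01"]
        np.testing.assert_allclose(R, 0.5 * (1 - np.exp(-cm / 50.0)), atol=1e-14)


class TestSimulateScreens:
    def test_noise_free_inversion_exact(self):
        cfg = SimConfig(seed=5, genome=[(400_000, 150_000)], n_genes_per_chromosome=30, noise_sd=0.0)
        screens, truth = simulate_screens(cfg)
        table = screens["chr01"]
        R = recombinant_fraction_array(
            table.f_query[:, None], table.f_array[None, :], table.f_double
        )
        np.testing.assert_allclose(R, truth.true_R["chr01"], atol=1e-12)

    def test_unlinked_pair_maps_to_cap(self):
        cfg = SimConfig(
            seed=5, genome=[(1_500_000, 750_000)], n_genes_per_chromosome=30,
            noise_sd=0.0, base_rate=1.43,
        )
        screens, truth = simulate_screens(cfg)
        pairs = estimate_pair_distances(screens)["chr01"]
        ids = truth.gene_ids["chr01"]
        far = [p for p in pairs if p.query_id == ids[0] and p.array_id == ids[-1]]
        assert far[0].sga_gd == 50.0

    def test_determinism(self):
        cfg = SimConfig(seed=9, genome=[(300_000, 150_000)], n_genes_per_chromosome=10, noise_sd=0.1)
        a = simulate_screens(cfg)[0]["chr01"]
        b = simulate_screens(cfg)[0]["chr01"]
        np.testing.assert_array_equal(a.f_double, b.f_double)
        np.testing.assert_array_equal(a.f_query, b.f_query)
        assert a.query_ids == b.query_ids

    def test_different_seeds_differ(self):
        base = dict(genome=[(300_000, 150_000)], n_genes_per_chromosome=10, noise_sd=0.1)
        a = simulate_screens(SimConfig(seed=1, **base))[0]["chr01"]
        b = simulate_screens(SimConfig(seed=2, **base))[0]["chr01"]
        assert not np.array_equal(a.f_double, b.f_double)

    def test_replicates_are_duplicate_rows(self):
        cfg = SimConfig(
            seed=1, genome=[(300_000, 150_000)], n_genes_per_chromosome=6,
            replicate_count=3, noise_sd=0.1,
        )
        table = simulate_screens(cfg)[0]["chr01"]
        assert len(table.query_ids) == 18
        assert table.query_ids[0] == table.query_ids[1] == table.query_ids[2]
        # replicate rows carry independent noise
        assert not np.array_equal(table.f_double[0], table.f_double[1])

    def test_residual_colony_in_self_cell(self):
        cfg = SimConfig(
            seed=1, genome=[(300_000, 150_000)], n_genes_per_chromosome=6,
            noise_sd=0.0, residual_colony=0.07,
        )
        table = simulate_screens(cfg)[0]["chr01"]
        for i, qid in enumerate(table.query_ids):
            j = table.array_ids.index(qid)
            assert table.f_double[i, j] == pytest.approx(0.07)


class TestSimulateTracks:
    def test_full_suppression_zeroes_pericentric_spo11(self):
        cfg = SimConfig(
            seed=2, genome=[(400_000, 200_000)], n_genes_per_chromosome=5,
            pericentric_radius_kb=20.0, pericentric_residual=0.0,
        )
        tracks, truth = simulate_tracks(cfg)
        t = tracks["spo11"]["chr01"]
        inside = np.abs(t.positions - 200_000) <= 19_000
        assert t.values[inside].sum() == 0.0

    def test_rec8_width_closed_loop(self):
        cfg = SimConfig(
            seed=2, genome=[(500_000, 250_000)], n_genes_per_chromosome=5,
            rec8_width0_kb=40.0,
        )
        sim = Simulation(cfg)
        tracks = sim.tracks()
        t = tracks["rec8"]["chr01"]
        gga = compute_gga([t], 25)
        width = cohesin_peak_width(t, 250_000, gga, 25).width_kb
        assert abs(width - 40.0) <= 25.0

    def test_genetic_map_matches_rate_integral(self):
        cfg = SimConfig(seed=2, genome=[(400_000, 200_000)], n_genes_per_chromosome=8, base_rate=1.1)
        sim = Simulation(cfg)
        tracks = sim.tracks()
        rm = sim.rate_maps["chr01"]
        assert float(rm.cm_at(400_000)) == pytest.approx(rm.total_cm)
        for site in tracks["genetic_map"]:
            assert site.score == pytest.approx(float(rm.cm_at(site.position)))

    def test_hotspot_sitelist_matches_plan(self):
        cfg = SimConfig(
            seed=6, genome=[(600_000, 250_000)], n_genes_per_chromosome=5,
            hotspots_per_chromosome=4, hotspot_min_separation_bp=30_000,
        )
        sim = Simulation(cfg)
        positions = sorted(s.position for s in sim.truth.hotspots)
        assert len(positions) == 4
        assert all(b - a >= 30_000 for a, b in zip(positions, positions[1:]))


class TestWriteSimulation:
    def test_fixture_round_trip(self, tmp_path):
        cfg = SimConfig(
            seed=4, genome=[(300_000, 150_000), (500_000, 250_000)],
            n_genes_per_chromosome=8, noise_sd=0.05, replicate_count=2,
            hotspots_per_chromosome=2,
        )
        sim = Simulation(cfg)
        write_simulation(sim, tmp_path)
        ann = read_annotation(tmp_path / "annotation.tsv")
        assert ann.chromosome_names == ["chr01", "chr02"]
        table = read_fitness_screens(tmp_path / "screens" / "chr01", chromosome="chr01")
        orig = sim.screens()["chr01"]
        np.testing.assert_allclose(table.f_double, orig.f_double)
        np.testing.assert_allclose(table.f_query, orig.f_query)
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["seed"] == 4
        assert set(truth["true_R"]) == {"chr01", "chr02"}
        assert (tmp_path / "hotspots.bed").exists()
        assert (tmp_path / "tracks" / "spo11_chr01.tsv").exists()
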