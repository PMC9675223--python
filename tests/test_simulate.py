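"""Population simulator: meiosis model, generation schemes, masks, metrics."""

import numpy as np
import pytest

from seriamap import (
    GeneticMap,
    LinkageGroup,
    MapEntry,
    SimulationConfig,
    evaluate_map,
    expected_joint_freqs,
    simulate_pop,
)
from seriamap.models import haldane_d_to_r
from seriamap.simulate import _gametes
from seriamap.types import MISSING, PopulationType


class TestMeiosisModel:
    def test_marker_grid_convention(self):
        sim = simulate_pop(
            SimulationConfig(
                population="BC", n_individuals=2, chrom_lengths_cM=(100.0, 200.0)
            )
        )
        assert sim.dataset.n_markers == 101 + 201
        assert [g.length for g in sim.truth_map.groups] == [100.0, 200.0]

    def test_mean_crossovers_poisson(self):
        """100 cM chromosome: 1.0 +/- 0.05 crossovers per gamete."""
        rng = np.random.default_rng(0)
        positions = np.linspace(0, 100, 101)
        g = _gametes(positions, 10_000, rng)
        switches = (np.diff(g, axis=1) != 0).sum(axis=1)
        # switches undercount crossovers (multiple per interval collapse);
        # at 1 cM spacing the correction is negligible
        assert switches.mean() == pytest.approx(1.0, abs=0.05)

    def test_adjacent_recombination_matches_haldane(self):
        """BC, 1 cM spacing, n = 10,000: recombinant fraction ~ 0.00990."""
        sim = simulate_pop(
            SimulationConfig(
                population="BC",
                n_individuals=10_000,
                chrom_lengths_cM=(1.0,),
                marker_spacing_cM=1.0,
                seed=2,
            )
        )
        g = sim.dataset.genotypes
        rec = (g[0] != g[1]).mean()
        assert rec == pytest.approx(float(haldane_d_to_r(1.0)), abs=0.001)


class TestMasksAndDeterminism:
    def test_same_seed_bitwise_identical(self):
        cfg = dict(
            population="CP",
            n_individuals=40,
            chrom_lengths_cM=(30.0,),
            marker_spacing_cM=3.0,
            error_rate=0.05,
            missing_rate=0.1,
            seed=123,
        )
        a = simulate_pop(SimulationConfig(**cfg))
        b = simulate_pop(SimulationConfig(**cfg))
        assert np.array_equal(a.dataset.genotypes, b.dataset.genotypes)
        assert np.array_equal(a.error_mask, b.error_mask)
        assert np.array_equal(a.missing_mask, b.missing_mask)
        assert np.array_equal(a.truth_phases, b.truth_phases)

    def test_masks_disjoint_and_consistent(self):
        sim = simulate_pop(
            SimulationConfig(
                population="F2",
                n_individuals=60,
                chrom_lengths_cM=(40.0,),
                marker_spacing_cM=2.0,
                error_rate=0.1,
                missing_rate=0.15,
                seed=4,
            )
        )
        assert not np.any(sim.error_mask & sim.missing_mask)
        assert np.all(sim.dataset.genotypes[sim.missing_mask] == MISSING)
        assert np.all(sim.dataset.genotypes[sim.error_mask] != MISSING)

    def test_zero_rates_clean_dataset(self):
        sim = simulate_pop(
            SimulationConfig(
                population="F2",
                n_individuals=30,
                chrom_lengths_cM=(20.0,),
                marker_spacing_cM=5.0,
                seed=5,
            )
        )
        assert not sim.error_mask.any()
        assert not sim.missing_mask.any()
        assert not (sim.dataset.genotypes == MISSING).any()


POPS = [
    ("BC", 50_000),
    ("F2", 50_000),
    ("RIL", 6_000),  # lineage simulation is per-individual; smaller n, wider SE
    ("IRIL3", 4_000),
]


class TestGenerationSchemes:
    @pytest.mark.parametrize("pop,n", POPS, ids=[p for p, _ in POPS])
    def test_empirical_two_locus_freqs_match_model(self, pop, n):
        """Empirical class frequencies agree with the expected tables (3 SE)."""
        d = 10.0
        sim = simulate_pop(
            SimulationConfig(
                population=pop,
                n_individuals=n,
                chrom_lengths_cM=(d,),
                marker_spacing_cM=d,
                seed=6,
            )
        )
        r = float(haldane_d_to_r(d))
        freqs = expected_joint_freqs(sim.dataset.population, r)
        g = sim.dataset.genotypes
        code = {0: "A", 1: "H", 2: "B"}
        for (c1, c2), p in freqs.items():
            inv1 = [k for k, v in code.items() if v == c1][0]
            inv2 = [k for k, v in code.items() if v == c2][0]
            obs = float(((g[0] == inv1) & (g[1] == inv2)).mean())
            se = max(np.sqrt(p * (1 - p) / n), 1e-4)
            assert obs == pytest.approx(p, abs=3.5 * se), (c1, c2)

    def test_cp_offspring_respect_parental_classes(self):
        sim = simulate_pop(
            SimulationConfig(
                population="CP",
                n_individuals=100,
                chrom_lengths_cM=(30.0,),
                marker_spacing_cM=3.0,
                seed=7,
            )
        )
        ds = sim.dataset
        for m in range(ds.n_markers):
            k = len(ds.cp_info[m].classes)
            col = ds.genotypes[m]
            assert np.all((col >= 0) & (col < k))

    def test_cp_empirical_freqs_match_model(self):
        """CP both-informative pair: empirical vs expected classes (3 SE)."""
        d = 10.0
        sim = simulate_pop(
            SimulationConfig(
                population="CP",
                n_individuals=50_000,
                chrom_lengths_cM=(d,),
                marker_spacing_cM=d,
                cp_class_probs={"abxcd": 1.0},
                seed=8,
            )
        )
        ds = sim.dataset
        r = float(haldane_d_to_r(d))
        phases = tuple(int(p) for p in sim.truth_phases[0] ^ sim.truth_phases[1])
        freqs = expected_joint_freqs(
            PopulationType("CP"),
            r,
            cp_pair=(ds.cp_info[0], ds.cp_info[1]),
            phases=phases,
        )
        g = ds.genotypes
        for (c1, c2), p in freqs.items():
            i1 = ds.cp_info[0].class_index(c1)
            i2 = ds.cp_info[1].class_index(c2)
            obs = float(((g[0] == i1) & (g[1] == i2)).mean())
            se = max(np.sqrt(p * (1 - p) / 50_000), 1e-4)
            assert obs == pytest.approx(p, abs=3.5 * se), (c1, c2)


class TestErrorRateModels:
    def test_uniform_rate_realized(self):
        sim = simulate_pop(
            SimulationConfig(
                population="BC",
                n_individuals=500,
                chrom_lengths_cM=(50.0,),
                marker_spacing_cM=1.0,
                error_rate=0.05,
                seed=9,
            )
        )
        assert sim.error_mask.mean() == pytest.approx(0.05, abs=0.005)

    def test_gamma_marker_rates_spread_then_concentrate(self):
        """Large Gamma shape converges to the uniform-rate model."""

        def marker_rate_std(shape, seed):
            sim = simulate_pop(
                SimulationConfig(
                    population="BC",
                    n_individuals=400,
                    chrom_lengths_cM=(50.0,),
                    marker_spacing_cM=1.0,
                    error_rate=0.05,
                    error_distribution="gamma_marker",
                    gamma_shape=shape,
                    seed=seed,
                )
            )
            return sim.error_mask.mean(axis=1).std(), sim.error_mask.mean()

        std_l, mean_l = marker_rate_std(0.5, 10)  # L-shaped
        std_u, mean_u = marker_rate_std(400.0, 10)  # near-uniform
        assert mean_l == pytest.approx(0.05, abs=0.012)
        assert mean_u == pytest.approx(0.05, abs=0.006)
        assert std_l > 2 * std_u


class TestEvaluateMap:
    def _truth(self):
        return GeneticMap(
            [
                LinkageGroup(
                    "chr1",
                    [MapEntry(f"m{k}", float(10 * k), "framework") for k in range(11)],
                )
            ]
        )

    def test_identity_scores_perfect(self):
        truth = self._truth()
        rep = evaluate_map(truth, truth)
        assert rep.min_spearman == pytest.approx(1.0)
        assert rep.length_ratio == pytest.approx(1.0)
        assert rep.inclusion_rate == pytest.approx(1.0)

    def test_reversed_orientation_free(self):
        truth = self._truth()
        rev = GeneticMap(
            [
                LinkageGroup(
                    "LG1",
                    [
                        MapEntry(f"m{10 - k}", float(10 * k), "framework")
                        for k in range(11)
                    ],
                )
            ]
        )
        rep = evaluate_map(rev, truth)
        assert rep.min_spearman == pytest.approx(1.0)

    def test_missing_terminal_segment_span_vs_full(self):
        """Dropping a terminal 10% leaves covered ratio 1, full ratio 0.9."""
        truth = self._truth()
        partial = GeneticMap(
            [
                LinkageGroup(
                    "LG1",
                    [MapEntry(f"m{k}", float(10 * k), "framework") for k in range(10)],
                )
            ]
        )
        rep = evaluate_map(partial, truth)
        assert rep.length_ratio == pytest.approx(1.0)
        assert rep.length_ratio_full == pytest.approx(0.9)

    def test_no_shared_markers_sentinel(self):
        truth = self._truth()
        alien = GeneticMap(
            [LinkageGroup("LG1", [MapEntry("x", 0.0, "framework"), MapEntry("y", 5.0, "framework")])]
        )
        rep = evaluate_map(alien, truth)
        assert np.isnan(rep.length_ratio)
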