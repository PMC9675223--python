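"""Multipoint HMM: likelihoods, EM fitting, imputation, phase inference."""

import numpy as np
import pytest
from dataclasses import replace

from seriamap import (
    MultipointModel,
    em_fit_intervals,
    estimate_two_point,
    impute_posteriors,
    infer_phase_on_extension,
    multipoint_loglik,
)
from seriamap.models import _compact_inbred_codes, _inbred_pair_table, _pair_counts, _pair_loglik
from seriamap.multipoint import (
    FittedChain,
    _forward_backward,
    estimate_error_rate,
)
from seriamap.types import PopulationType

from .conftest import (
    hmm_loglik_bruteforce,
    make_cp_dataset,
    make_inbred_dataset,
    posterior_bruteforce,
)


def _cp_model(ds, idx, r, eps=0.01, phases=None):
    if phases is None:
        phases = np.zeros((len(idx), 2), dtype=np.int8)
        for k, m in enumerate(idx):
            info = ds.cp_info[m]
            phases[k] = (0 if info.het1 else -1, 0 if info.het2 else -1)
    return MultipointModel(ds.population, idx, np.asarray(r, float), epsilon=eps, phases=phases)


class TestMultipointLoglik:
    def test_two_marker_reduction_to_two_point(self, f2_small_sim):
        """With eps = 0, the 2-locus chain likelihood equals the 2-point one."""
        ds = f2_small_sim.dataset
        r = 0.08
        mdl = MultipointModel(ds.population, [0, 2], np.array([r]), epsilon=0.0)
        ll = multipoint_loglik(mdl, ds)
        G, nc = _compact_inbred_codes(ds)
        N, M, _ = _inbred_pair_table("F2")
        counts = _pair_counts(G[0], G[2], nc)
        ll2 = _pair_loglik(counts[None, :], N, M, np.array([r]))[0] / np.log(10)
        const = counts.sum() * np.log10(0.25)  # per-individual gamete normalization
        assert ll == pytest.approx(ll2 + const, abs=1e-9)

    @pytest.mark.parametrize("kind", ["BC", "F2", "RIL"])
    def test_matches_exhaustive_enumeration_inbred(self, kind):
        codes = {
            "BC": ["ABAB", "AAB-", "BBAA"],
            "F2": ["AHBC", "H-AB", "DHBA"],
            "RIL": ["ABAB", "AHB-", "BBAA"],
        }[kind]
        ds = make_inbred_dataset(kind, codes)
        mdl = MultipointModel(ds.population, [0, 1, 2], np.array([0.1, 0.25]), epsilon=0.02)
        assert multipoint_loglik(mdl, ds) == pytest.approx(
            hmm_loglik_bruteforce(mdl, ds), abs=1e-10
        )

    def test_matches_exhaustive_enumeration_cp(self):
        ds = make_cp_dataset(
            [("ab", "aa"), ("ab", "ab"), ("ab", "cd")],
            [
                ["aa", "ab", "aa", "--", "ab"],
                ["aa", "ab", "bb", "ab", "aa"],
                ["ac", "bd", "ad", "bc", "ac"],
            ],
        )
        mdl = _cp_model(ds, [0, 1, 2], [0.15, 0.08], eps=0.03)
        assert multipoint_loglik(mdl, ds) == pytest.approx(
            hmm_loglik_bruteforce(mdl, ds), abs=1e-10
        )

    def test_all_missing_marker_is_uninformative(self):
        """A silent locus leaves the likelihood a function of total distance only."""
        ds = make_inbred_dataset("BC", ["ABAB", "----", "BBAA"])
        from seriamap.models import haldane_d_to_r, haldane_r_to_d

        base = MultipointModel(ds.population, [0, 1, 2], np.array([0.1, 0.2]), epsilon=0.0)
        d = haldane_r_to_d(0.1) + haldane_r_to_d(0.2)
        ll1 = multipoint_loglik(base, ds)
        r_a = haldane_d_to_r(d * 0.3)
        r_b = haldane_d_to_r(d * 0.7)
        alt = MultipointModel(ds.population, [0, 1, 2], np.array([r_a, r_b]), epsilon=0.0)
        assert multipoint_loglik(alt, ds) == pytest.approx(ll1, abs=1e-12)

    def test_forward_backward_consistency(self, f2_small_sim):
        ds = f2_small_sim.dataset
        mdl = MultipointModel(ds.population, list(range(6)), np.full(5, 0.05))
        fb = _forward_backward(mdl, ds)
        assert fb.loglik10 == pytest.approx(multipoint_loglik(mdl, ds), abs=1e-10)
        gamma = fb.gamma
        sums = gamma.sum(axis=2)
        assert np.allclose(sums, 1.0, atol=1e-10)

    @pytest.mark.parametrize("pop", ["BC", "F2", "RIL", "CP"])
    def test_reversal_invariance(self, pop):
        """Reversing marker order and intervals leaves the likelihood unchanged."""
        if pop == "CP":
            ds = make_cp_dataset(
                [("ab", "ab"), ("ab", "aa"), ("ab", "cd")],
                [["aa", "ab", "bb", "ab"], ["aa", "ab", "aa", "ab"], ["ac", "bd", "ad", "bc"]],
            )
            mdl = _cp_model(ds, [0, 1, 2], [0.12, 0.3], eps=0.02)
        else:
            ds = make_inbred_dataset(pop, ["ABAB", "A-BB", "BABA"])
            mdl = MultipointModel(
                ds.population, [0, 1, 2], np.array([0.12, 0.3]), epsilon=0.02
            )
        assert multipoint_loglik(mdl.reversed(), ds) == pytest.approx(
            multipoint_loglik(mdl, ds), abs=1e-10
        )

    def test_error_model_absorbs_singleton(self):
        """A lone discordant call is likelier under eps > 0 than eps = 0."""
        ds = make_inbred_dataset("BC", ["A" * 10, "A" * 5 + "B" + "A" * 4, "A" * 10])
        tight = np.array([0.01, 0.01])
        with_err = MultipointModel(ds.population, [0, 1, 2], tight, epsilon=0.01)
        without = MultipointModel(ds.population, [0, 1, 2], tight, epsilon=0.0)
        assert multipoint_loglik(with_err, ds) > multipoint_loglik(without, ds)


class TestEmFitIntervals:
    def test_complete_bc_data_equals_count_estimates(self, bc_chrom_sim):
        ds = bc_chrom_sim.dataset
        idx = list(range(0, 50, 10))
        mdl = MultipointModel(ds.population, idx, np.full(len(idx) - 1, 0.2), epsilon=0.0)
        r, ll, conv = em_fit_intervals(mdl, ds)
        assert conv
        for k in range(len(idx) - 1):
            direct = estimate_two_point(ds, idx[k], idx[k + 1]).r_hat
            assert r[k] == pytest.approx(direct, abs=1e-6)

    def test_loglik_non_decreasing_and_final_ge_initial(self, f2_small_sim):
        ds = f2_small_sim.dataset
        mdl = MultipointModel(ds.population, list(range(0, 30, 5)), np.full(5, 0.3))
        ll0 = multipoint_loglik(mdl, ds)
        r, ll, _ = em_fit_intervals(mdl, ds)
        assert ll >= ll0 - 1e-9

    def test_missing_data_parameter_recovery(self):
        """Adjacent r = 0.05, 20% missing: mean r-hat within 0.015 of truth."""
        from seriamap import SimulationConfig, simulate_pop
        from seriamap.models import haldane_r_to_d

        d = float(haldane_r_to_d(0.05))
        errs = []
        for rep in range(20):
            sim = simulate_pop(
                SimulationConfig(
                    population="F2",
                    n_individuals=200,
                    chrom_lengths_cM=(4 * d,),
                    marker_spacing_cM=d,
                    missing_rate=0.2,
                    seed=100 + rep,
                )
            )
            ds = sim.dataset
            mdl = MultipointModel(ds.population, list(range(5)), np.full(4, 0.1))
            r, _, _ = em_fit_intervals(mdl, ds)
            errs.append(r.mean() - 0.05)
        assert abs(np.mean(errs)) < 0.015

    def test_ril_transition_on_big_R_scale(self):
        """Fitted RIL intervals return r, not the inflated observed R."""
        from seriamap import SimulationConfig, simulate_pop

        sim = simulate_pop(
            SimulationConfig(
                population="RIL",
                n_individuals=300,
                chrom_lengths_cM=(20.0,),
                marker_spacing_cM=10.0,
                seed=9,
            )
        )
        ds = sim.dataset
        mdl = MultipointModel(ds.population, [0, 1, 2], np.full(2, 0.2))
        r, _, _ = em_fit_intervals(mdl, ds)
        # truth r for 10 cM is 0.0906; observed R would be ~0.153
        assert np.all(r < 0.14)
        assert r.mean() == pytest.approx(0.0906, abs=0.04)


class TestImputePosteriors:
    def test_unambiguous_call_posterior_one(self):
        ds = make_inbred_dataset("BC", ["AB", "AB"])
        mdl = MultipointModel(ds.population, [0, 1], np.array([0.1]), epsilon=0.0)
        post = impute_posteriors(mdl, ds)
        assert post.probs[0, 0, 0] == pytest.approx(1.0)
        assert post.probs[0, 1, 1] == pytest.approx(1.0)

    def test_missing_call_forced_by_tight_flanks(self):
        ds = make_inbred_dataset("BC", ["AB", "--", "AB"])
        mdl = MultipointModel(
            ds.population, [0, 1, 2], np.array([1e-6, 1e-6]), epsilon=0.0
        )
        post = impute_posteriors(mdl, ds)
        assert post.probs[1, 0, 0] == pytest.approx(1.0, abs=1e-4)
        assert post.argmax()[1, 1] == 1

    def test_matches_bruteforce_conditional_enumeration(self):
        ds = make_inbred_dataset("BC", ["AB-A", "-BAA", "ABB-"])
        mdl = MultipointModel(ds.population, [0, 1, 2], np.array([0.15, 0.3]), epsilon=0.02)
        post = impute_posteriors(mdl, ds)
        brute = posterior_bruteforce(mdl, ds)
        assert np.allclose(post.probs, brute, atol=1e-10)


class TestPhaseInference:
    def test_one_parent_marker_has_two_variants(self):
        ds = make_cp_dataset(
            [("ab", "ab"), ("ab", "ab"), ("ab", "aa")],
            [["aa", "ab", "bb", "ab"], ["aa", "ab", "bb", "ab"], ["aa", "ab", "aa", "ab"]],
        )
        mdl = _cp_model(ds, [0, 1], [0.1])
        from seriamap.multipoint import candidate_emissions

        Ecs, phases = candidate_emissions(mdl, ds, 2)
        assert len(Ecs) == 2  # only the female side carries a phase bit

    def test_phase_advantage_non_negative(self):
        ds3 = make_cp_dataset(
            [("ab", "aa"), ("ab", "aa"), ("ab", "aa")],
            [["aa", "ab"] * 10, ["aa", "ab"] * 10, ["ab", "aa"] * 10],
        )
        mdl = _cp_model(ds3, [0, 1], [0.05])
        phase, advantage, _ = infer_phase_on_extension(mdl, ds3, 2, r_link=0.05)
        assert advantage >= 0.0
        assert phase[0] == 1  # repulsion relative to the reference marker

    def test_uninformative_marker_rejected(self):
        ds = make_cp_dataset(
            [("ab", "aa"), ("ab", "aa"), ("aa", "aa")],
            [["aa", "ab"] * 5, ["ab", "aa"] * 5, ["aa", "aa"] * 5],
        )
        mdl = _cp_model(ds, [0, 1], [0.1])
        with pytest.raises(ValueError, match="uninformative"):
            infer_phase_on_extension(mdl, ds, 2)

    def test_simulated_phase_recovery_rate(self):
        """Known-phase CP markers recovered >= 95% at r = 0.1 to the map end.

        The chain mixes marker informativeness classes (the generator's
        default), which anchors both parental homolog labelings; only
        phase bits identifiable from the chain are scored (a parent
        never heterozygous along the chain leaves no reference).
        """
        from seriamap import SimulationConfig, simulate_pop
        from seriamap.models import haldane_r_to_d

        d = float(haldane_r_to_d(0.1))
        hits = total = 0
        for rep in range(50):
            sim = simulate_pop(
                SimulationConfig(
                    population="CP",
                    n_individuals=200,
                    chrom_lengths_cM=(5 * d,),
                    marker_spacing_cM=d,
                    seed=3000 + rep,
                )
            )
            ds = sim.dataset
            truth = sim.truth_phases
            cand = 5
            anchored = [
                p
                for p in range(2)
                if truth[cand][p] >= 0 and any(truth[k][p] >= 0 for k in range(5))
            ]
            if not anchored:
                continue
            mdl = _cp_model(ds, list(range(5)), np.full(4, 0.1), phases=truth[:5].copy())
            phase, _, _ = infer_phase_on_extension(mdl, ds, cand, r_link=0.1)
            hits += int(all(phase[p] == truth[cand][p] for p in anchored))
            total += 1
        assert total >= 40
        assert hits / total >= 0.95


class TestFittedChainScan:
    def test_scan_gap_positive_for_clear_insertion(self, bc_chrom_sim):
        ds = bc_chrom_sim.dataset
        idx = [0, 10, 20, 30, 40]
        mdl = MultipointModel(ds.population, idx, np.full(4, 0.09), epsilon=0.001)
        chain = FittedChain(mdl, ds)
        scan = chain.scan_marker(15)  # true position: middle of interval 1
        kind, k = scan.positions[scan.best()]
        assert (kind, k) == ("interval", 1)
        assert scan.gap() > 3.0

    def test_scan_end_extension_detected(self, bc_chrom_sim):
        ds = bc_chrom_sim.dataset
        idx = [0, 10, 20, 30]
        mdl = MultipointModel(ds.population, idx, np.full(3, 0.09), epsilon=0.001)
        chain = FittedChain(mdl, ds)
        scan = chain.scan_marker(45)
        kind, _ = scan.positions[scan.best()]
        assert kind == "end"
        assert scan.detail[scan.best()] == pytest.approx(15.0, abs=4.0)


class TestErrorRateEstimation:
    @pytest.mark.parametrize("true_eps", [0.0, 0.05])
    def test_recovers_simulated_rate(self, true_eps):
        from seriamap import SimulationConfig, simulate_pop

        sim = simulate_pop(
            SimulationConfig(
                population="BC",
                n_individuals=200,
                chrom_lengths_cM=(40.0,),
                marker_spacing_cM=2.0,
                error_rate=true_eps,
                seed=5,
            )
        )
        ds = sim.dataset
        mdl = MultipointModel(ds.population, list(range(21)), np.full(20, 0.02))
        eps, _ = estimate_error_rate(mdl, ds)
        assert eps == pytest.approx(true_eps, abs=0.012)
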