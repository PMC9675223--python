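"""Mapping functions, joint frequencies, RIL transforms, 2-point EM."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seriamap import (
    estimate_two_point,
    expected_joint_freqs,
    haldane_d_to_r,
    haldane_r_to_d,
    kosambi_d_to_r,
    kosambi_r_to_d,
    ril_observed_R,
    two_point_matrix,
)
from seriamap.models import (
    _compact_inbred_codes,
    _inbred_pair_table,
    _pair_counts,
    _pair_loglik,
    ril_transform,
)
from seriamap.types import PopulationType

from .conftest import (
    f2_joint_freqs_bruteforce,
    grid_ml_two_point,
    make_cp_dataset,
    make_inbred_dataset,
)


class TestMappingFunctions:
    def test_haldane_closed_form_values(self):
        assert haldane_r_to_d(0.0) == 0.0
        assert haldane_r_to_d(0.25) == pytest.approx(-50 * np.log(0.5), abs=1e-9)
        assert haldane_d_to_r(100.0) == pytest.approx((1 - np.exp(-2)) / 2, abs=1e-9)

    def test_unlinked_r_is_infinite_distance(self):
        with pytest.warns(UserWarning):
            assert np.isinf(haldane_r_to_d(0.5))

    @given(st.floats(0.0, 0.49))
    @settings(max_examples=50, deadline=None)
    def test_haldane_mutually_inverse(self, r):
        assert haldane_d_to_r(haldane_r_to_d(r)) == pytest.approx(r, abs=1e-12)

    @given(st.floats(0.0, 0.49))
    @settings(max_examples=50, deadline=None)
    def test_kosambi_mutually_inverse(self, r):
        assert kosambi_d_to_r(kosambi_r_to_d(r)) == pytest.approx(r, abs=1e-12)

    def test_kosambi_shorter_than_haldane(self):
        assert kosambi_r_to_d(0.2) < haldane_r_to_d(0.2)


R_GRID = [0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5]


class TestExpectedJointFreqs:
    @pytest.mark.parametrize("r", R_GRID)
    @pytest.mark.parametrize(
        "pop",
        [
            PopulationType("BC"),
            PopulationType("F2"),
            PopulationType("RIL"),
            PopulationType("RIL", selfing_generations=4),
            PopulationType("IRIL", intermating_generations=2),
        ],
        ids=str,
    )
    def test_probabilities_sum_to_one(self, pop, r):
        freqs = expected_joint_freqs(pop, r)
        assert all(v >= -1e-15 for v in freqs.values())
        assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_bc_r0_only_parental_classes(self):
        freqs = expected_joint_freqs(PopulationType("BC"), 0.0)
        assert freqs[("A", "A")] == pytest.approx(0.5)
        assert freqs[("B", "B")] == pytest.approx(0.5)
        assert freqs[("A", "B")] == 0.0

    def test_f2_independence_at_half(self):
        freqs = expected_joint_freqs(PopulationType("F2"), 0.5)
        margin = {"A": 0.25, "H": 0.5, "B": 0.25}
        for (c1, c2), v in freqs.items():
            assert v == pytest.approx(margin[c1] * margin[c2], abs=1e-12)

    @pytest.mark.parametrize("r", R_GRID)
    def test_f2_matches_gamete_enumeration(self, r):
        freqs = expected_joint_freqs(PopulationType("F2"), r)
        brute = f2_joint_freqs_bruteforce(r)
        for key, v in brute.items():
            assert freqs[key] == pytest.approx(v, abs=1e-12)

    def test_f2_double_heterozygote_formula(self):
        for r in (0.0, 0.1, 0.3):
            freqs = expected_joint_freqs(PopulationType("F2"), r)
            assert freqs[("H", "H")] == pytest.approx(
                ((1 - r) ** 2 + r**2) / 2, abs=1e-12
            )

    def test_cp_pair_freqs_sum_to_one(self):
        from seriamap.types import CPMarkerInfo

        a = CPMarkerInfo(parent1=("a", "b"), parent2=("a", "a"))
        b = CPMarkerInfo(parent1=("a", "b"), parent2=("c", "d"))
        freqs = expected_joint_freqs(
            PopulationType("CP"), 0.2, cp_pair=(a, b), phases=(0, )
        )
        assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-12)


class TestRilObservedR:
    def test_boundaries(self):
        pop = PopulationType("RIL")
        assert ril_observed_R(pop, 0.0) == 0.0
        assert ril_observed_R(pop, 0.5) == pytest.approx(0.5)

    def test_haldane_waddington_vs_chain(self):
        """Fixation closed form 2r/(1+2r) agrees with Markov-chain iteration."""
        closed = PopulationType("RIL")
        chain = PopulationType("RIL", selfing_generations=60)  # numerically fixed
        for r in (0.05, 0.2, 0.35):
            assert ril_observed_R(closed, r) == pytest.approx(
                2 * r / (1 + 2 * r), abs=1e-12
            )
            assert ril_observed_R(chain, r) == pytest.approx(
                2 * r / (1 + 2 * r), abs=1e-9
            )

    def test_iril_zero_intermating_equals_plain_ril(self):
        iril0 = PopulationType("IRIL", intermating_generations=0)
        ril = PopulationType("RIL")
        for r in np.linspace(0.0, 0.5, 11):
            assert ril_observed_R(iril0, float(r)) == pytest.approx(
                ril_observed_R(ril, float(r)), abs=1e-9
            )

    def test_intermating_expands_observed_recombination(self):
        r = 0.05
        r0 = ril_observed_R(PopulationType("RIL"), r)
        r3 = ril_observed_R(PopulationType("IRIL", intermating_generations=3), r)
        assert r3 > r0

    def test_transform_interpolant_matches_exact(self):
        pop = PopulationType("IRIL", intermating_generations=2)
        tr = ril_transform(pop)
        for r in (0.02, 0.11, 0.27, 0.44):
            exact = ril_observed_R(pop, r)
            assert tr.R(r) == pytest.approx(exact, abs=1e-6)
            assert tr.r(exact) == pytest.approx(r, abs=1e-6)


class TestEstimateTwoPoint:
    def test_bc_count_ml(self):
        codes_m2 = "B" * 10 + "A" * 90
        ds = make_inbred_dataset("BC", ["A" * 100, codes_m2])
        res = estimate_two_point(ds, "m1", "m2")
        assert res.r_hat == pytest.approx(0.10, abs=1e-9)
        assert res.n_informative == 100

    def test_bc_no_recombinants_lod(self):
        ds = make_inbred_dataset("BC", ["AB" * 50, "AB" * 50])
        res = estimate_two_point(ds, "m1", "m2")
        assert res.r_hat <= 1e-5
        assert res.lod == pytest.approx(100 * np.log10(2), abs=1e-3)

    def test_symmetric_in_arguments(self, f2_small_sim):
        ds = f2_small_sim.dataset
        a = estimate_two_point(ds, 0, 7)
        b = estimate_two_point(ds, 7, 0)
        assert a.r_hat == pytest.approx(b.r_hat, abs=1e-10)
        assert a.lod == pytest.approx(b.lod, abs=1e-8)

    def test_cp_opposite_pseudo_testcross_uninformative(self):
        """Male x female pseudo-backcross pairs carry no linkage information."""
        ds = make_cp_dataset(
            [("ab", "aa"), ("aa", "ab")],
            [["aa", "ab", "aa", "ab"] * 5, ["aa", "aa", "ab", "ab"] * 5],
        )
        res = estimate_two_point(ds, "m1", "m2")
        assert not res.informative
        assert res.lod == 0.0
        assert np.isnan(res.r_hat)

    def test_cp_phase_reported(self):
        # perfectly coupled female pseudo-testcross markers
        ds = make_cp_dataset(
            [("ab", "aa"), ("ab", "aa")],
            [["aa", "ab"] * 15, ["aa", "ab"] * 15],
        )
        res = estimate_two_point(ds, "m1", "m2")
        assert res.informative
        assert res.phase == "c-"
        assert res.r_hat <= 1e-5

    def test_zero_cotyped_individuals_uninformative(self):
        ds = make_inbred_dataset("BC", ["AB--", "--AB"])
        res = estimate_two_point(ds, "m1", "m2")
        assert not res.informative
        assert res.lod == 0.0


def _em_vs_grid(ds, i, j, tol=5e-4):
    """EM estimate must match a fine-grid argmax of the exact likelihood."""
    res = estimate_two_point(ds, i, j)
    if not res.informative:
        return
    pop = ds.population
    if pop.is_cp:
        from seriamap.models import _cp_pair_tables, _pair_counts_cp

        info_i, info_j = ds.cp_info[i], ds.cp_info[j]
        M, combos, tables, _ = _cp_pair_tables(info_i, info_j)
        counts = _pair_counts_cp(
            ds.genotypes[i], ds.genotypes[j], len(info_i.classes), len(info_j.classes)
        )

        def ll(r):
            return max(
                _pair_loglik(counts[None, :], tables[c], M, np.array([r]))[0]
                for c in combos
            )

        grid_hat = grid_ml_two_point(ll)
        assert res.r_hat == pytest.approx(grid_hat, abs=tol)
        return
    G, nc = _compact_inbred_codes(ds)
    N, M, _ = _inbred_pair_table(pop.kind)
    counts = _pair_counts(G[i], G[j], nc)

    def ll(r):
        return _pair_loglik(counts[None, :], N, M, np.array([r]))[0]

    grid_hat = grid_ml_two_point(ll)
    if pop.kind in ("RIL", "IRIL"):
        grid_hat = float(ril_transform(pop).r(grid_hat))
    assert res.r_hat == pytest.approx(grid_hat, abs=tol)


class TestEmEqualsGridML:
    """EM estimate equals fine-grid ML across population types."""

    def test_f2_with_dominant_codes(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(20, 60))
            codes = [
                "".join(rng.choice(list("ABHCD-"), size=n, p=[0.2, 0.2, 0.3, 0.1, 0.1, 0.1]))
                for _ in range(2)
            ]
            ds = make_inbred_dataset("F2", codes)
            _em_vs_grid(ds, 0, 1)

    def test_bc_and_ril(self):
        rng = np.random.default_rng(43)
        for kind, alphabet in (("BC", "AB-"), ("RIL", "ABH-")):
            for _ in range(20):
                n = int(rng.integers(20, 60))
                codes = ["".join(rng.choice(list(alphabet), size=n)) for _ in range(2)]
                ds = make_inbred_dataset(kind, codes)
                _em_vs_grid(ds, 0, 1)

    def test_cp_mixed_configurations(self):
        rng = np.random.default_rng(44)
        configs = [("ab", "aa"), ("ab", "ab"), ("ab", "cd")]
        for _ in range(15):
            pa = configs[rng.integers(0, 3)]
            pb = configs[rng.integers(0, 3)]
            from seriamap.types import CPMarkerInfo

            ia = CPMarkerInfo(parent1=(pa[0][0], pa[0][1]), parent2=(pa[1][0], pa[1][1]))
            ib = CPMarkerInfo(parent1=(pb[0][0], pb[0][1]), parent2=(pb[1][0], pb[1][1]))
            n = int(rng.integers(20, 50))
            ca = [str(rng.choice(ia.classes + ["--"])) for _ in range(n)]
            cb = [str(rng.choice(ib.classes + ["--"])) for _ in range(n)]
            ds = make_cp_dataset([pa, pb], [ca, cb])
            _em_vs_grid(ds, 0, 1)


class TestTwoPointMatrix:
    def test_symmetric_with_sentinel_diagonal(self, f2_small_sim):
        ds = f2_small_sim.dataset.subset_markers(range(8))
        r, lod = two_point_matrix(ds)
        assert np.all(np.isnan(np.diag(r)))
        assert np.allclose(lod, lod.T)
        finite = ~np.isnan(r)
        assert np.array_equal(finite, finite.T)
        assert np.allclose(r[finite], r.T[finite])

    def test_matrix_agrees_with_single_pair_path(self, cp_small_sim):
        ds = cp_small_sim.dataset.subset_markers(range(6))
        r, lod = two_point_matrix(ds)
        for i in range(6):
            for j in range(i + 1, 6):
                res = estimate_two_point(ds, i, j)
                if res.informative:
                    assert lod[i, j] == pytest.approx(res.lod, abs=1e-6)
                    assert r[i, j] == pytest.approx(res.r_hat, abs=1e-8)
                else:
                    assert lod[i, j] == 0.0

    def test_twin_pair_reaches_maximal_lod(self):
        col = "AB" * 30
        ds = make_inbred_dataset("BC", [col, col, "A" * 60])
        _, lod = two_point_matrix(ds)
        assert lod[0, 1] == pytest.approx(60 * np.log10(2), abs=1e-3)

    def test_invariant_under_individual_permutation(self, f2_small_sim):
        ds = f2_small_sim.dataset.subset_markers(range(6))
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.n_individuals)
        import copy

        ds2 = copy.deepcopy(ds)
        ds2.genotypes = ds2.genotypes[:, perm]
        r1, l1 = two_point_matrix(ds)
        r2, l2 = two_point_matrix(ds2)
        assert np.allclose(l1, l2, atol=1e-9)
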