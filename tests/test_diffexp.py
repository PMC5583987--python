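"""Exact test vs brute-force enumeration, dispersion recovery, BH, pipeline DE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracle_exact import enumeration_exact_test

from mirswitch.core_io import MirswitchError, ValidationError
from mirswitch.diffexp import (
    bh_fdr,
    equalize_library_sizes,
    estimate_common_dispersion,
    exact_test,
    run_pairwise_de,
)
from mirswitch.simulate import PlantedEffect, SimulationDesign, simulate_counts


class TestExactTest:
    def test_poisson_limit_closed_form(self):
        # conditional binomial: splits of 10 with P(k) <= P(0) are k=0 and k=10
        assert exact_test([0], [10], 0.0) == pytest.approx(2 / 1024, abs=1e-12)

    def test_mode_split_gives_p_one(self):
        assert exact_test([5], [5], 0.0) == pytest.approx(1.0)

    def test_symmetry_under_group_swap(self):
        for phi in (0.0, 0.1, 0.5):
            assert exact_test([3, 1], [9, 8], phi) == pytest.approx(
                exact_test([9, 8], [3, 1], phi), abs=1e-12
            )

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    def test_matches_enumeration_oracle(self, phi, rng):
        # random two-group splits with conditioned totals <= 60,
        # mixed replicate layouts
        layouts = [(1, 1), (4, 4), (2, 3)]
        for _ in range(200):
            na, nb = layouts[rng.integers(len(layouts))]
            total = int(rng.integers(1, 61))
            cuts = np.sort(rng.integers(0, total + 1, size=na + nb - 1))
            parts = np.diff(np.concatenate([[0], cuts, [total]]))
            a, b = parts[:na], parts[na:]
            assert exact_test(a, b, phi) == pytest.approx(
                enumeration_exact_test(a, b, phi), abs=1e-9
            )

    def test_oracle_invariant_to_nuisance_mean(self):
        a, b = [7, 3], [1, 0]
        assert enumeration_exact_test(a, b, 0.2, mean_per_lib=2.0) == pytest.approx(
            enumeration_exact_test(a, b, 0.2, mean_per_lib=50.0), abs=1e-12
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            exact_test([-1], [3], 0.1)

    def test_all_zero_counts_give_p_one(self):
        assert exact_test([0, 0], [0, 0], 0.1) == 1.0

    def test_type_one_error_calibration(self, rng):
        # 4 vs 4 null NB features at the true dispersion: rejection at 0.05
        # should sit near the nominal level
        phi, r, n = 0.1, 10.0, 4000
        mu = np.exp(rng.uniform(np.log(30), np.log(300), size=n))
        ya = rng.negative_binomial(r, r / (r + mu[:, None]), size=(n, 4))
        yb = rng.negative_binomial(r, r / (r + mu[:, None]), size=(n, 4))
        ps = np.array([exact_test(ya[i], yb[i], phi) for i in range(n)])
        assert 0.035 <= (ps < 0.05).mean() <= 0.065


class TestEqualization:
    def test_equal_libraries_are_fixed_point(self):
        counts = pd.DataFrame({"a": [10, 0], "b": [7, 3]}, index=["f1", "f2"])
        pseudo, common = equalize_library_sizes(counts, [1e6, 1e6])
        assert common == pytest.approx(1e6)
        assert np.allclose(pseudo.to_numpy(), counts.to_numpy())

    def test_pseudo_library_is_geometric_mean(self):
        counts = pd.DataFrame({"a": [10], "b": [40]}, index=["f1"])
        _, common = equalize_library_sizes(counts, [1e6, 4e6])
        assert common == pytest.approx(2e6)

    def test_rescaling_all_libraries_is_invariant(self):
        counts = pd.DataFrame({"a": [10, 5], "b": [40, 2], "c": [3, 30]})
        p1, _ = equalize_library_sizes(counts, [1e6, 4e6, 2e6], phi=0.1)
        p2, _ = equalize_library_sizes(counts, [3e6, 12e6, 6e6], phi=0.1)
        assert np.allclose(p1.to_numpy(), p2.to_numpy())

    def test_zero_library_rejected(self):
        with pytest.raises(ValidationError):
            equalize_library_sizes(pd.DataFrame({"a": [1]}), [0.0])


class TestDispersion:
    def _pseudo(self, phi, n_features, rng, reps=4):
        r = np.inf if phi == 0 else 1.0 / phi
        mu = np.exp(rng.uniform(np.log(50), np.log(2000), size=n_features))[:, None]
        if phi == 0:
            y = rng.poisson(np.tile(mu, (1, 2 * reps)))
        else:
            y = rng.negative_binomial(r, r / (r + np.tile(mu, (1, 2 * reps))))
        cols = [f"a{i}" for i in range(reps)] + [f"b{i}" for i in range(reps)]
        return pd.DataFrame(y, columns=cols), [cols[:reps], cols[reps:]]

    def test_poisson_data_estimates_near_zero(self, rng):
        pseudo, groups = self._pseudo(0.0, 2000, rng)
        assert estimate_common_dispersion(pseudo, groups).phi <= 0.01

    def test_recovery_of_true_dispersion(self, rng):
        pseudo, groups = self._pseudo(0.2, 2000, rng)
        est = estimate_common_dispersion(pseudo, groups)
        assert 0.16 <= est.phi <= 0.24
        assert est.method == "conditional_ML"

    def test_constant_within_group_counts_hit_lower_bound(self):
        pseudo = pd.DataFrame(
            {"a1": [100] * 50, "a2": [100] * 50, "b1": [200] * 50, "b2": [200] * 50}
        )
        est = estimate_common_dispersion(pseudo, [["a1", "a2"], ["b1", "b2"]])
        assert est.phi <= 1e-4

    def test_unreplicated_design_refused(self):
        pseudo = pd.DataFrame({"a": [5], "b": [9]})
        with pytest.raises(MirswitchError, match="fixed"):
            estimate_common_dispersion(pseudo, [["a"], ["b"]])


class TestBH:
    def test_hand_computed_step_up(self):
        q = bh_fdr([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(q, [0.02, 0.02, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.123])[0] == pytest.approx(0.123)

    def test_all_ones_stay_one(self):
        assert np.all(bh_fdr([1.0, 1.0, 1.0]) == 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.0, 0.5])

    @given(st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=40))
    @settings(deadline=None, max_examples=80)
    def test_monotone_and_bounded(self, ps):
        q = bh_fdr(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)

    @given(st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=40), st.randoms())
    @settings(deadline=None, max_examples=40)
    def test_permutation_equivariance(self, ps, pyrandom):
        perm = list(range(len(ps)))
        pyrandom.shuffle(perm)
        q = bh_fdr(ps)
        q_perm = bh_fdr([ps[i] for i in perm])
        assert np.allclose(q_perm, q[perm])


class TestPairwiseDE:
    def test_planted_recovery_sensitivity_and_fdr(self):
        planted = tuple(
            PlantedEffect(f"gene{i:04d}", "E18", "D3", (1.0 + i % 9) * (1 if i % 2 else -1))
            for i in range(200)
        )
        design = SimulationDesign(
            n_features={"mrna": 2000, "mirna": 20},
            dispersion={"mrna": 0.1, "mirna": 0.02},
            planted_de=planted,
            rng_seed=5,
        )
        mats, _ = simulate_counts(design)
        results = run_pairwise_de(mats["mrna"], [("E18", "D3")])[("E18", "D3")]
        truth = {e.feature_id for e in planted}
        called = {r.feature_id for r in results if r.significant}
        sensitivity = len(called & truth) / len(truth)
        fdr = len(called - truth) / max(1, len(called))
        assert sensitivity >= 0.85
        assert fdr <= 0.10

    def test_null_simulation_calls_almost_nothing(self):
        design = SimulationDesign(
            n_features={"mrna": 2000, "mirna": 20}, rng_seed=9
        )
        mats, _ = simulate_counts(design)
        results = run_pairwise_de(mats["mrna"], [("E18", "D3")])[("E18", "D3")]
        frac = np.mean([r.significant for r in results])
        assert frac <= 0.01

    def test_identical_group_means_not_significant(self, small_mrna_counts):
        results = run_pairwise_de(
            small_mrna_counts, [("E18", "D3")], fixed_dispersion=0.1
        )[("E18", "D3")]
        flat = next(r for r in results if r.feature_id == "geneB")
        assert not flat.significant

    def test_unreplicated_without_fixed_phi_raises(self, small_mirna_counts):
        single = small_mirna_counts.subset_samples(["s1", "s3"])
        with pytest.raises(MirswitchError, match="unreplicated"):
            run_pairwise_de(single, [("E18", "D3")])

    def test_unknown_stage_rejected(self, small_mirna_counts):
        with pytest.raises(ValidationError, match="unknown stage"):
            run_pairwise_de(small_mirna_counts, [("E18", "D9")])

    def test_q_never_below_p_and_significance_rule(self, small_mrna_counts):
        results = run_pairwise_de(
            small_mrna_counts, [("E18", "D3")], fixed_dispersion=0.05
        )[("E18", "D3")]
        for r in results:
            assert r.q >= r.p - 1e-12
            assert r.significant == (abs(r.log2fc) > 1.0 and r.q < 0.05)
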