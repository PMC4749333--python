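import numpy as np
import pandas as pd
import pytest

from refstab import (
    expression_ratio,
    randomization_test,
    simulate_validation_scenario,
)


def tables(values_ctrl, values_trt, genes):
    c = pd.DataFrame(values_ctrl, index=genes, dtype=float)
    t = pd.DataFrame(values_trt, index=genes, dtype=float)
    return c, t


class TestExpressionRatio:
    def test_two_cycle_drop_with_flat_reference(self):
        c, t = tables(
            {"r1": [24.0, 20.0], "r2": [24.0, 20.0]},
            {"r1": [22.0, 20.0], "r2": [22.0, 20.0]},
            ["tgt", "ref"],
        )
        res = expression_ratio(c, t, "tgt", ["ref"], {"tgt": 1.0, "ref": 1.0})
        assert res.ratio == pytest.approx(4.0)

    def test_reference_drop_halves_the_ratio(self):
        c, t = tables(
            {"r1": [24.0, 20.0], "r2": [24.0, 20.0]},
            {"r1": [22.0, 19.0], "r2": [22.0, 19.0]},
            ["tgt", "ref"],
        )
        res = expression_ratio(c, t, "tgt", ["ref"], {"tgt": 1.0, "ref": 1.0})
        assert res.ratio == pytest.approx(2.0)

    def test_multi_reference_geometric_mean(self):
        # reference factors 2 and 8 -> geomean 4; a 4-fold target shift cancels
        c, t = tables(
            {"r1": [24.0, 20.0, 21.0], "r2": [24.0, 20.0, 21.0]},
            {"r1": [22.0, 19.0, 18.0], "r2": [22.0, 19.0, 18.0]},
            ["tgt", "refA", "refB"],
        )
        eff = {"tgt": 1.0, "refA": 1.0, "refB": 1.0}
        res = expression_ratio(c, t, "tgt", ["refA", "refB"], eff)
        assert res.ratio == pytest.approx(1.0)

    def test_log_ratio_equals_ddcq_with_constant_reference(self):
        rng = np.random.default_rng(0)
        genes = ["tgt", "ref"]
        c = pd.DataFrame(rng.uniform(20, 24, size=(2, 4)), index=genes)
        t = pd.DataFrame(rng.uniform(20, 24, size=(2, 4)), index=genes)
        t.loc["ref"] = c.loc["ref"].to_numpy()  # reference unchanged
        eff = {"tgt": 1.0, "ref": 1.0}
        res = expression_ratio(c, t, "tgt", ["ref"], eff)
        ddcq = c.loc["tgt"].mean() - t.loc["tgt"].mean()
        assert np.log2(res.ratio) == pytest.approx(ddcq)

    def test_unstable_reference_biases_by_its_own_fold_change(self):
        ctrl, trt, truth = simulate_validation_scenario(
            fold_change=4.0, unstable_ref_shift=2.0, noise_sd=0.0, seed=1
        )
        eff = truth["efficiencies"]
        stable = expression_ratio(ctrl, trt, truth["target"], truth["stable_refs"], eff)
        biased = expression_ratio(ctrl, trt, truth["target"], truth["unstable_refs"], eff)
        assert stable.ratio == pytest.approx(4.0)
        assert biased.ratio == pytest.approx(1.0)  # 4-fold masked by 4-fold reference drift

    def test_empty_reference_set_and_missing_efficiency(self):
        c, t = tables({"r1": [24.0], "r2": [24.0]}, {"r1": [22.0], "r2": [22.0]}, ["tgt"])
        with pytest.raises(ValueError, match="nonempty"):
            expression_ratio(c, t, "tgt", [], {"tgt": 1.0})
        c2, t2 = tables(
            {"r1": [24.0, 20.0], "r2": [24.0, 20.0]},
            {"r1": [22.0, 20.0], "r2": [22.0, 20.0]},
            ["tgt", "ref"],
        )
        with pytest.raises(ValueError, match="no efficiency"):
            expression_ratio(c2, t2, "tgt", ["ref"], {"tgt": 1.0})

    def test_per_replicate_ratios_average_near_overall(self):
        ctrl, trt, truth = simulate_validation_scenario(fold_change=4.0, noise_sd=0.0, seed=2)
        res = expression_ratio(ctrl, trt, truth["target"], truth["stable_refs"], truth["efficiencies"])
        np.testing.assert_allclose(res.per_replicate_ratios, 4.0)


class TestRandomizationTest:
    def scenario(self, fold, seed, noise=0.2, reps=3):
        ctrl, trt, truth = simulate_validation_scenario(
            fold_change=fold, noise_sd=noise, reps=reps, seed=seed
        )
        return ctrl, trt, truth

    def test_null_data_has_large_p(self):
        ctrl, trt, truth = self.scenario(fold=1.0, seed=3, noise=0.0)
        res = randomization_test(
            ctrl, trt, truth["target"], truth["stable_refs"], truth["efficiencies"],
            n_permutations=500, seed=0,
        )
        assert res.p_value >= 0.5

    def test_seed_determinism(self):
        ctrl, trt, truth = self.scenario(fold=2.0, seed=4)
        kwargs = dict(n_permutations=500, seed=11)
        r1 = randomization_test(ctrl, trt, truth["target"], truth["stable_refs"], truth["efficiencies"], **kwargs)
        r2 = randomization_test(ctrl, trt, truth["target"], truth["stable_refs"], truth["efficiencies"], **kwargs)
        assert r1.p_value == r2.p_value

    def test_small_designs_fall_back_to_exact_enumeration(self):
        ctrl, trt, truth = self.scenario(fold=4.0, seed=5, reps=2)
        with pytest.warns(UserWarning, match="exact enumeration"):
            res = randomization_test(
                ctrl, trt, truth["target"], truth["stable_refs"], truth["efficiencies"],
                n_permutations=2000, seed=0,
            )
        assert res.n_permutations == 6  # C(4, 2) distinct reallocations

    def test_exact_and_monte_carlo_agree_within_binomial_error(self):
        ctrl, trt, truth = self.scenario(fold=2.0, seed=6, reps=3)
        genes = [truth["target"]] + truth["stable_refs"]
        eff = truth["efficiencies"]
        mc = randomization_test(ctrl, trt, genes[0], truth["stable_refs"], eff,
                                n_permutations=4000, seed=1)
        # exact reference: enumerate all C(6,3)=20 reallocations by hand
        from itertools import combinations

        z = []
        pooled = pd.concat([ctrl.loc[genes], trt.loc[genes]], axis=1).to_numpy()
        w = np.log2(2.0)
        contrast = np.array([w] + [-w / len(truth["stable_refs"])] * len(truth["stable_refs"]))
        zc = contrast @ pooled
        obs = abs(zc[:3].mean() - zc[3:].mean())
        stats_all = [
            abs(zc[list(c)].mean() - zc[[i for i in range(6) if i not in c]].mean())
            for c in combinations(range(6), 3)
        ]
        exact = np.mean(np.asarray(stats_all) >= obs - 1e-12)
        se = np.sqrt(exact * (1 - exact) / 4000)
        assert abs(mc.p_value - exact) <= max(4 * se, 0.02)

    def test_minimum_p_is_bounded_by_reallocation_count(self):
        # 3v3 whole-sample reallocation has only C(6,3)=20 labelings and the
        # two-sided statistic pairs each with its mirror, so p >= ~0.1 always
        ctrl, trt, truth = self.scenario(fold=64.0, seed=7, noise=0.01)
        res = randomization_test(
            ctrl, trt, truth["target"], truth["stable_refs"], truth["efficiencies"],
            n_permutations=2000, seed=1,
        )
        assert res.p_value >= 0.05

    def test_power_against_fourfold_induction(self):
        # 4v4 replicates give 70 labelings, enough granularity to reject at 0.05
        hits = 0
        n = 60
        for seed in range(n):
            ctrl, trt, truth = self.scenario(fold=4.0, seed=seed, reps=4)
            res = randomization_test(
                ctrl, trt, truth["target"], truth["stable_refs"], truth["efficiencies"],
                n_permutations=2000, seed=seed + 1,
            )
            hits += res.p_value < 0.05
        assert hits / n >= 0.9
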