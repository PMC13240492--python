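"""Tests for distributions, the decision rule, PSA, CEAC and subgroups."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eswtcea as e

from conftest import make_fit


def _point_values() -> dict:
    """Variance-free parameter block matching the deterministic inputs."""
    return dict(
        p_open_to_amputee=0.00308674, p_healed_to_open=0.00308674,
        p_open_to_dead=0.00019921, p_healed_to_dead=6.0435e-05,
        p_amputee_to_dead=0.000456958,
        c_open=15.01, c_amputee=22.64, c_healed=1.89,
        u_open=0.671, u_amputee=0.316, u_healed=0.757,
    )


class TestDistributions:
    def test_gamma_cost_sample_means(self):
        rng = np.random.default_rng(0)
        amputee = e.GammaSpec(49.0, 0.46201166)
        assert amputee.sample(rng, 100_000).mean() == pytest.approx(
            22.64, rel=0.01)
        assert amputee.mean == pytest.approx(22.64, rel=0.005)
        assert e.GammaSpec(49.0, 0.30623907).mean == pytest.approx(
            15.01, rel=0.005)

    def test_amputee_utility_beta_mean(self):
        rng = np.random.default_rng(1)
        spec = e.BetaSpec(0.647532157, 1.39838303)
        closed = 0.647532157 / (0.647532157 + 1.39838303)
        assert spec.mean == pytest.approx(closed)
        assert spec.sample(rng, 200_000).mean() == pytest.approx(
            closed, rel=0.02)

    def test_point_mass_is_degenerate(self):
        rng = np.random.default_rng(2)
        draws = e.PointMassSpec(0.5).sample(rng, 100)
        assert np.all(draws == 0.5)

    def test_invalid_hyperparameters_rejected_at_construction(self):
        with pytest.raises(ValueError):
            e.BetaSpec(0.0, 1.0)
        with pytest.raises(ValueError):
            e.GammaSpec(49.0, -1.0)

    def test_corrected_means_match_deterministic_within_half_percent(self):
        dists = e.ParameterDistributions.published()
        for name, value in _point_values().items():
            assert getattr(dists, name).mean == pytest.approx(
                value, rel=0.005), name

    def test_as_printed_toggles_expose_inconsistencies(self):
        raw = e.ParameterDistributions.published(
            correct_event_betas=False, correct_healed_cost=False,
            swap_open_healed_utilities=False)
        # published pairs are ten-fold off / swapped vs deterministic values
        assert raw.p_open_to_amputee.mean == pytest.approx(0.000308674,
                                                           rel=1e-6)
        assert raw.c_healed.mean == pytest.approx(0.1897, rel=1e-3)
        assert raw.u_open.mean == pytest.approx(0.757, abs=5e-4)
        assert raw.u_healed.mean == pytest.approx(0.671, abs=5e-4)


class TestDecisionRule:
    def test_nmb_examples(self):
        assert e.nmb(0.022, -921.67, 20_000) == pytest.approx(1361.67)
        assert e.nmb(0.5, 123.0, 0.0) == -123.0
        assert e.nmb(0.0, 0.0, 20_000) == 0.0

    def test_cheaper_more_effective_is_dominant(self):
        table = e.dominance([4538.48, 3616.81], [0.650, 0.672],
                            labels=["standard", "high_dose"])
        assert table.loc["high_dose", "label"] == "dominant"
        assert "no incremental analysis" in table.loc["high_dose", "note"]
        assert np.isnan(table.loc["high_dose", "icer_vs_reference"])

    def test_tie_has_no_icer(self):
        table = e.dominance([100.0, 100.0], [0.5, 0.5], labels=["a", "b"])
        assert (table["label"] == "non-dominated").all()
        assert "undefined" in table.loc["b", "note"]

    def test_icer_for_costlier_more_effective(self):
        table = e.dominance([100.0, 300.0], [0.5, 0.6], labels=["a", "b"])
        assert table.loc["b", "icer_vs_reference"] == pytest.approx(2000.0)

    @given(st.integers(2, 5), st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_labels_match_bruteforce_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        costs = rng.uniform(0, 1000, n).round(1)
        qalys = rng.uniform(0, 1, n).round(3)
        table = e.dominance(costs, qalys)
        for i in range(n):
            dominant = all(qalys[i] > qalys[j] and costs[i] < costs[j]
                           for j in range(n) if j != i)
            dominated = any(qalys[j] > qalys[i] and costs[j] < costs[i]
                            for j in range(n) if j != i)
            expected = ("dominant" if dominant
                        else "dominated" if dominated else "non-dominated")
            assert table["label"].iloc[i] == expected

    def test_incremental_table_arithmetic(self):
        table = e.incremental_table([100.0, 100.0], [0.5, 0.5], ["a", "b"])
        assert table.loc["b", "d_cost"] == 0.0
        assert table.loc["b", "d_qaly"] == 0.0


class TestPsa:
    def test_seed_reproducibility(self, default_model, published_dists):
        a = e.run_psa(default_model, published_dists, n_iter=50, seed=3)
        b = e.run_psa(default_model, published_dists, n_iter=50, seed=3)
        pd.testing.assert_frame_equal(a.costs, b.costs)
        pd.testing.assert_frame_equal(a.qalys, b.qalys)

    def test_variance_free_psa_equals_deterministic(self, default_fit,
                                                    default_model):
        frozen = dataclasses.replace(default_fit,
                                     vcov=np.zeros_like(default_fit.vcov))
        model = dataclasses.replace(default_model, fit=frozen)
        dists = e.ParameterDistributions.point_mass(_point_values())
        psa = e.run_psa(model, dists, n_iter=8, seed=0)
        det = e.deterministic_analysis(model)
        for s in model.strategies:
            # tiny Cholesky jitter aside, every draw equals the point run
            np.testing.assert_allclose(psa.costs[s], det.table.loc[s, "cost"],
                                       rtol=1e-6)
            np.testing.assert_allclose(psa.qalys[s], det.table.loc[s, "qaly"],
                                       rtol=1e-6)
        curve = e.ceac(psa, [0.0, 20_000.0])
        probs = curve[list(model.strategies)].to_numpy()
        assert set(np.unique(probs)) <= {0.0, 1.0}

    def test_deterministic_dominance_for_default_conditions(self,
                                                            default_model):
        det = e.deterministic_analysis(default_model)
        assert det.table.loc["high_dose", "label"] == "dominant"
        assert det.table.loc["high_dose", "d_cost"] < 0
        assert det.table.loc["high_dose", "d_qaly"] > 0

    def test_ceac_probabilities_sum_to_one(self, default_model,
                                           published_dists):
        psa = e.run_psa(default_model, published_dists, n_iter=200, seed=5)
        curve = e.ceac(psa, [0, 10_000, 20_000, 30_000])
        totals = curve[list(default_model.strategies)].sum(axis=1)
        np.testing.assert_allclose(totals, 1.0, atol=1e-12)

    def test_ceac_hand_enumeration(self):
        # 4 hand-built draws, threshold 1: NMB = qaly - cost
        psa = e.PsaResult(
            costs=pd.DataFrame({"a": [0.0, 0, 0, 0], "b": [0.0, 0, 0, 0]}),
            qalys=pd.DataFrame({"a": [1.0, 3.0, 5.0, 1.0],
                                "b": [2.0, 2.0, 2.0, 1.0]}),
            strategies=("a", "b"), seed=0, n_iter=4)
        curve = e.ceac(psa, [1.0])
        # a wins draws 2,3; b wins draw 1; draw 4 ties (split 50:50)
        assert curve.loc[0, "a"] == pytest.approx((2 + 0.5) / 4)
        assert curve.loc[0, "b"] == pytest.approx((1 + 0.5) / 4)

    def test_single_strategy_ceac_is_one(self):
        psa = e.PsaResult(costs=pd.DataFrame({"only": [1.0, 2.0]}),
                          qalys=pd.DataFrame({"only": [0.1, 0.2]}),
                          strategies=("only",), seed=0, n_iter=2)
        curve = e.ceac(psa, [0.0, 20_000.0])
        assert (curve["only"] == 1.0).all()

    def test_ce_plane_increments(self, default_model, published_dists):
        psa = e.run_psa(default_model, published_dists, n_iter=20, seed=6)
        plane = e.ce_plane(psa)
        assert set(plane["strategy"]) == {"low_dose", "high_dose"}
        row = plane[(plane.strategy == "high_dose") & (plane.draw == 0)]
        assert row["d_cost"].iloc[0] == pytest.approx(
            psa.costs.loc[0, "high_dose"] - psa.costs.loc[0, "standard"])


class TestSubgroups:
    def test_zero_treatment_effect_costs_the_intervention(self):
        # no effect and no uncertainty: incremental NMB is minus the
        # intervention cost for both active arms
        fit = make_fit(shape=1.1, coeffs={"const": -6.0})
        model = e.DecisionModel(fit=fit)
        dists = e.ParameterDistributions.point_mass(_point_values())
        table = e.subgroup_analysis(model, dists,
                                    profiles=[e.SubgroupProfile(0, 1.0, 30.0)],
                                    n_iter=4, seed=0)
        np.testing.assert_allclose(table["inc_nmb"], -141.0, atol=1e-6)

    def test_high_dose_has_highest_nmb_in_every_subgroup(self, big_model,
                                                         published_dists):
        table = e.subgroup_analysis(big_model, published_dists,
                                    n_iter=300, seed=7)
        pivot = table.pivot_table(
            index=["infected", "area_cm2", "duration_days"],
            columns="strategy", values="inc_nmb")
        assert (pivot["high_dose"] > pivot["low_dose"]).all()

    def test_nmb_declines_with_size_and_duration(self, big_model,
                                                 published_dists):
        # larger/older ulcers heal more slowly, so the treatment's
        # incremental NMB shrinks along the subgroup grid
        table = e.subgroup_analysis(big_model, published_dists,
                                    n_iter=300, seed=7)
        for infected in (0, 1):
            sub = table[(table.infected == infected)
                        & (table.strategy == "high_dose")]
            ordered = sub.sort_values("area_cm2")["inc_nmb"].to_numpy()
            assert ordered[0] > ordered[-1]
            assert np.all(np.diff(ordered) < 0)
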