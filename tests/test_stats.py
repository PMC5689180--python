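"""Welch t-tests, Holm-Bonferroni, regressions and the sensitivity driver."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myogait import (
    CurveSet,
    HomologMap,
    compare_species,
    comparison_summary,
    default_curves,
    fat_fraction_regression,
    holm_bonferroni,
    muscle_excursion,
    sensitivity_analysis,
    static_equilibrium_fiber_length,
    two_sample_t,
)
from myogait.excursion import CohortTable

from conftest import make_kinematics
from test_excursion import linear_surface_model


def table_from_values(species: str, values: dict) -> CohortTable:
    """CohortTable with excursion samples per muscle (other tables empty)."""
    rows = [
        {"species": species, "subject_id": f"{species}-{i}", "muscle": m, "E": v}
        for m, vals in values.items()
        for i, v in enumerate(vals)
    ]
    empty = pd.DataFrame()
    return CohortTable(species, pd.DataFrame(rows), empty, empty)


class TestTwoSampleT:
    def test_identical_samples(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == 1.0

    def test_fully_separated_samples(self):
        x = np.zeros(4) + 1e-12 * np.array([1, 2, 3, 4])
        y = np.ones(4) + 1e-12 * np.array([1, 2, 3, 4])
        _, p = two_sample_t(x, y)
        assert p < 1e-6

    def test_welch_formula_by_hand(self):
        # x = 1..5, y = 2..6: means 3, 4; s^2 = 2.5, n = 5 each
        # t = -1 / sqrt(2.5/5 + 2.5/5) = -1;  Welch df = 8
        x, y = [1, 2, 3, 4, 5], [2, 3, 4, 5, 6]
        t, p = two_sample_t(x, y)
        assert t == pytest.approx(-1.0, abs=1e-12)
        from scipy import stats as sps
        assert p == pytest.approx(2 * sps.t.sf(1.0, df=8), rel=1e-9)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])

    def test_student_variant_switchable(self):
        x = [1.0, 2.0, 3.0, 9.0]
        y = [2.0, 2.1, 2.2]
        t_w, _ = two_sample_t(x, y, equal_var=False)
        t_s, _ = two_sample_t(x, y, equal_var=True)
        assert t_w != t_s


class TestHolmBonferroni:
    def test_step_down_hand_worked_example(self):
        # m=4, alpha=0.05: 0.01 <= 0.05/4 -> reject; 0.02 > 0.05/3 -> stop.
        # adjusted = running max of (m-i+1) p_(i): 0.04, 0.06, 0.06, 0.06
        p_adj, reject = holm_bonferroni([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        np.testing.assert_allclose(p_adj, [0.04, 0.06, 0.06, 0.06], atol=1e-12)
        assert reject.tolist() == [True, False, False, False]

    def test_all_zero_p(self):
        p_adj, reject = holm_bonferroni([0.0, 0.0, 0.0])
        assert np.all(p_adj == 0.0)
        assert np.all(reject)

    def test_single_test_uncorrected(self):
        p_adj, reject = holm_bonferroni([0.03], alpha=0.05)
        assert p_adj[0] == pytest.approx(0.03)
        assert reject[0]

    def test_results_in_input_order(self):
        p = [0.04, 0.001, 0.2]
        p_adj, _ = holm_bonferroni(p)
        # the smallest raw p keeps the smallest adjusted p at its own slot
        assert np.argmin(p_adj) == 1

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.2])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_sandwiched_between_bonferroni_and_uncorrected(self, p):
        alpha = 0.05
        p = np.asarray(p)
        _, holm = holm_bonferroni(p, alpha=alpha)
        bonf = p <= alpha / p.size
        raw = p <= alpha
        assert np.all(holm[bonf])   # Holm rejects whatever Bonferroni rejects
        assert np.all(raw[holm])    # and never rejects what raw p won't


class TestCompareSpecies:
    def _map(self, muscles):
        return HomologMap(pairs=[(m, m) for m in muscles])

    def test_known_effect_all_significant(self):
        # human E = 2x mouse E, small noise: power > 0.999 for all 25 pairs
        rng = np.random.default_rng(42)
        muscles = [f"m{i:02d}" for i in range(1, 26)]
        base = rng.uniform(0.1, 0.4, size=25)
        mouse = {
            m: base[i] + rng.normal(0, 0.005, size=16)
            for i, m in enumerate(muscles)
        }
        human = {
            m: 2 * base[i] + rng.normal(0, 0.005, size=5)
            for i, m in enumerate(muscles)
        }
        rows = compare_species(
            table_from_values("mouse", mouse),
            table_from_values("human", human),
            self._map(muscles),
        )
        assert len(rows) == 25
        assert all(r.significant and r.direction == "human_larger" for r in rows)

    def test_identical_cohorts_nothing_significant(self):
        rng = np.random.default_rng(7)
        muscles = ["a", "b", "c"]
        vals = {m: rng.normal(0.3, 0.05, size=8) for m in muscles}
        rows = compare_species(
            table_from_values("mouse", vals),
            table_from_values("human", vals),
            self._map(muscles),
        )
        assert all(not r.significant and r.direction == "none" for r in rows)

    def test_constructed_ratio_summary(self):
        # noise-free tables with mouse E = 0.48 * human E -> family mean
        # ratio 48 % over the human-larger significant pairs
        muscles = [f"m{i}" for i in range(6)]
        human = {m: np.full(5, 0.2 + 0.05 * i) for i, m in enumerate(muscles)}
        jitter = 1e-9 * np.arange(5)  # avoid exactly-zero variance
        mouse = {m: 0.48 * human[m] + jitter for m in muscles}
        human = {m: human[m] + jitter for m in muscles}
        rows = compare_species(
            table_from_values("mouse", mouse),
            table_from_values("human", human),
            self._map(muscles),
        )
        s = comparison_summary(rows)
        assert s["n_human_larger"] == 6
        assert s["mean_ratio_mouse_over_human_pct"] == pytest.approx(48.0, abs=1e-3)

    def test_missing_muscle_fails_naming_pair(self):
        rows = {"a": np.ones(4) + np.arange(4) * 0.01}
        with pytest.raises(KeyError, match="b"):
            compare_species(
                table_from_values("mouse", rows),
                table_from_values("human", rows),
                self._map(["b"]),
            )

    def test_null_familywise_error_controlled(self):
        # equal species distributions: familywise error <= 0.07 over
        # seeded replicates at alpha = 0.05 (light version; the acceptance
        # suite runs 1000 replicates)
        rng = np.random.default_rng(123)
        muscles = [f"m{i}" for i in range(10)]
        fw_errors = 0
        n_rep = 200
        for _ in range(n_rep):
            mouse = {m: rng.normal(0.3, 0.05, 16) for m in muscles}
            human = {m: rng.normal(0.3, 0.05, 5) for m in muscles}
            rows = compare_species(
                table_from_values("mouse", mouse),
                table_from_values("human", human),
                self._map(muscles),
            )
            fw_errors += any(r.significant for r in rows)
        assert fw_errors / n_rep <= 0.07


class TestFatFractionRegression:
    def test_exact_line_recovered(self):
        E = {f"m{i}": 0.1 * i for i in range(1, 6)}
        fat = {m: 2 * v + 1 for m, v in E.items()}
        groups = {m: "upper_leg" for m in E}
        groups.update({f"l{i}": "lower_leg" for i in range(3)})
        E.update({f"l{i}": 0.05 * (i + 1) for i in range(3)})
        fat.update({f"l{i}": 0.5 * E[f"l{i}"] for i in range(3)})
        res = {r.group: r for r in fat_fraction_regression(E, fat, groups)}
        assert res["upper_leg"].slope == pytest.approx(2.0, abs=1e-10)
        assert res["upper_leg"].intercept == pytest.approx(1.0, abs=1e-10)
        assert res["upper_leg"].r2 == pytest.approx(1.0, abs=1e-10)
        assert res["lower_leg"].slope == pytest.approx(0.5, abs=1e-10)

    def test_flat_response_r2_zero(self):
        E = {f"m{i}": 0.1 * i for i in range(1, 5)}
        fat = {m: 0.4 for m in E}
        groups = {m: "upper_leg" for m in E}
        E.update({f"l{i}": 0.1 * i for i in range(1, 4)})
        fat.update({f"l{i}": 0.1 * i / 10 for i in range(1, 4)})
        groups.update({f"l{i}": "lower_leg" for i in range(1, 4)})
        res = {r.group: r for r in fat_fraction_regression(E, fat, groups)}
        assert res["upper_leg"].r2 == 0.0
        assert res["upper_leg"].p == 1.0

    def test_merge_averages_excursions_before_fit(self):
        # two heads merged into one predictor (fat imaged as one muscle)
        E = {"per_longus": 0.2, "per_brevis": 0.4, "a": 0.1, "b": 0.3, "c": 0.5}
        fat = {"peroneus": 0.35, "a": 0.2, "b": 0.4, "c": 0.6}
        groups = {m: "lower_leg" for m in list(E) + ["peroneus"]}
        res = fat_fraction_regression(
            E, fat, groups,
            merges=[ (["per_longus", "per_brevis"], "peroneus") ],
        )
        (lower,) = [r for r in res if r.group == "lower_leg"]
        assert lower.n == 4  # a, b, c + merged peroneus at E = 0.3
        # merged point (0.3, 0.35) lies off the exact line of a, b, c
        assert lower.r2 < 1.0

    def test_exclusions_and_min_group_size(self):
        E = {f"m{i}": 0.1 * i for i in range(1, 5)}
        fat = {m: v for m, v in E.items()}
        groups = {m: "upper_leg" for m in E}
        with pytest.raises(ValueError, match="upper_leg"):
            fat_fraction_regression(E, fat, groups, exclusions=["m1", "m2"])

    def test_slope_recovery_within_monte_carlo_error(self):
        # light version of the sampling-distribution check (acceptance runs
        # 500 replicates): mean slope estimate within 2 SE of truth
        rng = np.random.default_rng(55)
        beta, sigma, n = 0.8, 0.03, 9
        x = np.linspace(0.05, 0.45, n)
        slopes = []
        groups = {f"m{i}": "lower_leg" for i in range(n)}
        for _ in range(200):
            y = beta * x + 0.05 + rng.normal(0, sigma, size=n)
            E = {f"m{i}": x[i] for i in range(n)}
            fat = {f"m{i}": y[i] for i in range(n)}
            res = fat_fraction_regression(E, fat, groups)
            slopes.append(res[0].slope)
        se = np.std(slopes, ddof=1) / math.sqrt(len(slopes))
        assert abs(np.mean(slopes) - beta) < 2 * se + 1e-12


class TestSensitivity:
    def _single_muscle_setup(self, L_o_sd=0.0, L_s_sd=0.0):
        model = linear_surface_model(slope=0.02, L_ref=0.5)
        u = model.units[0]
        u.L_o_sd, u.L_s_sd = L_o_sd, L_s_sd
        kin = make_kinematics({"hinge": 90.0})
        return model, u, kin

    def test_zero_sds_give_zero_deltas(self, curves):
        model, _, kin = self._single_muscle_setup(0.0, 0.0)
        reports = sensitivity_analysis(
            model, curves, kin,
            parameters=("L_o_plus_sd", "L_o_minus_sd", "L_s_plus_sd",
                        "L_s_minus_sd"),
        )
        for r in reports:
            assert r.per_muscle_delta == {"toy": 0.0}
            assert r.mean_delta == 0.0

    def test_missing_sd_skips_muscle_with_warning(self, curves):
        model, _, kin = self._single_muscle_setup()
        model.units[0].L_o_sd = None
        with pytest.warns(UserWarning, match="without a reported SD"):
            reports = sensitivity_analysis(
                model, curves, kin, parameters=("L_o_plus_sd",)
            )
        assert reports[0].per_muscle_delta == {}
        assert reports[0].skipped == ["toy"]

    def test_rigid_muscle_insensitive_to_tendon_strain(self, curves):
        model, u, kin = self._single_muscle_setup()
        u.L_o, u.L_s, u.alpha_o = 0.05, 0.01, 0.0  # rigid: tendon curve unused
        reports = sensitivity_analysis(
            model, curves, kin, parameters=("eps_2pct", "eps_9pct")
        )
        for r in reports:
            assert r.per_muscle_delta["toy"] == 0.0

    def test_tendon_slack_shift_matches_two_point_oracle(self, curves):
        # constant input: |delta E| equals the difference of the dual
        # static-solve excursions computed independently
        model, u, kin = self._single_muscle_setup(L_s_sd=0.004)
        L_MT = 0.5 + 0.02 * math.radians(90.0)

        def static_E(L_s):
            import copy
            v = copy.deepcopy(u)
            v.L_s = L_s
            lo = static_equilibrium_fiber_length(L_MT, 0.05, v, curves)
            hi = static_equilibrium_fiber_length(L_MT, 1.0, v, curves)
            return (lo.L_M - hi.L_M) / v.L_o

        expected = abs(static_E(u.L_s + 0.004) - static_E(u.L_s))
        reports = sensitivity_analysis(
            model, curves, kin, parameters=("L_s_plus_sd",)
        )
        assert reports[0].per_muscle_delta["toy"] == pytest.approx(
            expected, abs=1e-9
        )

    def test_sensitivity_symmetry_for_locally_linear_muscle(self, curves):
        model, u, kin = self._single_muscle_setup(L_s_sd=0.001)
        reports = {
            r.parameter: r for r in sensitivity_analysis(
                model, curves, kin, parameters=("L_s_plus_sd", "L_s_minus_sd")
            )
        }
        plus = reports["L_s_plus_sd"].per_muscle_delta["toy"]
        minus = reports["L_s_minus_sd"].per_muscle_delta["toy"]
        assert plus == pytest.approx(minus, rel=0.2)

    def test_eps_variants_move_compliant_excursions(self, curves):
        model, u, kin = self._single_muscle_setup()
        reports = sensitivity_analysis(
            model, curves, kin, parameters=("eps_2pct", "eps_9pct")
        )
        assert all(r.per_muscle_delta["toy"] > 0 for r in reports)
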