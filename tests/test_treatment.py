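"""Treatment layer: photon yield chain, compensation coefficient,
survival laws and the kill bookkeeping."""

import numpy as np
import pytest

from xpdt import (ParamSet, RandomStream, TreatmentPlan, apply_xpdt,
                  calibrate_eta, census, kill_probability, load_config,
                  pdt_kill, repair_normal, rt_survival, scintillation_density,
                  singlet_oxygen)
from xpdt.cells import NORMAL, PROLIF, QUIESC, TREATED, TUMOR
from xpdt.simulate import initialize_state, make_fixture

CO2_REF = 5.2e-6


@pytest.fixture
def params():
    return ParamSet()


def make_plan(params, d=4.0, C=4.0, **kw):
    return TreatmentPlan.from_params(params, d, C, **kw)


class TestScintillation:
    def test_reference_plan_photon_density(self, params):
        # 4 Gy, 4 mg/ml, Y=1e5, unit cross-section ratio
        plan = make_plan(params)
        assert scintillation_density(plan) == pytest.approx(9.92e12, rel=1e-12)

    def test_zero_dose_no_photons(self, params):
        assert scintillation_density(make_plan(params, d=0.0)) == 0.0

    @pytest.mark.parametrize("field", ["d", "C_sc", "Y_sc"])
    def test_linear_in_each_factor(self, params, field):
        plan = make_plan(params)
        doubled = make_plan(params, **{
            "d": plan.d * 2 if field == "d" else plan.d,
            "C": plan.C_sc * 2 if field == "C_sc" else plan.C_sc,
        })
        if field == "Y_sc":
            doubled = make_plan(params, Y_sc=plan.Y_sc * 2)
        assert scintillation_density(doubled) == \
            pytest.approx(2 * scintillation_density(plan))


class TestSingletOxygen:
    def test_no_oxygen_no_singlet_oxygen(self, params):
        c, n = singlet_oxygen(make_plan(params), 0.0)
        assert c == 0.0 and n == 0.0

    def test_half_saturation_at_kp_over_kot(self, params):
        plan = make_plan(params)
        c, _ = singlet_oxygen(plan, 11.9e-6)
        assert c == pytest.approx(0.5 * scintillation_density(plan))

    def test_per_cell_yield_at_reference_oxygen(self, params):
        # 9.92e12 * (5.2/17.1) * 2e-8 per cell
        _, n = singlet_oxygen(make_plan(params), CO2_REF)
        assert n == pytest.approx(6.03e4, rel=2e-3)


class TestCompensationCoefficient:
    def test_reference_yield_scaled_exactly_to_threshold(self, params):
        plan = make_plan(params)
        eta = calibrate_eta(plan)
        _, n_ref = singlet_oxygen(plan, CO2_REF)
        assert eta * n_ref == pytest.approx(plan.N_th, rel=1e-12)

    def test_eta_value(self, params):
        assert calibrate_eta(make_plan(params)) == pytest.approx(663.0, rel=2e-3)

    def test_yield_equal_threshold_gives_eta_one(self, params):
        plan = make_plan(params)
        _, n_ref = singlet_oxygen(plan, CO2_REF)
        plan2 = make_plan(params, N_th=float(n_ref))
        assert calibrate_eta(plan2) == pytest.approx(1.0)

    def test_zero_reference_yield_raises(self, params):
        from xpdt.treatment import CalibrationError
        plan = make_plan(params, d=0.0)
        with pytest.raises(CalibrationError):
            calibrate_eta(plan)


class TestSurvivalLaw:
    def test_closed_forms(self, params):
        # SF(0,4) = exp(-0.168), SF(4,4) = exp(-2.8*0.168)
        assert np.exp(-(1 + 0.45 * 0) * (0.002 * 4 + 0.01 * 16)) == \
            pytest.approx(0.8455, abs=2e-4)
        assert np.exp(-(1 + 0.45 * 4) * (0.002 * 4 + 0.01 * 16)) == \
            pytest.approx(0.6248, abs=2e-4)

    def test_zero_dose_kills_nobody(self, params):
        lat, par, rng = load_config({"nx": 32, "ny": 32, "vascularized": False})
        state = initialize_state(lat, par, rng)
        plan = make_plan(par, d=0.0, C=0.0)
        before = census(state.grid)
        rt_survival(plan, state.grid, rng, par)
        assert census(state.grid) == before

    def test_monte_carlo_matches_closed_form(self, params):
        """Kill fraction over ~1e4 identical quiescent cells within
        3 binomial standard errors of 1 - SF."""
        lat, par, rng = load_config({"nx": 101, "ny": 101,
                                     "vascularized": False,
                                     "normal_density": 0.0})
        state = initialize_state(lat, par, rng)
        g = state.grid
        g.kind[:, :] = TUMOR
        g.state[:, :] = QUIESC
        n = g.kind.size
        plan = make_plan(par, d=4.0, C=4.0)
        killed = rt_survival(plan, g, rng, par)["tumor"]
        p = 1 - 0.6248
        se = np.sqrt(p * (1 - p) / n)
        assert killed / n == pytest.approx(p, abs=3 * se)

    def test_phase_sensitivity_ordering(self, params):
        """G2/M proliferative cells die more than G1 under the same dose."""
        lat, par, rng = load_config({"nx": 101, "ny": 101,
                                     "vascularized": False,
                                     "normal_density": 0.0,
                                     "beta": 1e-6})  # isolate the alpha term
        par.validate()
        state = initialize_state(lat, par, rng)
        kills = {}
        for phase in (0, 2):
            g = state.grid.copy()
            g.kind[:, :] = TUMOR
            g.state[:, :] = PROLIF
            g.phase[:, :] = phase
            plan = TreatmentPlan.from_params(par, 8.0, 0.0)
            kills[phase] = rt_survival(plan, g, RandomStream(4), par)["tumor"]
        assert kills[2] > kills[0]


class TestPdtKill:
    def test_no_yield_no_kills(self, params):
        state = make_fixture("tiny-tumor")
        plan = make_plan(state.params, d=0.0)
        plan.eta_c = 1.0
        out = pdt_kill(plan, state.fields.C_O2, state.grid, state.rng)
        assert out["tumor"] == 0 and out["normal"] == 0

    def test_hypoxic_core_protected(self):
        state = make_fixture("hypoxic-core")
        plan = make_plan(state.params)
        calibrate_eta(plan)
        core = state.fields.C_O2 == 0.0
        pdt_kill(plan, state.fields.C_O2, state.grid, state.rng)
        assert not np.any(state.grid.state[core] == TREATED)

    def test_uniform_oxic_uniform_probability(self):
        state = make_fixture("uniform-oxic")
        plan = make_plan(state.params)
        calibrate_eta(plan)
        p = kill_probability(plan, state.fields.C_O2)
        assert np.unique(p).size == 1

    def test_oxygen_multiplier_monotonicity(self):
        """Mean tumor kill probability is nondecreasing in the background
        oxygen multiplier (0.125x .. 4x reference)."""
        state = make_fixture("hypoxic-core")
        plan = make_plan(state.params)
        calibrate_eta(plan)
        base = state.fields.C_O2
        means = [kill_probability(plan, base * m).mean()
                 for m in (0.125, 0.5, 1, 2, 4)]
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_saturation_vascularized_converges_to_uniform(self):
        """At very high background oxygen the kill map saturates and the
        heterogeneous (vascularized-like) and homogeneous maps agree."""
        state = make_fixture("hypoxic-core")
        plan = make_plan(state.params)
        calibrate_eta(plan)
        hetero = state.fields.C_O2 + 0.1 * CO2_REF  # no true zeros
        homo = np.full_like(hetero, CO2_REF)
        m = 1e4
        p_het = kill_probability(plan, hetero * m)
        p_hom = kill_probability(plan, homo * m)
        np.testing.assert_allclose(p_het, p_hom, atol=1e-3)

    def test_one_hit_law_below_linear(self):
        state = make_fixture("uniform-oxic")
        plan_lin = make_plan(state.params)
        calibrate_eta(plan_lin)
        plan_hit = make_plan(state.params, kill_law="one_hit",
                             eta_c=plan_lin.eta_c)
        p_lin = kill_probability(plan_lin, CO2_REF * np.ones(3))
        p_hit = kill_probability(plan_hit, CO2_REF * np.ones(3))
        assert np.all(p_hit <= p_lin + 1e-12)


class TestApplyXpdt:
    def test_null_plan_changes_nothing(self):
        state = make_fixture("tiny-tumor")
        before = census(state.grid)
        plan = make_plan(state.params, d=0.0, C=0.0)
        plan.eta_c = 663.0
        out = apply_xpdt(state.grid, state.fields.C_O2, plan, state.rng,
                         state.params)
        assert census(state.grid) == before
        assert out.viability("tumor") == 100.0

    def test_combined_kill_at_least_each_component(self):
        """Independent mechanisms: combined kill >= max single kill."""
        state = make_fixture("uniform-oxic")
        g = state.grid
        g.kind[:, :] = TUMOR
        g.state[:, :] = QUIESC
        plan = make_plan(state.params)
        calibrate_eta(plan)
        results = {}
        for mech in (("pdt",), ("rt",), ("pdt", "rt")):
            gg = g.copy()
            out = apply_xpdt(gg, state.fields.C_O2, plan,
                             RandomStream(5), state.params, mechanisms=mech)
            results[mech] = 100 - out.viability("tumor")
        assert results[("pdt", "rt")] >= max(results[("pdt",)],
                                             results[("rt",)]) - 1.0

    def test_outcome_accounting_consistent(self):
        state = make_fixture("uniform-oxic")
        plan = make_plan(state.params)
        calibrate_eta(plan)
        out = apply_xpdt(state.grid, state.fields.C_O2, plan, state.rng,
                         state.params)
        killed = sum(out.killed[m]["tumor"] for m in out.killed)
        c = census(state.grid)
        assert killed == c["tumor"]["treated"]
        assert out.viability("tumor") == pytest.approx(
            100 * (out.totals["tumor"] - killed) / out.totals["tumor"])


class TestRepair:
    def _treated_grid(self):
        state = make_fixture("uniform-oxic")
        plan = make_plan(state.params)
        calibrate_eta(plan)
        apply_xpdt(state.grid, state.fields.C_O2, plan, state.rng,
                   state.params)
        return state

    def test_no_repair_before_delay(self):
        state = self._treated_grid()
        before = census(state.grid)
        assert repair_normal(state.grid, elapsed_days=2.0) == 0
        assert census(state.grid) == before

    def test_normal_cells_restored_after_delay(self):
        state = self._treated_grid()
        assert census(state.grid)["normal"]["treated"] > 0
        repair_normal(state.grid, elapsed_days=4.16)
        assert census(state.grid)["normal"]["treated"] == 0

    def test_tumor_cells_never_repair(self):
        state = self._treated_grid()
        t_before = census(state.grid)["tumor"]["treated"]
        repair_normal(state.grid, elapsed_days=100.0)
        assert census(state.grid)["tumor"]["treated"] == t_before
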