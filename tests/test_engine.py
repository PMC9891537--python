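"""Integration accuracy, sweeps and coupled-cell behaviour."""

import numpy as np
import pytest

from notchdimer import (
    ExternalSignal,
    ModelParameters,
    ValidationError,
    cis_activation_run,
    compartment_sweep,
    dimerization_sweep,
    integrate,
    interior_peak,
    ligand_pulse_dynamics,
    mi_steady_state,
    normalize_activity,
    oligomer_sweep,
    production_sweep,
    t1_rhs,
    t1_steady_state,
    two_cell_production_sweep,
    two_cell_steady_state,
)

NONE = ExternalSignal()


class TestIntegrate:
    def test_exponential_decay_against_closed_form(self):
        # pure decay: L(t) = 100 exp(-0.1 t); half-life ~ 7 h
        p = ModelParameters(b_L=0.0, b_N=0.0, k_d=0.0)
        grid = np.linspace(0, 50, 51)
        traj = integrate(t1_rhs, (100.0, 0.0, 0.0, 0.0), NONE, p, (0, 50), grid)
        np.testing.assert_allclose(traj["L"], 100.0 * np.exp(-0.1 * grid), rtol=1e-6, atol=1e-8)
        assert np.interp(np.log(2) / 0.1, grid, traj["L"]) == pytest.approx(50.0, rel=1e-3)

    def test_converges_to_closed_form_steady_state(self, baseline_t1, trans_bath):
        traj = integrate(t1_rhs, np.zeros(4), trans_bath, baseline_t1, (0, 2000))
        np.testing.assert_allclose(traj.final, t1_steady_state(baseline_t1, trans_bath),
                                   rtol=1e-5)

    def test_zero_length_span_returns_init(self, baseline_t1):
        traj = integrate(t1_rhs, (1.0, 2.0, 3.0, 4.0), NONE, baseline_t1, (5.0, 5.0))
        assert traj.times.tolist() == [5.0]
        np.testing.assert_array_equal(traj.states, [[1.0, 2.0, 3.0, 4.0]])

    def test_rejects_negative_init(self, baseline_t1):
        with pytest.raises(ValidationError):
            integrate(t1_rhs, (-1.0, 0, 0, 0), NONE, baseline_t1, (0, 1))


class TestNormalizeActivity:
    def test_scales_to_unit_max(self):
        np.testing.assert_allclose(normalize_activity([1, 2, 4]), [0.25, 0.5, 1.0])

    def test_singleton(self):
        np.testing.assert_allclose(normalize_activity([5.0]), [1.0])

    def test_idempotent(self):
        once = normalize_activity([0.2, 3.0, 1.7])
        np.testing.assert_array_equal(normalize_activity(once), once)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            normalize_activity([0.0, 0.0])


GRID = np.linspace(0, 4000, 7)


class TestProductionSweep:
    @pytest.mark.parametrize("config", ["C1", "C2", "C3"])
    def test_cis_ligand_inhibits_activity(self, config):
        res = production_sweep(config, GRID)
        assert np.all(np.diff(res.activity) <= 1e-9 * res.activity.max())

    def test_no_cis_ligand_limit(self):
        # b_L = 0 in the bath: S = k_t * 1500 * N / beta_S with N = b_N/beta2
        res = production_sweep("C1", np.array([0.0]))
        p = ModelParameters.cis_config("C1")
        beta2 = p.beta + p.k1 * 1500.0
        expected = p.k1 * 1500.0 * (p.b_N / beta2) / p.beta_S
        assert res.activity[0] == pytest.approx(expected, rel=1e-6)

    def test_trans_sweep_monotone_increasing(self):
        res = production_sweep("T1", GRID)
        assert np.all(np.diff(res.activity) >= -1e-9 * res.activity.max())

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            production_sweep("C1", [])


class TestDimerizationSweep:
    KD = np.geomspace(1e-9, 1e-3, 7)

    def test_dimer_cis_model_recovers_without_dimers(self):
        # C1: dimer-deficient ligand fails to cis-inhibit
        res = dimerization_sweep("C1", self.KD, fixed_b_L=4000.0)
        uninhibited = production_sweep("C1", np.array([0.0])).activity[0]
        assert res.activity[0] > 0.5 * uninhibited
        assert res.activity[-1] < 0.1 * uninhibited

    def test_monomer_cis_model_stays_suppressed(self):
        # C2: monomers cis-inhibit regardless of dimerization
        res = dimerization_sweep("C2", self.KD, fixed_b_L=4000.0)
        uninhibited = production_sweep("C2", np.array([0.0])).activity[0]
        assert np.all(res.activity < 0.25 * uninhibited)

    def test_no_dimerization_equals_no_cis_inhibition(self, trans_bath):
        # C1 at k_d = 0: no dimers, hence no cis term; the receptor balance
        # is linear with N = b_N/beta2 and S = k_t * L_ext * N / beta_S
        res = dimerization_sweep("C1", np.array([0.0]), fixed_b_L=4000.0)
        p = ModelParameters.cis_config("C1")
        beta2 = p.beta + p.k1 * trans_bath.L_ext
        expected = p.k1 * trans_bath.L_ext * (p.b_N / beta2) / p.beta_S
        assert res.activity[0] == pytest.approx(expected, rel=1e-5)


class TestTwoCell:
    def test_identical_cells_stay_identical(self):
        a, b = two_cell_steady_state("T1", b_L=800.0)
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_monomer_trans_model_peaks_then_collapses(self):
        res = two_cell_production_sweep("T1", GRID)
        assert interior_peak(res.activity)
        assert res.activity[-1] < 0.25

    def test_dimer_trans_model_does_not_collapse(self):
        res = two_cell_production_sweep("T3", GRID)
        assert res.activity[-1] > 0.4


class TestCisActivationRun:
    BL = np.geomspace(10, 2e4, 9)

    def test_monomer_activation_is_nonmonotonic(self):
        res = cis_activation_run(1, self.BL)
        assert interior_peak(res.activity)
        assert res.activity[-1] < 0.10 * res.activity.max()

    def test_dimer_coactivation_resists_suppression(self):
        r1 = cis_activation_run(1, self.BL)
        r3 = cis_activation_run(3, self.BL)
        assert r3.activity[-1] > 0.25 * r3.activity.max()
        assert r3.activity[-1] > 5.0 * r1.activity[-1]

    def test_lower_dimer_affinity_boosts_activation(self):
        # weaker cis-inhibition (lower k_ci) -> stronger cis-activation
        hi = cis_activation_run(1, self.BL, k_ci=6e-4)
        lo = cis_activation_run(1, self.BL, k_ci=6e-5)
        assert lo.activity.max() > hi.activity.max()
        assert lo.activity[-1] > hi.activity[-1]

    def test_dimerization_rate_shapes_the_peak(self):
        fast = cis_activation_run(1, self.BL, k_d=1e-3)
        slow = cis_activation_run(1, self.BL, k_d=1e-5)
        # slower dimerization: peak moved to higher ligand and taller
        assert np.argmax(slow.activity) > np.argmax(fast.activity)
        assert slow.activity.max() > fast.activity.max()

    def test_no_activation_rate_no_signal(self):
        res = cis_activation_run(1, self.BL, k_ca=0.0)
        np.testing.assert_allclose(res.activity, 0.0, atol=1e-12)


class TestLigandPulse:
    def test_initial_state_and_ligand_budget(self):
        traj = ligand_pulse_dynamics()
        np.testing.assert_array_equal(traj.states[0], [500.0, 9500.0, 0.0, 0.0])
        total = traj["L"] + 2.0 * traj["Lstar"]
        assert np.all(np.diff(total) <= 1e-6 * total[0])

    def test_delayed_onset_then_full_activation(self, baseline_t1, trans_bath):
        traj = ligand_pulse_dynamics(t_span=(0.0, 400.0))
        S = traj["S"]
        early = np.interp(5.0, traj.times, S)
        # dimer store exhausts; S approaches the no-ligand steady state
        final_expected = t1_steady_state(baseline_t1.with_(b_L=1e-12), trans_bath)[3]
        assert early < 0.1 * final_expected
        assert S[-1] == pytest.approx(final_expected, rel=1e-3)


class TestOligomerAndCompartment:
    BL = np.geomspace(10, 2e4, 6)

    @pytest.mark.parametrize("setting,shape", [
        ("fixed-trans", "decreasing"),
        ("two-cell", "peaked"),
        ("single-cell", "peaked"),
    ])
    def test_shape_invariant_across_oligomer_size(self, setting, shape):
        for n in (2, 3, 4):
            res = oligomer_sweep(setting, n, self.BL)
            if shape == "decreasing":
                assert np.all(np.diff(res.activity) <= 1e-9)
            else:
                assert interior_peak(res.activity)

    def test_cytoplasmic_cis_inhibition_is_at_least_as_strong(self):
        homog = compartment_sweep("fixed-trans", "homogeneous", self.BL, normalized=False)
        cyto = compartment_sweep("fixed-trans", "cytoplasmic", self.BL, normalized=False)
        assert np.all(cyto.activity <= homog.activity * (1 + 1e-9))

    def test_fast_transport_drains_cytoplasm(self):
        # k_r >> beta: cytoplasmic monomer pool empties into the membrane
        from notchdimer import compartment_rhs, numeric_fixed_point
        p = ModelParameters.t1(k_r=100.0)
        y = numeric_fixed_point(compartment_rhs, p, NONE, init=np.zeros(6))
        assert y[0] < 0.02 * p.b_L / p.beta
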