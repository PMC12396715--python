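import math

import numpy as np
import pytest

from trnsim import kernels
from trnsim.constants import rt_over_f_mv
from trnsim.ion_dynamics import (IonState, glial_and_vascular_k_exchange,
                                 ion_concentration_derivatives,
                                 nernst_potential,
                                 pump_and_cotransport_currents,
                                 update_reversal_potentials)


class TestNernst:
    def test_symmetric_concentrations_give_zero(self):
        assert nernst_potential(1, 10.0, 10.0, 310.0) == pytest.approx(0.0)

    def test_physiological_potassium(self):
        # RT/zF ln(4/140) at 310 K with R=8.314, F=96485
        e = nernst_potential(1, 140.0, 4.0, 310.0)
        assert e == pytest.approx(-94.96, abs=0.1)

    def test_valence_scaling(self):
        e1 = nernst_potential(1, 140.0, 4.0, 310.0)
        e2 = nernst_potential(2, 140.0, 4.0, 310.0)
        assert e2 == pytest.approx(e1 / 2.0)

    @pytest.mark.parametrize("ci,co", [(0.0, 4.0), (140.0, -1.0)])
    def test_nonpositive_concentration_names_ion(self, ci, co):
        with pytest.raises(ValueError, match="K"):
            nernst_potential(1, ci, co, ion="K")

    def test_zero_valence_rejected(self):
        with pytest.raises(ValueError):
            nernst_potential(0, 1.0, 2.0)


class TestReversalPotentials:
    def test_resting_values(self, params):
        rev = update_reversal_potentials(IonState(), params)
        assert rev.E_K < -80.0
        assert rev.E_Ca > 100.0
        assert rev.E_Na > 0.0
        assert rev.E_Cl < 0.0

    def test_doubling_bath_calcium_shifts_by_half_rtf_ln2(self, params):
        ions = IonState()
        r1 = update_reversal_potentials(ions, params)
        r2 = update_reversal_potentials(ions.replace(Ca_o=2 * ions.Ca_o),
                                        params)
        expected = rt_over_f_mv(params.temperature) / 2.0 * math.log(2.0)
        assert r2.E_Ca - r1.E_Ca == pytest.approx(expected)

    def test_deterministic(self, params):
        ions = IonState()
        assert update_reversal_potentials(ions, params) == \
            update_reversal_potentials(ions, params)


class TestConcentrationDerivatives:
    def test_zero_currents_zero_derivatives(self, params):
        d = ion_concentration_derivatives(IonState(), {}, {}, params)
        assert all(v == 0.0 for v in d.values())

    def test_potassium_efflux_signs_and_volume_ratio(self, params):
        d = ion_concentration_derivatives(IonState(), {"K": 2.0}, {}, params)
        assert d["K_i"] < 0 < d["K_o"]
        assert d["K_o"] / -d["K_i"] == pytest.approx(params.vol_ratio)

    def test_linearity_in_current(self, params):
        d1 = ion_concentration_derivatives(IonState(), {"Na": 1.0}, {},
                                           params)
        d2 = ion_concentration_derivatives(IonState(), {"Na": 2.0}, {},
                                           params)
        assert d2["Na_i"] == pytest.approx(2 * d1["Na_i"])

    def test_unknown_species_rejected(self, params):
        with pytest.raises(ValueError, match="Mg"):
            ion_concentration_derivatives(IonState(), {"Mg": 1.0}, {},
                                          params)

    def test_chloride_sign_convention(self, params):
        # outward Cl current = anion influx
        d = ion_concentration_derivatives(IonState(), {"Cl": 1.0}, {},
                                          params)
        assert d["Cl_i"] > 0


class TestGliaVasculature:
    def test_equilibrium_fluxes_vanish(self, params):
        # bath K with the glial buffer at its balance point
        k_o = params.k_bath
        uptake = float(kernels.glial_uptake(k_o, params.glia_max,
                                            params.glia_k_half,
                                            params.glia_k_slope))
        k_glia_eq = uptake / params.glia_release
        j_glia, j_vasc = glial_and_vascular_k_exchange(k_o, k_glia_eq, params)
        assert j_vasc == pytest.approx(0.0, abs=1e-12)
        assert j_glia == pytest.approx(0.0, abs=1e-12)

    def test_raised_potassium_is_removed_by_both_paths(self, params):
        j_glia, j_vasc = glial_and_vascular_k_exchange(
            params.k_bath + 5.0, 20.0, params)
        assert j_vasc > 0
        assert j_glia > 0

    def test_zero_diffusion_constant(self, params):
        p = params.replace(eps_k=0.0)
        _, j_vasc = glial_and_vascular_k_exchange(10.0, 20.0, p)
        assert j_vasc == 0.0


class TestPumpAndCotransport:
    def test_zero_pump_scale(self, params):
        p = params.replace(rho_pump=0.0)
        cur = pump_and_cotransport_currents(IonState(), -69.0, p)
        assert cur["Na"] == cur["K"] == cur["net"] == 0.0

    def test_stoichiometry_three_to_two(self, params):
        cur = pump_and_cotransport_currents(IonState(), -69.0, params)
        assert cur["Na"] == pytest.approx(-1.5 * cur["K"])
        assert cur["net"] == pytest.approx(cur["Na"] + cur["K"])
        assert cur["net"] > 0  # net outward

    def test_pump_increases_with_internal_sodium(self, params):
        vals = [pump_and_cotransport_currents(
            IonState(Na_i=na), -69.0, params)["net"]
            for na in (10.0, 15.0, 20.0, 30.0)]
        assert np.all(np.diff(vals) > 0)

    def test_kcc2_zero_at_product_equilibrium(self, params):
        ions = IonState(K_i=140.0, Cl_i=130.0 * 3.0 / 140.0,
                        K_o=3.0, Cl_o=130.0)
        cur = pump_and_cotransport_currents(ions, -69.0, params)
        assert cur["KCC2"] == pytest.approx(0.0, abs=1e-12)

    def test_kcc2_extrudes_when_internal_product_higher(self, params):
        cur = pump_and_cotransport_currents(IonState(), -69.0, params)
        assert cur["KCC2"] > 0


class TestChargeBookkeeping:
    def test_current_integral_matches_concentration_change(self, params,
                                                           rest_state):
        """Over 10 ms, the integral of each ionic current (converted by
        gamma/valence) equals the net concentration change, with the
        non-electrogenic transport paths switched off."""
        from trnsim.trn_cell import (SolverConfig, StimulusProtocol,
                                     integrate)
        from trnsim.state import IDX_NAI, IDX_KI
        p = params.replace(kcc2_rate=0.0, glia_max=0.0, glia_release=0.0,
                           eps_k=0.0)
        y0, _ = rest_state
        solver = SolverConfig(rtol=1e-9, atol=1e-12, sample_dt=0.01)
        tr = integrate(y0, StimulusProtocol([]), (0.0, 10.0), p, solver)
        cur = tr.current_channels()
        i_na = (cur["I_Na"] + 3.0 * cur["I_pump"] + 3.0 * cur["I_NCX"]
                + p.can_na_frac * cur["I_CAN"])
        i_k = (cur["I_K"] + cur["I_KCa"] - 2.0 * cur["I_pump"]
               + (1.0 - p.can_na_frac) * cur["I_CAN"])
        g = p.gamma_conv
        pred_na = -g * np.trapezoid(i_na, tr.t)
        pred_k = -g * np.trapezoid(i_k, tr.t)
        assert tr.y[-1, IDX_NAI] - tr.y[0, IDX_NAI] == \
            pytest.approx(pred_na, abs=1e-6)
        assert tr.y[-1, IDX_KI] - tr.y[0, IDX_KI] == \
            pytest.approx(pred_k, abs=1e-6)
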