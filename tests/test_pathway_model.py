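"""Rate laws, integration, conservation and yield accounting."""

import numpy as np
import pytest

from biapath.pathway_model import (
    EnzymeParams, PathwayConfigError, PathwayState, PathwaySpec,
    PathwayValidationError, Topology, condensation_rate, ddc_rate,
    dhpaas_rates, dopa_conservation_residual, feed_term, mao_rate, simulate,
    thp_yield_pct)


class TestRateLaws:
    def test_ddc_rate_half_saturation_and_inhibition(self, mao_spec):
        # no substrate -> zero; S = Km -> Vmax/2; competitive DA feedback
        assert ddc_rate(PathwayState(S=0.0), mao_spec) == 0.0
        v = ddc_rate(PathwayState(S=0.1), mao_spec)
        assert v == pytest.approx(5.0)
        fb = mao_spec.copy()
        fb.feedback = True
        # S = 2Km, DA = Ki -> Km_eff = 2Km -> Vmax*2Km/(2Km+2Km) = Vmax/2
        v_fb = ddc_rate(PathwayState(S=0.2, DA=0.1), fb)
        assert v_fb == pytest.approx(5.0)

    def test_ddc_rate_requires_block(self, single_dhpaas_spec):
        with pytest.raises(PathwayConfigError):
            ddc_rate(PathwayState(S=1.0), single_dhpaas_spec)

    def test_mao_rate_amine_competition(self, mao_spec):
        assert mao_rate(PathwayState(DA=0.0), mao_spec) == 0.0
        clean = mao_spec.copy()
        clean.amine_pool = 0.0
        assert mao_rate(PathwayState(DA=0.2), clean) == pytest.approx(0.25)
        # DA = Km, amine_pool = Ki -> Vmax*Km/(2Km + Km) = Vmax/3
        third = mao_spec.copy()
        third.amine_pool = 0.1
        assert mao_rate(PathwayState(DA=0.2), third) == pytest.approx(0.5 / 3)

    def test_mao_rate_wrong_topology(self, single_dhpaas_spec):
        with pytest.raises(PathwayConfigError):
            mao_rate(PathwayState(DA=1.0), single_dhpaas_spec)

    @pytest.mark.parametrize("phi,expected", [
        (1.0, (2.5, 0.0)),
        (0.0, (0.0, 2.5)),
    ])
    def test_dhpaas_pure_branches(self, single_dhpaas_spec, phi, expected):
        spec = single_dhpaas_spec.copy()
        spec.phi_aldehyde = phi
        rates = dhpaas_rates(PathwayState(S=0.05), spec)
        assert rates == pytest.approx(expected)

    def test_dhpaas_saturation_partition(self, single_dhpaas_spec):
        # S >> Km with the wild-type 95% aldehyde partition
        spec = single_dhpaas_spec.copy()
        spec.phi_aldehyde = 0.95
        v_ald, v_dec = dhpaas_rates(PathwayState(S=50.0), spec)
        assert v_ald == pytest.approx(0.95 * 5.0, rel=2e-3)
        assert v_dec == pytest.approx(0.05 * 5.0, rel=2e-3)
        assert v_ald + v_dec == pytest.approx(
            spec.dhpaas.rate(50.0), abs=1e-12)

    def test_phi_validation(self):
        with pytest.raises(PathwayValidationError):
            PathwaySpec(topology=Topology.SINGLE_DHPAAS_PATH,
                        dhpaas=EnzymeParams(vmax=1, km=1), phi_aldehyde=1.5)

    def test_condensation_mass_action(self, condensation_only_spec):
        spec = condensation_only_spec.copy()
        spec.k_cond = 1.0
        assert condensation_rate(PathwayState(DA=0, AL=3), spec) == 0.0
        assert condensation_rate(PathwayState(DA=2, AL=3), spec) == 6.0
        # second order: doubling both reactants quadruples the rate
        r1 = condensation_rate(PathwayState(DA=1.5, AL=2.5), spec)
        r2 = condensation_rate(PathwayState(DA=3.0, AL=5.0), spec)
        assert r2 == pytest.approx(4 * r1)
        with pytest.raises(PathwayValidationError):
            condensation_rate(PathwayState(DA=-1, AL=1), spec)

    def test_feed_term_switches_at_cap(self, single_dhpaas_spec):
        spec = single_dhpaas_spec
        assert feed_term(PathwayState(fed=0.0), spec) == spec.feed_rate
        assert feed_term(PathwayState(fed=spec.feed_cap), spec) == 0.0


class TestTopologyValidation:
    def test_missing_required_blocks(self):
        with pytest.raises(PathwayConfigError):
            PathwaySpec(topology=Topology.MAO_PATH,
                        ddc=EnzymeParams(vmax=1, km=1))  # no mao
        with pytest.raises(PathwayConfigError):
            PathwaySpec(topology=Topology.DDC_DHPAAS_PATH,
                        dhpaas=EnzymeParams(vmax=1, km=1))  # no ddc

    def test_enzyme_params_domains(self):
        with pytest.raises(PathwayValidationError):
            EnzymeParams(vmax=-1, km=1)
        with pytest.raises(PathwayValidationError):
            EnzymeParams(vmax=1, km=0)
        with pytest.raises(PathwayValidationError):
            EnzymeParams(vmax=1, km=1, ki={"dopamine": 0.0})


class TestSimulate:
    def test_null_dynamics_constant_state(self):
        spec = PathwaySpec(topology=Topology.SINGLE_DHPAAS_PATH,
                           dhpaas=EnzymeParams(vmax=0.0, km=1.0),
                           k_cond=0.0, feed_rate=0.0)
        ini = PathwayState(S=1.0, DA=0.5, AL=0.25, T=0.1)
        traj = simulate(spec, ini, t_end=10.0)
        for name, val in (("S", 1.0), ("DA", 0.5), ("AL", 0.25), ("T", 0.1)):
            assert np.allclose(getattr(traj, name), val, atol=1e-9)

    def test_condensation_closed_form(self, condensation_only_spec):
        # dDA/dt = -k*DA^2 when DA == AL: DA(t) = c0/(1 + k*c0*t)
        c0, k = 2.0, condensation_only_spec.k_cond
        traj = simulate(condensation_only_spec,
                        PathwayState(DA=c0, AL=c0), t_end=10.0)
        idx = np.linspace(0, len(traj) - 1, 10).astype(int)
        exact = c0 / (1.0 + k * c0 * traj.t[idx])
        assert np.max(np.abs(traj.DA[idx] - exact) / exact) < 1e-5

    def test_feed_cap_piecewise_integral(self, single_dhpaas_spec):
        # feed 4 mM/h against a 100 mM cap: cap binds at t=25, fed(50)=100
        spec = single_dhpaas_spec.copy()
        spec.feed_rate = 4.0
        traj = simulate(spec, t_end=50.0)
        assert traj.final.fed == pytest.approx(100.0, abs=1e-6)
        mid = np.searchsorted(traj.t, 12.5)
        assert traj.fed[mid] == pytest.approx(4.0 * traj.t[mid], rel=1e-8)
        assert np.max(traj.fed) <= 100.0 + 1e-6

    def test_monotonic_cumulative_quantities(self, mao_spec):
        spec = mao_spec.copy()
        spec.k_drain = 1.0
        traj = simulate(spec, t_end=50.0)
        for name in ("T", "fed", "drained"):
            assert np.all(np.diff(getattr(traj, name)) >= -1e-9), name

    def test_trajectory_contract(self, single_dhpaas_spec):
        ini = PathwayState(S=1.0)
        traj = simulate(single_dhpaas_spec, ini, t_end=50.0)
        assert np.all(np.diff(traj.t) > 0)
        assert traj.initial.S == pytest.approx(1.0)
        assert traj.t[0] == 0.0 and traj.t[-1] == 50.0
        assert len(traj) == 501

    def test_invalid_t_end(self, single_dhpaas_spec):
        with pytest.raises(PathwayValidationError):
            simulate(single_dhpaas_spec, t_end=0.0)


class TestYield:
    def test_yield_from_printed_worked_values(self, condensation_only_spec):
        # 9.45 µM THP from 1 mM L-DOPA -> 1.89%; complete conversion -> 100%
        traj = simulate(condensation_only_spec, PathwayState(DA=1, AL=1),
                        t_end=1.0)
        traj.T[-1] = 0.00945
        traj.S[:] = 0.0
        traj.DA[0] = 0.5
        traj.AL[0] = 0.5
        assert thp_yield_pct(traj) == pytest.approx(1.89)
        traj.T[-1] = 0.5
        assert thp_yield_pct(traj) == pytest.approx(100.0)

    def test_yield_bounds_and_errors(self, single_dhpaas_spec):
        traj = simulate(single_dhpaas_spec, t_end=50.0)
        assert 0.0 <= thp_yield_pct(traj) <= 100.0
        null = simulate(single_dhpaas_spec.copy(), PathwayState(), t_end=1.0)
        null.fed[:] = 0.0
        null.spec.feed_rate = 0.0
        with pytest.raises(PathwayValidationError):
            thp_yield_pct(null)


def test_balance_property_phi_scan(single_dhpaas_spec):
    """Yield of the single-enzyme pathway peaks at the 50/50 product split."""
    phis = np.round(np.arange(0.05, 0.96, 0.05), 2)
    yields = []
    for phi in phis:
        spec = single_dhpaas_spec.copy()
        spec.phi_aldehyde = float(phi)
        yields.append(thp_yield_pct(simulate(spec, t_end=50.0)))
    yields = np.asarray(yields)
    assert phis[int(np.argmax(yields))] == pytest.approx(0.5)
    # and the scan is symmetric: phi and 1-phi give the same yield
    assert np.allclose(yields, yields[::-1], rtol=1e-6)


def test_conservation_across_topologies(single_dhpaas_spec, mao_spec):
    for spec in (single_dhpaas_spec, mao_spec):
        drained = spec.copy()
        drained.k_drain = 0.5
        traj = simulate(drained, t_end=50.0)
        assert dopa_conservation_residual(traj) < 1e-6


def test_spec_dict_round_trip(mao_spec):
    again = PathwaySpec.from_dict(mao_spec.to_dict())
    assert again.to_dict() == mao_spec.to_dict()
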