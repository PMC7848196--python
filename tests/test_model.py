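"""Model core: right-hand side, forward simulation, structural properties."""

import numpy as np
import pytest

import circabp as c
from circabp.exceptions import DomainError, InvalidConfigError
from circabp.model import rhs, state_jacobian, svr_production

from conftest import constant_inputs


def make_params(**kw):
    defaults = dict(k1=614.7, n=2.472, ki1=801.3, ki2=3861.0, ki3=805.3,
                    ki4=24.79, k2=7654.0)
    defaults.update(kw)
    return c.ParameterSet(**defaults)


class TestRhs:
    def test_sbp_steady_state_cancellation(self):
        # SBP = SVR*HR/(ki3+HR) makes the pressure drive vanish
        p = make_params(ki3=805.3)
        sbp = 1500.0 * 70.0 / (805.3 + 70.0)
        assert sbp == pytest.approx(119.96, abs=0.01)
        d = rhs([1500.0, sbp, 70.0, 80.0], 0.0, p, constant_inputs())
        assert d[1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_activity_hr_decays(self):
        p = make_params()
        d = rhs([300.0, 50.0, 70.0, 40.0], 0.0, p,
                constant_inputs(a=0.0))
        assert d[2] == pytest.approx(-p.k4 * 40.0 * 70.0)
        assert d[2] < 0

    def test_vanishing_ne_drive_svr_decays(self):
        # as NE -> 0+ the production term vanishes and SVR strictly decays
        p = make_params()
        tiny = 1e-12
        assert svr_production(p, 100.0, tiny, 5.0) < 1e-10
        d = rhs([300.0, 50.0, 70.0, 40.0], 0.0, p,
                constant_inputs(ne=tiny))
        assert d[0] < 0

    def test_nonpositive_glc_is_domain_error(self):
        with pytest.raises(DomainError):
            constant_inputs(glc=0.0)

    def test_steady_state_quadratic_root(self):
        # independent oracle: positive root of SVR^2 - P*SVR - P*ki2 = 0
        p = make_params()
        P = svr_production(p, 100.0, 2.5, 5.0)
        assert P == pytest.approx(24.4, abs=0.1)
        roots = np.roots([1.0, -P, -P * p.ki2])
        svr_star = float(roots[roots > 0][0])
        assert svr_star == pytest.approx(319.4, abs=0.5)
        ss = c.steady_state(p, 100.0, 2.5, 5.0)
        assert ss["SVR"] == pytest.approx(svr_star, rel=1e-10)

    def test_unknown_dbp_variant_rejected(self):
        with pytest.raises(InvalidConfigError):
            rhs([1, 1, 1, 1], 0.0, make_params(), constant_inputs(),
                dbp_equation="bogus")

    @pytest.mark.parametrize("scale", [0.5, 1.0, 2.0])
    def test_monotone_parameter_effects(self, scale):
        # production increases with ki1; HR drive decreases with ki4
        p = make_params()
        a, ne, glc = 80.0, 2.5, 5.0
        prods = [svr_production(make_params(ki1=v), a, ne, glc)
                 for v in (p.ki1 * scale, p.ki1 * scale * 1.5)]
        assert prods[1] > prods[0]
        drives = [make_params(ki4=v).k2 * a / (v + a)
                  for v in (p.ki4 * scale, p.ki4 * scale * 1.5)]
        assert drives[1] < drives[0]


class TestSimulate:
    def test_fixed_point_preserved(self):
        p = make_params()
        ins = constant_inputs()
        ss = c.steady_state(p, 100.0, 2.5, 5.0)
        init = np.array([ss[n] for n in c.STATE_NAMES])
        traj = c.simulate(p, ins, init, ins.grid, rtol=1e-8, atol=1e-10)
        for name in c.STATE_NAMES:
            assert np.max(np.abs(traj[name] - ss[name])) <= \
                10 * (1e-8 * abs(ss[name]) + 1e-10)

    def test_pulse_pressure_conserved_as_printed(self, dipper_trajectory):
        pp = dipper_trajectory["DBP"] - dipper_trajectory["SBP"]
        scale = np.max(np.abs(dipper_trajectory["SBP"]))
        assert np.ptp(pp) <= 10 * 1e-6 * scale

    def test_relaxed_variant_breaks_conservation(self, dipper_inputs,
                                                 dipper_init):
        traj = c.simulate(c.REFERENCE_DIPPER, dipper_inputs, dipper_init,
                          dipper_inputs.grid, dbp_equation="relaxed_to_dbp")
        pp = traj["DBP"] - traj["SBP"]
        assert np.ptp(pp) > 1.0

    def test_tolerance_convergence(self, dipper_inputs, dipper_init):
        p = c.REFERENCE_DIPPER
        grid = dipper_inputs.grid
        a = c.simulate(p, dipper_inputs, dipper_init, grid,
                       rtol=1e-6, atol=1e-9)
        b = c.simulate(p, dipper_inputs, dipper_init, grid,
                       rtol=5e-7, atol=5e-10)
        for name in c.STATE_NAMES:
            rel = np.abs(a[name] - b[name]) / np.abs(b[name])
            assert np.max(rel) < 1e-4

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_positivity_preserved(self, seed, dipper_inputs):
        rng = np.random.default_rng(seed)
        factors = 10.0 ** rng.uniform(-0.3, 0.3, size=7)
        names = ("k1", "n", "ki1", "ki2", "ki3", "ki4", "k2")
        p = c.REFERENCE_DIPPER.with_values(
            names, c.REFERENCE_DIPPER.to_array(names) * factors)
        init = c.default_initial_state(p, dipper_inputs)
        traj = c.simulate(p, dipper_inputs, init, dipper_inputs.grid)
        for name in c.STATE_NAMES:
            assert np.all(traj[name] > 0)

    def test_steady_state_oracle_under_constant_inputs(self):
        # long simulation settles onto the algebraic fixed point
        p = make_params()
        n = 48
        ins = constant_inputs(a=100.0, ne=2.5, glc=5.0, n=n)
        init = np.array([250.0, 55.0, 120.0, 40.0])
        grid = np.linspace(0.0, 400.0, 801)
        traj = c.simulate(p, ins, init, grid, rtol=1e-10, atol=1e-12)
        final = {name: traj[name][-1] for name in c.STATE_NAMES}
        pp = init[3] - init[1]  # conserved by the as-printed DBP equation
        svr, sbp, hr, dbp = (final[nme] for nme in c.STATE_NAMES)
        prod = svr_production(p, 100.0, 2.5, 5.0)
        assert svr ** 2 / (p.ki2 + svr) == pytest.approx(prod, rel=1e-6)
        assert hr == pytest.approx(
            p.k2 * 100.0 / ((p.ki4 + 100.0) * p.k4 * dbp), rel=1e-6)
        assert sbp == pytest.approx(svr * hr / (p.ki3 + hr), rel=1e-6)
        assert dbp - sbp == pytest.approx(pp, rel=1e-6)
        ss = c.steady_state(p, 100.0, 2.5, 5.0, pulse_pressure=-pp)
        for name in c.STATE_NAMES:
            assert final[name] == pytest.approx(ss[name], rel=1e-6)

    def test_invalid_init_rejected(self, dipper_inputs):
        with pytest.raises(InvalidConfigError):
            c.simulate(c.REFERENCE_DIPPER, dipper_inputs,
                       [-1.0, 50.0, 70.0, 40.0], dipper_inputs.grid)


class TestJacobians:
    def test_state_jacobian_matches_finite_differences(self):
        p = make_params()
        ins = constant_inputs()
        y0 = np.array([300.0, 50.0, 120.0, 35.0])
        J = state_jacobian(y0, 1.0, p, ins)
        h = 1e-6
        for k in range(4):
            yp, ym = y0.copy(), y0.copy()
            step = h * y0[k]
            yp[k] += step
            ym[k] -= step
            col = (rhs(yp, 1.0, p, ins) - rhs(ym, 1.0, p, ins)) / (2 * step)
            assert np.allclose(J[:, k], col, rtol=1e-5, atol=1e-8)


class TestInputSignals:
    @pytest.mark.parametrize("mode", ["pchip", "linear", "zoh"])
    def test_grid_nodes_returned_exactly(self, mode):
        grid = c.half_hour_grid()
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 100, grid.size)
        ne = rng.uniform(1, 4, grid.size)
        glc = rng.uniform(4, 8, grid.size)
        ins = c.InputSignals(grid=grid, A=a, NE=ne, glc=glc, mode=mode)
        for t_idx in (0, 7, 47):
            av, nev, gv = ins.evaluate(grid[t_idx])
            assert av == pytest.approx(a[t_idx], abs=1e-12)
            assert nev == pytest.approx(ne[t_idx], abs=1e-12)
            assert gv == pytest.approx(glc[t_idx], abs=1e-12)

    def test_pchip_stays_nonnegative(self):
        grid = c.half_hour_grid()
        rng = np.random.default_rng(2)
        a = np.where(rng.uniform(size=grid.size) < 0.4, 0.0,
                     rng.uniform(0, 100, grid.size))
        ins = c.InputSignals(grid=grid, A=a, NE=np.full(grid.size, 2.0),
                             glc=np.full(grid.size, 5.0))
        fine = np.linspace(0, 24, 4001)
        assert np.all(ins.activity(fine) >= 0)

    def test_periodic_wrap(self, dipper_inputs):
        assert dipper_inputs.activity(24.0) == \
            pytest.approx(dipper_inputs.activity(0.0))
        assert dipper_inputs.activity(25.5) == \
            pytest.approx(dipper_inputs.activity(1.5))

    def test_nonpositive_ne_rejected(self):
        grid = c.half_hour_grid()
        with pytest.raises(DomainError):
            c.InputSignals(grid=grid, A=np.zeros(48),
                           NE=np.zeros(48), glc=np.full(48, 5.0))
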