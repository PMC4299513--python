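"""Control functions, the regulated ODE, its fixed point, and stability."""

import numpy as np
import pytest

from growthlaws import (
    FixedPointError,
    find_fixed_point,
    make_control_function,
    ode_rhs,
    simulate,
    solve_steady_amino_acid,
    stability,
)
from growthlaws.io import sample_control_family


class TestMakeControlFunction:
    def test_constant_is_unregulated(self):
        chi = make_control_function("constant", value=0.3)
        assert chi.unregulated
        assert float(chi(0.0)) == float(chi(1.0)) == 0.3

    def test_hill_zero_amplitude_is_constant_valued(self):
        chi = make_control_function("hill", baseline=0.2, amplitude=0.0, K_chi=1e-3)
        a = np.logspace(-6, 0, 10)
        assert np.allclose(chi(a), 0.2)

    def test_decreasing_table_rejected(self):
        with pytest.raises(ValueError, match="supply-driven"):
            make_control_function(
                "table", a_points=[1e-5, 1e-3, 1e-1], chi_points=[0.4, 0.3, 0.2]
            )

    def test_range_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            make_control_function("hill", baseline=0.6, amplitude=0.6, K_chi=1e-3)
        with pytest.raises(ValueError):
            make_control_function("constant", value=1.2)

    def test_piecewise_linear_interpolates(self):
        chi = make_control_function(
            "piecewise-linear", a_points=[1e-4, 1e-2], chi_points=[0.1, 0.5]
        )
        assert float(chi(1e-5)) == pytest.approx(0.1)   # flat below
        assert float(chi(1.0)) == pytest.approx(0.5)    # flat above
        assert 0.1 < float(chi(5e-3)) < 0.5


class TestOdeRhs:
    def test_zero_at_fixed_point(self, fig3, chi_fig3):
        ss = find_fixed_point(chi_fig3, fig3)
        da, dphi = ode_rhs((ss.a_star, ss.phiR_star), fig3, chi_fig3)
        assert abs(da) < 1e-10 and abs(dphi) < 1e-10

    def test_growth_arrested_below_offset(self, fig3, chi_fig3):
        da, dphi = ode_rhs((1e-4, fig3.phiR_min / 2), fig3, chi_fig3)
        assert dphi == 0.0  # lambda clamps to zero, allocation frozen
        assert da > 0       # supply still fills the pool

    def test_supply_only_at_empty_pool(self, fig3, chi_fig3):
        da, _ = ode_rhs((0.0, 0.3), fig3, chi_fig3)
        assert da == pytest.approx(fig3.nu0 * (fig3.phiR_max - 0.3))


class TestFindFixedPoint:
    def test_steady_state_identity(self, fig3, chi_fig3):
        # the defining relation: allocation rule equals realized fraction
        ss = find_fixed_point(chi_fig3, fig3)
        assert float(chi_fig3(ss.a_star)) == pytest.approx(ss.phiR_star, rel=1e-14)

    def test_constant_chi_reduction_exact_without_dilution(self, fig3):
        chi = make_control_function("constant", value=0.25)
        ss = find_fixed_point(chi, fig3, dilution=False)
        assert ss.phiR_star == 0.25
        assert ss.a_star == pytest.approx(
            solve_steady_amino_acid(0.25, fig3), rel=1e-10
        )

    def test_constant_chi_reduction_with_dilution(self, fig3):
        # dilution shifts the pool by O(a*) relative — small but nonzero
        chi = make_control_function("constant", value=0.25)
        ss = find_fixed_point(chi, fig3)
        a_undiluted = solve_steady_amino_acid(0.25, fig3)
        assert ss.a_star == pytest.approx(a_undiluted, rel=5 * a_undiluted)
        assert ss.a_star != pytest.approx(a_undiluted, rel=1e-8)

    def test_unique_intersection(self, fig3, chi_fig3):
        ss = find_fixed_point(chi_fig3, fig3)
        # scan: chi - balance changes sign exactly once
        from growthlaws.dynamics import _phiR_balance_dynamic

        a = np.logspace(-8, 0, 400)
        diff = np.array([float(chi_fig3(x)) - _phiR_balance_dynamic(x, fig3) for x in a])
        assert np.sum(np.diff(np.sign(diff)) != 0) == 1
        assert a[np.argmin(np.abs(diff))] == pytest.approx(ss.a_star, rel=0.1)

    def test_no_intersection_raises(self, fig3):
        lofty = make_control_function("constant", value=0.99)
        with pytest.raises(FixedPointError, match="above"):
            find_fixed_point(lofty, fig3)
        flat = make_control_function("constant", value=0.0)
        with pytest.raises(FixedPointError, match="below"):
            find_fixed_point(flat, fig3)


class TestSimulate:
    def test_start_at_fixed_point_stays(self, fig3, chi_fig3):
        ss = find_fixed_point(chi_fig3, fig3)
        traj = simulate((ss.a_star, ss.phiR_star), chi_fig3, fig3, t_end=10.0)
        assert np.allclose(traj.a, ss.a_star, rtol=1e-6)
        assert np.allclose(traj.phiR, ss.phiR_star, rtol=1e-8)

    def test_multi_start_convergence(self, fig3, chi_fig3):
        """Seeded random interior starts all relax to the same attractor."""
        ss = find_fixed_point(chi_fig3, fig3)
        rng = np.random.default_rng(1234)
        for _ in range(8):
            a0 = 10.0 ** rng.uniform(-7, -1)
            phiR0 = rng.uniform(fig3.phiR_min + 0.01, fig3.phiR_max - 0.01)
            traj = simulate((a0, phiR0), chi_fig3, fig3, t_end=500.0)
            assert traj.converged
            assert traj.a[-1] == pytest.approx(ss.a_star, rel=1e-6)
            assert traj.phiR[-1] == pytest.approx(ss.phiR_star, rel=1e-6)

    def test_constant_chi_drives_phiR_to_value(self, fig3):
        chi = make_control_function("constant", value=0.3)
        traj = simulate((1e-4, 0.15), chi, fig3, t_end=500.0)
        assert traj.converged
        assert traj.phiR[-1] == pytest.approx(0.3, rel=1e-8)

    def test_forward_invariance(self, fig3, chi_fig3):
        traj = simulate((1e-7, 0.95), chi_fig3, fig3, t_end=300.0)
        assert np.all(traj.a >= 0)
        assert np.all((traj.phiR >= 0) & (traj.phiR <= 1))


class TestStability:
    def test_fig3_fixed_point_stable(self, fig3, chi_fig3):
        ss = stability(find_fixed_point(chi_fig3, fig3), chi_fig3, fig3)
        assert ss.stable
        assert all(ev.real < 0 for ev in ss.eigenvalues)

    def test_non_fixed_point_rejected(self, fig3, chi_fig3):
        from growthlaws.steady_state import make_steady_state

        bogus = make_steady_state(1e-3, 0.4, fig3)
        with pytest.raises(ValueError, match="not a fixed point"):
            stability(bogus, chi_fig3, fig3)

    def test_seeded_family_all_stable(self, fig3):
        for chi in sample_control_family(fig3, n=10, seed=99):
            ss = stability(find_fixed_point(chi, fig3), chi, fig3)
            assert ss.stable

    def test_constant_chi_matches_1d_subsystem(self, fig3):
        """With phiR pinned, one eigenvalue is the pool subsystem's derivative."""
        chi = make_control_function("constant", value=0.3)
        ss = stability(find_fixed_point(chi, fig3), chi, fig3)
        h = 1e-6 * ss.a_star
        f = lambda a: ode_rhs((a, ss.phiR_star), fig3, chi)[0]
        slope_1d = (f(ss.a_star + h) - f(ss.a_star - h)) / (2 * h)
        reals = sorted(ev.real for ev in ss.eigenvalues)
        assert min(abs(r - slope_1d) for r in reals) < 1e-3 * abs(slope_1d)

    def test_perturbation_returns(self, fig3, chi_fig3):
        ss = find_fixed_point(chi_fig3, fig3)
        traj = simulate((1.1 * ss.a_star, ss.phiR_star), chi_fig3, fig3, t_end=200.0)
        assert traj.converged
        assert traj.a[-1] == pytest.approx(ss.a_star, rel=1e-6)
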