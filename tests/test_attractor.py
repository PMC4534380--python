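"""Hopfield dynamics: sigmoid, drift, fixed points, pure attractor baseline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from battm import (
    HopfieldParams,
    find_neutral_state,
    find_stable_fixed_points,
    hopfield_drift,
    hopfield_jacobian,
    pure_attractor_trial,
    sigmoid,
)


class TestSigmoid:
    @pytest.mark.parametrize(
        "z, slope, centre, expected",
        [
            (10.0, 1.0, 10.0, 0.5),
            (5.0, 0.7, 5.0, 0.5),
            (10.0 + np.log(3.0), 1.0, 10.0, 0.75),
            (1e6, 1.0, 0.0, 1.0),
            (-1e6, 1.0, 0.0, 0.0),
        ],
    )
    def test_values(self, z, slope, centre, expected):
        assert sigmoid(np.array([z]), slope, centre)[0] == pytest.approx(
            expected, abs=1e-12
        )

    def test_no_overflow_and_monotone(self):
        z = np.linspace(-1e4, 1e4, 101)
        with np.errstate(over="raise"):
            out = sigmoid(z, 1.0, 10.0)
        assert np.all(np.diff(out) >= 0)
        assert np.all((out >= 0) & (out <= 1))


class TestDrift:
    def test_zero_at_neutral_state(self, params, mu0):
        assert np.max(np.abs(hopfield_drift(mu0, params))) < 1e-8

    def test_equal_components_stay_equal(self, params):
        z = np.array([3.7, 3.7])
        dz = hopfield_drift(z, params)
        assert dz[0] == pytest.approx(dz[1], rel=1e-14)

    def test_dimension_mismatch_raises(self, params):
        with pytest.raises(ValueError):
            hopfield_drift(np.zeros(3), params)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        z=st.lists(
            st.floats(min_value=-5.0, max_value=15.0), min_size=3, max_size=3
        )
    )
    def test_permutation_equivariance(self, z):
        """Relabelling alternatives permutes the drift components exactly."""
        p = HopfieldParams(n_alt=3)
        z = np.array(z)
        perm = np.array([2, 0, 1])
        assert np.allclose(
            hopfield_drift(z[perm], p), hopfield_drift(z, p)[perm]
        )

    def test_jacobian_matches_finite_differences(self, params):
        z = np.array([6.0, 2.5])
        J = hopfield_jacobian(z, params)
        eps = 1e-6
        for j in range(2):
            dz = np.zeros(2)
            dz[j] = eps
            num = (
                hopfield_drift(z + dz, params) - hopfield_drift(z - dz, params)
            ) / (2 * eps)
            assert np.allclose(J[:, j], num, atol=1e-6)


class TestFixedPoints:
    def test_default_stability_condition_holds(self, params):
        assert params.satisfies_stability_condition

    def test_locations_near_goal_corners(self, params, phi):
        """Stable points sit near g*e_m: winner at ~g, loser at ~0."""
        g = params.g
        assert phi.shape == (2, 2)
        for m in range(2):
            assert abs(phi[m, m] - g) < 1e-3 * g
            assert abs(phi[m, 1 - m]) < 1e-3 * g

    def test_drift_vanishes_at_stable_points(self, params, phi):
        for m in range(2):
            assert np.max(np.abs(hopfield_drift(phi[m], params))) < 1e-8

    def test_attracting_by_numerical_jacobian(self, params, phi):
        """All eigenvalue real parts negative, using a finite-difference
        Jacobian independent of the analytic one."""
        eps = 1e-6
        for m in range(2):
            J = np.empty((2, 2))
            for j in range(2):
                dz = np.zeros(2)
                dz[j] = eps
                J[:, j] = (
                    hopfield_drift(phi[m] + dz, params)
                    - hopfield_drift(phi[m] - dz, params)
                ) / (2 * eps)
            assert np.all(np.linalg.eigvals(J).real < 0)

    def test_permuting_alternatives_permutes_points(self):
        p = HopfieldParams(n_alt=3)
        pts = find_stable_fixed_points(p)
        # phi_m is phi_0 with components 0 and m swapped
        for m in (1, 2):
            swapped = pts[0].copy()
            swapped[[0, m]] = swapped[[m, 0]]
            assert np.allclose(pts[m], swapped, atol=1e-8)


class TestNeutralState:
    def test_components_equal_and_drift_zero(self, params, mu0):
        assert mu0[0] == pytest.approx(mu0[1], abs=1e-12)
        assert np.max(np.abs(hopfield_drift(mu0, params))) < 1e-8

    def test_value_matches_bisection_oracle(self, params, mu0):
        """Independent bisection of the scalar diagonal drift
        k*(-b_lat/(1+exp(-(c-o))) + b_lin*(g-c))."""

        def diag_drift(c):
            return params.k * (
                -params.b_lat / (1.0 + np.exp(-(c - params.o)))
                + params.b_lin * (params.g - c)
            )

        lo, hi = 0.0, params.g
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if diag_drift(lo) * diag_drift(mid) <= 0:
                hi = mid
            else:
                lo = mid
        assert mu0[0] == pytest.approx(0.5 * (lo + hi), abs=1e-10)

    def test_unstable_off_diagonal(self, params, mu0):
        """A small antisymmetric perturbation grows under Euler integration."""
        z = mu0 + np.array([1e-3, -1e-3])
        d0 = np.abs(z[0] - z[1])
        for _ in range(10):
            z = z + 0.05 * hopfield_drift(z, params)
        assert np.abs(z[0] - z[1]) > d0

    def test_failure_reported_when_equilibrium_not_unstable(self):
        # weak lateral inhibition relative to the goal attractor makes the
        # diagonal equilibrium stable, which is diagnosed explicitly
        p = HopfieldParams(b_lat=0.1, b_lin=0.05)
        with pytest.raises(RuntimeError):
            find_neutral_state(p)


class TestPureAttractor:
    def test_fixed_point_is_invariant_without_input(self, phi):
        traj = pure_attractor_trial(
            0.0, 0.0, [(0, 200.0)], seed=0, z0=phi[0]
        )
        assert np.allclose(traj[-1], phi[0], atol=1e-8)

    def test_neutral_start_stays_without_input_or_noise(self, mu0):
        traj = pure_attractor_trial(0.0, 0.0, [(0, 200.0)], seed=0)
        assert np.allclose(traj[-1], mu0, atol=1e-6)

    def test_noise_free_trajectory_matches_finer_euler(self, params, mu0):
        """10x-finer-step Euler oracle, same continuous input level."""
        I = 40.0
        coarse = pure_attractor_trial(I, 0.0, [(0, 400.0)], dt_ms=4.0, seed=0)

        dt_fine = 0.4 / 50.0
        z = mu0.copy()
        for _ in range(1000):
            inp = np.array([dt_fine * I, 0.0])
            z = z + dt_fine * hopfield_drift(z, params) + inp
        assert np.allclose(coarse[-1], z, rtol=0.02, atol=0.05)

    def test_asymptote_increases_with_input(self):
        asym = []
        for I in (20.0, 40.0, 80.0):
            traj = pure_attractor_trial(I, 0.0, [(0, 800.0)], seed=0)
            asym.append(traj[-1, 0])
        assert asym[0] < asym[1] < asym[2]
        # attained state moves away from the intrinsic fixed point level
        assert asym[-1] > 10.5
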