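"""Trajectories, hysteresis ramps, separatrix and basins of attraction."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from thermoreg import (
    SaturationShape,
    State,
    ThermoParams,
    basin_map,
    find_equilibria,
    fold_points,
    integrate,
    ramp_protocol,
    separatrix,
)
from thermoreg.model import rhs_array

BISTABLE = ThermoParams(T_A=303.0)


class TestIntegrate:
    def test_fixed_point_stays_fixed(self, shape):
        eq = [e for e in find_equilibria(BISTABLE, shape) if e.label == "homeostatic"][0]
        traj = integrate(eq.state, BISTABLE, shape, 1000.0)
        drift = np.max(np.abs(traj.states - eq.state.as_array()))
        assert drift < 1e-6

    @pytest.mark.parametrize(
        "start, target_label, target_T_C",
        [
            ((310.0, 310.0), "homeostatic", 309.7144),
            ((303.0, 303.0), "non_homeostatic", 303.0000),
        ],
    )
    def test_convergence_to_the_basin_attractor(self, shape, start, target_label, target_T_C):
        traj = integrate(State(*start), BISTABLE, shape, 5000.0,
                         to_convergence=True)
        assert traj.converged
        assert traj.final_state.T_C == pytest.approx(target_T_C, abs=1e-3)

    def test_nonconvergence_flagged_not_raised(self, shape):
        traj = integrate(State(290.0, 340.0), BISTABLE, shape, 0.5,
                         to_convergence=True)
        assert not traj.converged
        assert traj.final_residual > 1e-9
        assert traj.t[-1] <= 0.5

    def test_pure_relaxation_without_regulation(self):
        """With f_S effectively off and no breathing term, both temperatures
        relax to ambient from any start."""
        params = ThermoParams(T_A=305.0, V_O2=0.0)
        shape = SaturationShape(p=1e-12, v=0.5)
        traj = integrate(State(290.0, 330.0), params, shape, 4000.0,
                         to_convergence=True)
        assert traj.final_state.T_S == pytest.approx(305.0, abs=1e-5)
        assert traj.final_state.T_C == pytest.approx(305.0, abs=1e-5)

    def test_time_reversal_returns_to_start(self, params, shape):
        fwd = integrate(State(305.0, 312.0), params, shape, 5.0, rtol=1e-12,
                        atol=1e-12, method="DOP853")
        end = fwd.states[-1]
        back = solve_ivp(lambda t, y: -rhs_array(y, params, shape), (0.0, 5.0),
                         end, method="DOP853", rtol=1e-12, atol=1e-12)
        assert np.max(np.abs(back.y[:, -1] - np.array([305.0, 312.0]))) < 1e-6

    def test_invalid_horizon(self, params, shape):
        with pytest.raises(ValueError):
            integrate(State(300.0, 310.0), params, shape, -1.0)


class TestRampProtocol:
    def test_warming_from_cold_failure_branch(self, params, shape):
        """Warming air from 295 K: the body stays on the failure branch until
        the fold near 306.6 K annihilates it."""
        res = ramp_protocol(295.0, 310.0, params, shape, step=0.1)
        verge = fold_points(params, shape).verges_by_border()["3-1"]
        assert res.jump_T_A == pytest.approx(verge, abs=0.1 + 1e-9)
        assert (res.branch_before, res.branch_after) == ("non_homeostatic", "homeostatic")

    def test_cooling_from_homeostatic_branch(self, params, shape):
        res = ramp_protocol(305.0, 295.0, params, shape, step=0.1)
        verge = fold_points(params, shape).verges_by_border()["2-3"]
        assert res.jump_T_A == pytest.approx(verge, abs=0.1 + 1e-9)
        assert (res.branch_before, res.branch_after) == ("homeostatic", "non_homeostatic")

    def test_overheating_past_the_hot_verge(self, params, shape):
        res = ramp_protocol(318.0, 323.0, params, shape, step=0.1,
                            initial=State(310.15, 310.15))
        verge = fold_points(params, shape).verges_by_border()["3-2"]
        assert res.jump_T_A == pytest.approx(verge, abs=0.1 + 1e-9)

    def test_no_jump_within_mono_stable_range(self, params, shape):
        res = ramp_protocol(308.0, 312.0, params, shape, step=0.2)
        assert res.jump_T_A is None

    def test_jump_converges_to_fold_with_step(self, params, shape):
        """Quasi-static jump point approaches the fold verge as step → 0."""
        verge = fold_points(params, shape).verges_by_border()["3-1"]
        errors = []
        for step in (0.5, 0.1, 0.02):
            res = ramp_protocol(305.5, 308.0, params, shape, step=step,
                                initial=State(305.5, 305.5))
            assert res.jump_T_A is not None
            err = abs(res.jump_T_A - verge)
            assert err <= step + 1e-9
            errors.append(err)
        assert errors[-1] < errors[0]

    def test_hysteresis_band_orientation(self, params, shape):
        up = ramp_protocol(295.0, 310.0, params, shape, step=0.5)
        down = ramp_protocol(305.0, 295.0, params, shape, step=0.5)
        assert up.jump_T_A > down.jump_T_A  # the loop encloses a band


class TestSeparatrix:
    def test_saddle_location(self, shape):
        """With k1=k2 the saddle skin temperature is the T_A/T_C* midpoint."""
        part = separatrix(BISTABLE, shape)
        saddle = part.separatrix[len(part.separatrix) // 2]
        # polyline passes through the saddle at its center join
        saddle_eq = [e for e in find_equilibria(BISTABLE, shape) if not e.stable][0]
        assert saddle_eq.T_S_star == pytest.approx((303.0 + saddle_eq.T_C_star) / 2)
        assert np.min(np.linalg.norm(part.separatrix
                                     - [saddle_eq.T_S_star, saddle_eq.T_C_star],
                                     axis=1)) < 1e-6

    def test_straddling_states_reach_different_attractors(self, shape):
        saddle = [e for e in find_equilibria(BISTABLE, shape) if not e.stable][0]
        J_eigs = np.linalg.eig(
            np.array([[-0.4, 0.2],
                      [0.2, -0.2 + float(shape.derivative(saddle.T_C_star)) - 0.018]])
        )
        i_un = int(np.argmax(J_eigs.eigenvalues.real))
        v_un = np.real(J_eigs.eigenvectors[:, i_un])
        v_un /= np.linalg.norm(v_un)
        finals = []
        for sgn in (+1, -1):
            y0 = saddle.state.as_array() + sgn * 0.1 * v_un
            traj = integrate(State(*y0), BISTABLE, shape, 20000.0,
                             to_convergence=True, residual_tol=1e-8)
            finals.append(traj.final_state.T_C)
        assert abs(finals[0] - finals[1]) > 1.0  # opposite basins

    def test_rejected_outside_bistable_area(self, shape):
        with pytest.raises(ValueError, match="area 1"):
            separatrix(ThermoParams(T_A=310.0), shape)


class TestBasinMap:
    def test_reference_cells_and_attractor_identity(self, shape):
        part = basin_map(BISTABLE, shape, T_S_range=(295.0, 320.0),
                        T_C_range=(295.0, 320.0), n=6)
        stable_labels = {e.label for e in find_equilibria(BISTABLE, shape) if e.stable}
        assert set(part.labels.ravel()) <= stable_labels
        # nearest grid cells to the two reference starts
        i_310 = int(np.argmin(np.abs(part.T_S_values - 310.0)))
        j_310 = int(np.argmin(np.abs(part.T_C_values - 310.0)))
        i_303 = int(np.argmin(np.abs(part.T_S_values - 303.0)))
        j_303 = int(np.argmin(np.abs(part.T_C_values - 303.0)))
        assert part.labels[j_310, i_310] == "homeostatic"
        assert part.labels[j_303, i_303] == "non_homeostatic"

    def test_labels_agree_with_separatrix_side(self, shape):
        """Grid labels match the side of the stable manifold each cell is on."""
        part = basin_map(BISTABLE, shape, T_S_range=(300.0, 312.0),
                        T_C_range=(300.0, 312.0), n=8)
        sep = separatrix(BISTABLE, shape).separatrix
        # orient the polyline: homeostatic side is toward larger T_C locally
        mismatches = 0
        for j, tc in enumerate(part.T_C_values):
            for i, ts in enumerate(part.T_S_values):
                k = int(np.argmin(np.linalg.norm(sep - [ts, tc], axis=1)))
                above = tc > sep[k, 1]
                want = "homeostatic" if above else "non_homeostatic"
                if part.labels[j, i] != want:
                    mismatches += 1
        assert mismatches <= round(0.01 * part.labels.size) + 1
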