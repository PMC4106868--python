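"""Full 4-variable model: initialisation, stepping, and numerics oracles."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

from branchrd.core import (
    FieldState,
    SimulationBlowup,
    init_full,
    run_full,
    step_full,
)
from branchrd.params import H_FLOOR, GridSpec, ModelParams


def homogeneous_rhs(p):
    """Right-hand side of the spatially homogeneous 4-variable kinetics."""

    def rhs(_, x):
        a, h, s, y = x
        auto = p.c * s * a * a
        return [
            auto / max(h, H_FLOOR) - p.mu * a + p.rhoA * y,
            auto - p.nu * h + p.rhoH * y,
            p.c0 - p.gamma * s - p.epsilon * y * s,
            p.d * a - p.e * y + y * y / (1.0 + p.f * y * y),
        ]

    return rhs


class TestInitFull:
    def test_seed_cell_count(self):
        g = GridSpec(nx=200, ny=200)
        state = init_full(g, seed_width=5, seed_length=10)
        assert int((state.Y == 1.0).sum()) == 50
        assert np.all(state.A == 0.001)
        assert np.all(state.H == 0.01)
        assert np.all(state.S == 1.0)
        # seed touches the left edge
        assert state.Y[:, 0].max() == 1.0

    def test_empty_seed_is_uniform_control(self):
        g = GridSpec(nx=40, ny=40)
        state = init_full(g, seed_width=0, seed_length=0)
        assert np.all(state.Y == 0.0)

    def test_total_substrate_mass(self):
        g = GridSpec(nx=37, ny=23)
        state = init_full(g)
        assert state.S.sum() == pytest.approx(37 * 23 * 1.0)

    def test_oversized_seed_rejected(self):
        with pytest.raises(ValueError, match="does not fit"):
            init_full(GridSpec(nx=8, ny=8), seed_width=5, seed_length=10)


class TestStepFull:
    def test_all_sources_vanish_without_activator(self, params):
        g = GridSpec(nx=10, ny=8)
        s0 = 0.5
        state = FieldState(
            A=np.zeros(g.shape),
            H=np.full(g.shape, H_FLOOR),
            S=np.full(g.shape, s0),
            Y=np.zeros(g.shape),
        )
        for _ in range(50):
            state = step_full(state, params, g)
        assert np.all(state.A == 0.0)
        assert np.all(state.Y == 0.0)
        # substrate relaxes monotonically toward c0/gamma = 1
        assert np.all(state.S > s0)
        assert np.all(state.S < params.c0 / params.gamma)

    def test_single_step_matches_hand_evaluation(self, params):
        """At a uniform cell far from the seed (Y = 0 in its neighbourhood),
        one step is exactly A + dt*(c*S*A^2/H - mu*A)."""
        g = GridSpec(nx=30, ny=20)
        state = init_full(g, seed_width=3, seed_length=3)
        new = step_full(state, params, g)
        a, h, s = 0.001, 0.01, 1.0
        expected = a + g.dt * (params.c * s * a * a / h - params.mu * a)
        assert new.A[-1, -1] == pytest.approx(expected, rel=1e-12)

    def test_homogeneous_equilibrium_is_fixed_point(self, params):
        """A uniform state at the ODE equilibrium moves < 1e-12 per step."""
        rhs = homogeneous_rhs(params)
        sol = solve_ivp(
            rhs, (0.0, 30_000.0), [0.5, 0.1, 0.5, 1.0],
            method="LSODA", rtol=1e-12, atol=1e-12,
        )
        eq = fsolve(lambda x: rhs(0.0, x), sol.y[:, -1], xtol=1e-13)
        assert np.allclose(rhs(0.0, eq), 0.0, atol=1e-12)
        g = GridSpec(nx=8, ny=8)
        state = FieldState(
            A=np.full(g.shape, eq[0]), H=np.full(g.shape, eq[1]),
            S=np.full(g.shape, eq[2]), Y=np.full(g.shape, eq[3]),
        )
        new = step_full(state, params, g)
        for name in ("A", "H", "S", "Y"):
            delta = np.abs(getattr(new, name) - getattr(state, name)).max()
            assert delta < 1e-12, name

    def test_input_state_unmodified(self, params):
        g = GridSpec(nx=10, ny=10)
        state = init_full(g, 2, 2)
        before = state.A.copy()
        step_full(state, params, g)
        np.testing.assert_array_equal(state.A, before)


class TestRunFull:
    def test_zero_steps_returns_initial_only(self, params):
        g = GridSpec(nx=12, ny=12)
        snaps = run_full(params, g, 0)
        assert len(snaps) == 1
        assert snaps[0].step == 0

    def test_seedless_state_stays_uniform(self, params):
        g = GridSpec(nx=14, ny=10)
        snaps = run_full(params, g, 500, 100, seed_width=0, seed_length=0)
        for snap in snaps:
            for name in ("A", "H", "S", "Y"):
                arr = getattr(snap, name)
                assert np.ptp(arr) == 0.0, (name, snap.step)

    def test_bit_identical_reruns(self, params):
        g = GridSpec(nx=20, ny=16)
        a = run_full(params, g, 2_000, 500)
        b = run_full(params, g, 2_000, 500)
        for sa, sb in zip(a, b):
            for name in ("A", "H", "S", "Y"):
                np.testing.assert_array_equal(
                    getattr(sa, name), getattr(sb, name)
                )

    def test_snapshot_cadence(self, params):
        g = GridSpec(nx=10, ny=10)
        snaps = run_full(params, g, 1_000, 250)
        assert [s.step for s in snaps] == [0, 250, 500, 750, 1000]

    def test_blowup_reports_field_and_cell(self, params):
        g = GridSpec(nx=6, ny=6)
        state = init_full(g, 2, 2)
        state.A[3, 4] = np.nan
        with pytest.raises(SimulationBlowup) as err:
            run_full(params, g, 10, state0=state)
        assert err.value.field == "A"

    def test_unstable_dt_rejected(self, params):
        g = GridSpec(nx=10, ny=10, dx=0.3, dt=0.1)  # dt*Dh/dx^2 > 0.25
        with pytest.raises(ValueError, match="unstable"):
            run_full(params, g, 10)


class TestNumericalProperties:
    def test_pure_diffusion_conserves_mass(self, rng):
        p = ModelParams(
            Da=0.002, Dh=0.26, Ds=0.06, c=0.0, c0=0.0, gamma=0.0,
            mu=0.0, nu=0.0, rhoA=0.0, rhoH=0.0, epsilon=0.0,
            d=0.0, e=0.0, f=0.0,
        )
        g = GridSpec(nx=16, ny=16)
        state = FieldState(
            A=rng.uniform(0, 1, g.shape), H=rng.uniform(0, 1, g.shape),
            S=rng.uniform(0, 1, g.shape), Y=np.zeros(g.shape),
        )
        m0 = [state.A.sum(), state.H.sum(), state.S.sum()]
        snaps = run_full(p, g, 10_000, 10_000, state0=state)
        final = snaps[-1]
        m1 = [final.A.sum(), final.H.sum(), final.S.sum()]
        np.testing.assert_allclose(m1, m0, rtol=1e-8)

    def test_forward_euler_matches_rk4_reference(self, params):
        """50 Euler steps vs an independent RK4 integrator at dt/20."""
        g = GridSpec(nx=8, ny=8)
        state0 = init_full(g, 3, 3)

        def rhs(A, H, S, Y):
            def lap(F):
                pad = np.pad(F, 1, mode="edge")
                return (
                    pad[:-2, 1:-1] + pad[2:, 1:-1]
                    + pad[1:-1, :-2] + pad[1:-1, 2:] - 4 * F
                ) / (g.dx * g.dx)

            p = params
            auto = p.c * S * A * A
            dA = auto / np.maximum(H, H_FLOOR) - p.mu * A + p.rhoA * Y + p.Da * lap(A)
            dH = auto - p.nu * H + p.rhoH * Y + p.Dh * lap(H)
            dS = p.c0 - p.gamma * S - p.epsilon * Y * S + p.Ds * lap(S)
            dY = p.d * A - p.e * Y + Y * Y / (1.0 + p.f * Y * Y)
            return dA, dH, dS, dY

        x = [state0.A.copy(), state0.H.copy(), state0.S.copy(), state0.Y.copy()]
        h = g.dt / 20.0
        for _ in range(50 * 20):
            k1 = rhs(*x)
            k2 = rhs(*(xi + 0.5 * h * ki for xi, ki in zip(x, k1)))
            k3 = rhs(*(xi + 0.5 * h * ki for xi, ki in zip(x, k2)))
            k4 = rhs(*(xi + h * ki for xi, ki in zip(x, k3)))
            x = [
                xi + h / 6.0 * (a + 2 * b + 2 * c + d)
                for xi, a, b, c, d in zip(x, k1, k2, k3, k4)
            ]
        euler = run_full(params, g, 50, 50, state0=state0)[-1]
        for ref, got in zip(x, (euler.A, euler.H, euler.S, euler.Y)):
            scale = np.abs(ref).max() or 1.0
            assert np.abs(got - ref).max() / scale < 1e-3

    @pytest.mark.parametrize(
        "p",
        [ModelParams(), ModelParams(epsilon=1.0), ModelParams(epsilon=0.0025)],
        ids=["default", "tip-splitting", "side-branching"],
    )
    def test_fields_stay_nonnegative(self, p):
        g = GridSpec(nx=24, ny=24)
        snaps = run_full(p, g, 100_000, 20_000)
        for snap in snaps:
            for name in ("A", "H", "S", "Y"):
                assert getattr(snap, name).min() >= 0.0, (name, snap.step)
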