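"""States and explicit finite-difference integrators.

Both models advance by forward Euler with a four-point Laplacian and no-flux
(mirrored-neighbour) boundaries; all fields update from the same time level.
The default time step ``dt = 0.4*dx**2`` keeps every shipped parameter set
inside the explicit diffusion stability limit ``dt*max(D)/dx**2 <= 0.25``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from . import _kernels
from .domains import DomainExhausted, StalkGeometry, fields_at
from .params import H_FLOOR, GridSpec, ModelParams

__all__ = [
    "FieldState",
    "AHState",
    "SimulationBlowup",
    "ReducedRun",
    "laplacian_noflux",
    "init_full",
    "step_full",
    "run_full",
    "init_ah",
    "step_reduced",
    "run_reduced",
]

#: How many steps between finite-ness checks during long runs.
_CHECK_EVERY = 2000


class SimulationBlowup(FloatingPointError):
    """A field went non-finite during integration."""

    def __init__(self, field: str, cell: tuple[int, int], step: int):
        self.field = field
        self.cell = cell
        self.step = step
        super().__init__(
            f"non-finite value in field {field!r} at cell {cell} "
            f"near step {step}"
        )


@dataclass
class FieldState:
    """The four scalar fields of the full model at one time point."""

    A: np.ndarray
    H: np.ndarray
    S: np.ndarray
    Y: np.ndarray
    t: float = 0.0
    step: int = 0

    def copy(self) -> "FieldState":
        return FieldState(
            self.A.copy(), self.H.copy(), self.S.copy(), self.Y.copy(),
            self.t, self.step,
        )

    def validate(self) -> None:
        for name in ("A", "H", "S", "Y"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                i, j = np.unravel_index(
                    int(np.argmin(np.isfinite(arr))), arr.shape
                )
                raise SimulationBlowup(name, (int(i), int(j)), self.step)


@dataclass
class AHState:
    """Activator and inhibitor fields of the reduced model."""

    A: np.ndarray
    H: np.ndarray
    t: float = 0.0
    step: int = 0

    def copy(self) -> "AHState":
        return AHState(self.A.copy(), self.H.copy(), self.t, self.step)

    def validate(self) -> None:
        for name in ("A", "H"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                i, j = np.unravel_index(
                    int(np.argmin(np.isfinite(arr))), arr.shape
                )
                raise SimulationBlowup(name, (int(i), int(j)), self.step)


def laplacian_noflux(field: np.ndarray, dx: float) -> np.ndarray:
    """Four-point Laplacian with mirrored (zero-normal-gradient) boundaries.

    The mirrored stencil makes the operator exactly conservative: the output
    sums to zero to rounding error on any finite field.
    """
    field = np.asarray(field, dtype=float)
    if not np.all(np.isfinite(field)):
        raise ValueError("laplacian_noflux: input field contains non-finite values")
    if not dx > 0:
        raise ValueError("dx must be positive")
    padded = np.pad(field, 1, mode="edge")
    return (
        padded[:-2, 1:-1]
        + padded[2:, 1:-1]
        + padded[1:-1, :-2]
        + padded[1:-1, 2:]
        - 4.0 * field
    ) / (dx * dx)


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------

def init_full(
    g: GridSpec, seed_width: int = 5, seed_length: int = 10
) -> FieldState:
    """Standard initial state: uniform morphogens, a Y seed at the left edge.

    A = 0.001 and H = 0.01 (small), S = 1.0 (plentiful substrate); Y = 1
    inside a ``seed_width`` x ``seed_length`` rectangle touching the left
    edge (vertically centred), 0 elsewhere.  A zero-size seed gives the
    uniform control state.
    """
    if seed_width < 0 or seed_length < 0:
        raise ValueError("seed dimensions must be >= 0")
    if seed_width > g.ny or seed_length > g.nx:
        raise ValueError(
            f"seed {seed_width}x{seed_length} does not fit the "
            f"{g.ny}x{g.nx} grid"
        )
    A = np.full(g.shape, 0.001)
    H = np.full(g.shape, 0.01)
    S = np.full(g.shape, 1.0)
    Y = np.zeros(g.shape)
    if seed_width and seed_length:
        i0 = (g.ny - seed_width) // 2
        Y[i0 : i0 + seed_width, 0:seed_length] = 1.0
    return FieldState(A, H, S, Y, t=0.0, step=0)


def _advance_full_inplace(
    state: FieldState, p: ModelParams, g: GridSpec, nsteps: int
) -> None:
    """Advance ``state`` by nsteps (mutates; used by the drivers)."""
    if nsteps == 0:
        return
    A, H, S, Y = (
        np.ascontiguousarray(state.A),
        np.ascontiguousarray(state.H),
        np.ascontiguousarray(state.S),
        np.ascontiguousarray(state.Y),
    )
    out = _kernels.advance_full(
        A, H, S, Y,
        np.empty_like(A), np.empty_like(H), np.empty_like(S), np.empty_like(Y),
        nsteps,
        p.Da, p.Dh, p.Ds, p.c, p.c0, p.gamma, p.mu, p.nu,
        p.rhoA, p.rhoH, p.epsilon, p.d, p.e, p.f,
        g.dx, g.dt, H_FLOOR,
    )
    state.A, state.H, state.S, state.Y = out
    state.step += nsteps
    state.t += nsteps * g.dt


def step_full(state: FieldState, p: ModelParams, g: GridSpec) -> FieldState:
    """One forward-Euler step of the full model; the input is not modified."""
    g.check_stability(p)
    new = state.copy()
    _advance_full_inplace(new, p, g, 1)
    new.validate()
    return new


def run_full(
    p: ModelParams,
    g: GridSpec,
    steps: int,
    snapshot_every: int | None = None,
    state0: FieldState | None = None,
    seed_width: int = 5,
    seed_length: int = 10,
) -> list[FieldState]:
    """Integrate the full model, returning snapshots (initial state included).

    Deterministic: identical inputs give bit-identical trajectories.  Raises
    :class:`SimulationBlowup` (with the offending field and cell) if any
    field goes non-finite.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    g.check_stability(p)
    state = state0.copy() if state0 is not None else init_full(
        g, seed_width, seed_length
    )
    if snapshot_every is None:
        snapshot_every = max(steps, 1)
    snapshots = [state.copy()]
    done = 0
    while done < steps:
        upcoming = min(
            snapshot_every - (done % snapshot_every) or snapshot_every,
            _CHECK_EVERY,
            steps - done,
        )
        _advance_full_inplace(state, p, g, upcoming)
        state.validate()
        done += upcoming
        if done % snapshot_every == 0 or done == steps:
            if not snapshots or snapshots[-1].step != state.step:
                snapshots.append(state.copy())
    return snapshots


# ---------------------------------------------------------------------------
# Reduced model
# ---------------------------------------------------------------------------

def init_ah(
    g: GridSpec,
    a0: float = 0.001,
    h0: float = 0.01,
    perturbation: dict | None = None,
) -> AHState:
    """Uniform initial A/H fields, optionally with multiplicative noise.

    ``perturbation`` is a mapping with keys ``amplitude`` (relative, e.g.
    0.02 for 2%) and ``seed``; noise is uniform in [-amplitude, +amplitude]
    and applied multiplicatively to both fields.
    """
    A = np.full(g.shape, float(a0))
    H = np.full(g.shape, float(h0))
    if perturbation and perturbation.get("amplitude", 0.0):
        amp = float(perturbation["amplitude"])
        rng = np.random.default_rng(perturbation.get("seed", 0))
        A *= 1.0 + amp * rng.uniform(-1.0, 1.0, size=g.shape)
        H *= 1.0 + amp * rng.uniform(-1.0, 1.0, size=g.shape)
    return AHState(A, H, t=0.0, step=0)


def _advance_reduced_inplace(
    state: AHState,
    yfield: np.ndarray,
    sfield: np.ndarray,
    p: ModelParams,
    g: GridSpec,
    nsteps: int,
) -> None:
    if nsteps == 0:
        return
    A = np.ascontiguousarray(state.A)
    H = np.ascontiguousarray(state.H)
    out = _kernels.advance_reduced(
        A, H, np.empty_like(A), np.empty_like(H),
        np.ascontiguousarray(yfield), np.ascontiguousarray(sfield),
        nsteps,
        p.Da, p.Dh, p.c, p.mu, p.nu, p.rhoA, p.rhoH,
        g.dx, g.dt, H_FLOOR,
    )
    state.A, state.H = out
    state.step += nsteps
    state.t += nsteps * g.dt


def step_reduced(
    state: AHState,
    yfield: np.ndarray,
    sfield: np.ndarray,
    p: ModelParams,
    g: GridSpec,
) -> AHState:
    """One forward-Euler step of the A/H model with frozen Y, S fields."""
    if yfield.shape != g.shape or sfield.shape != g.shape:
        raise ValueError("Y/S fields must match the grid shape")
    new = state.copy()
    _advance_reduced_inplace(new, yfield, sfield, p, g, 1)
    new.validate()
    return new


class ReducedRun(Sequence):
    """Snapshot sequence from a reduced-model run.

    Behaves as a sequence of :class:`AHState`; also records the geometry,
    the perturbation seed and, for growing stalks, whether and when the run
    stopped because the stalk outgrew the grid (``exhausted_at``).
    """

    def __init__(self, snapshots, geometry, exhausted_at=None, seed=None):
        self.snapshots: list[AHState] = snapshots
        self.geometry = geometry
        self.exhausted_at: int | None = exhausted_at
        self.seed = seed

    def __len__(self) -> int:
        return len(self.snapshots)

    def __getitem__(self, i):
        return self.snapshots[i]

    def __iter__(self) -> Iterator[AHState]:
        return iter(self.snapshots)

    @property
    def final(self) -> AHState:
        return self.snapshots[-1]


def run_reduced(
    geom: StalkGeometry,
    p: ModelParams,
    g: GridSpec,
    steps: int,
    snapshot_every: int | None = None,
    perturbation: dict | None = None,
    state0: AHState | None = None,
) -> ReducedRun:
    """Integrate the reduced A/H model over prescribed stalk fields.

    Starts from the standard uniform initial values A = 0.001, H = 0.01
    (optionally multiplicatively perturbed with a recorded seed).  For a
    growing stalk the prescribed fields are refreshed at every elongation
    event; the run stops cleanly when the stalk outgrows the grid.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    g.check_stability(p)
    state = state0.copy() if state0 is not None else init_ah(
        g, perturbation=perturbation
    )
    if snapshot_every is None:
        snapshot_every = max(steps, 1)
    try:
        yfield, sfield = fields_at(geom, g, state.step)
    except DomainExhausted:
        return ReducedRun(
            [state.copy()], geom, exhausted_at=state.step,
            seed=(perturbation or {}).get("seed"),
        )
    snapshots = [state.copy()]
    exhausted_at = None
    interval = geom.growth_interval
    target = state.step + steps
    while state.step < target:
        upcoming = min(_CHECK_EVERY, target - state.step)
        upcoming = min(
            upcoming, snapshot_every - (state.step % snapshot_every) or snapshot_every
        )
        if interval:
            to_growth = interval - (state.step % interval) or interval
            upcoming = min(upcoming, to_growth)
        _advance_reduced_inplace(state, yfield, sfield, p, g, upcoming)
        state.validate()
        if interval and state.step % interval == 0:
            try:
                yfield, sfield = fields_at(geom, g, state.step)
            except DomainExhausted:
                exhausted_at = state.step
                if snapshots[-1].step != state.step:
                    snapshots.append(state.copy())
                break
        if state.step % snapshot_every == 0 or state.step == target:
            if snapshots[-1].step != state.step:
                snapshots.append(state.copy())
    return ReducedRun(
        snapshots, geom, exhausted_at=exhausted_at,
        seed=(perturbation or {}).get("seed"),
    )
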