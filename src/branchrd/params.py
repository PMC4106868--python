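"""Model parameters and lattice geometry.

The kinetic scheme is a four-variable Meinhardt-type net-formation model:
an autocatalytic activator ``A``, its fast-diffusing antagonist ``H``, a
consumable substrate ``S`` that fuels autocatalysis, and an irreversible
cell-differentiation marker ``Y`` (the stalk).  The reduced two-variable
model keeps only the ``A``/``H`` kinetics and treats ``Y`` and ``S`` as
prescribed fields.

Published parameter sets for this model family are printed as ordered value
lists without symbols, so the symbol assignment is a calibration question.
The assignment used here (see ``REDUCED_AH_PARAMS`` / ``SIDE_BRANCHING_PARAMS``)
was fixed by requiring the linear-stability portrait of the A/H subsystem to
show the three regimes (oscillatory / Turing / stable) in the documented
arrangement, a stable non-Turing point at (S, Y) = (0.6, 1.0), and
fastest-growing wavenumbers of order 0.4-1.0 inside the Turing region; see
``docs/methods.md`` for the full calibration account.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

__all__ = [
    "ModelParams",
    "GridSpec",
    "H_FLOOR",
    "REDUCED_AH_PARAMS",
    "SIDE_BRANCHING_PARAMS",
    "TIP_SPLITTING_PARAMS",
]

#: Guard for the autocatalysis denominator c*S*A^2 / max(H, H_FLOOR).
#: H = 0 only occurs in degenerate initial states; the guard sits far
#: below every dynamical scale of the model.
H_FLOOR = 1e-8


@dataclass(frozen=True)
class ModelParams:
    """Rate and diffusion constants of the four-variable model.

    The reduced activator/inhibitor model uses the subset
    ``{Da, Dh, c, mu, nu, rhoA, rhoH}``.

    Attributes
    ----------
    Da, Dh, Ds:
        Diffusion coefficients of activator, inhibitor and substrate
        (space^2 / time).  The differentiation marker Y does not diffuse.
    c:
        Autocatalysis rate of the activator (also the production rate of
        inhibitor by activator; both terms share the kinetic factor c*S*A^2).
    c0:
        Baseline substrate production rate.
    gamma:
        First-order substrate decay rate.
    mu, nu:
        First-order decay rates of activator and inhibitor.
    rhoA, rhoH:
        Activator / inhibitor secretion rates by differentiated (Y) cells.
    epsilon:
        Substrate consumption rate by differentiated cells (the ``eps*Y*S``
        sink).  This is the switch between side branching and tip splitting.
    d:
        Activation rate of the differentiation switch by activator.
    e:
        Decay rate of the differentiation marker.
    f:
        Saturation constant of the sigmoidal self-activation ``Y^2/(1+f*Y^2)``
        of the differentiation switch.
    """

    Da: float = 0.002
    Dh: float = 0.26
    Ds: float = 0.06
    c: float = 0.04
    c0: float = 0.02
    gamma: float = 0.02
    mu: float = 0.16
    nu: float = 0.02
    rhoA: float = 0.03
    rhoH: float = 0.0001
    epsilon: float = 0.025
    d: float = 0.008
    e: float = 0.1
    f: float = 10.0

    def __post_init__(self) -> None:
        for fld in fields(self):
            v = getattr(self, fld.name)
            if not math.isfinite(v):
                raise ValueError(f"ModelParams.{fld.name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"ModelParams.{fld.name} must be >= 0, got {v!r}")

    @property
    def max_diffusion(self) -> float:
        return max(self.Da, self.Dh, self.Ds)

    def with_(self, **overrides: float) -> "ModelParams":
        """Return a copy with the given symbols replaced."""
        return replace(self, **overrides)


#: A/H-subsystem parameter set used for the stalk-pattern (side-branching)
#: experiments and for the (S, Y) regime scan.
REDUCED_AH_PARAMS = ModelParams()

#: Full-model set producing side branching (low substrate consumption).
SIDE_BRANCHING_PARAMS = ModelParams(epsilon=0.025)

#: Full-model set producing tip splitting (high substrate consumption).
TIP_SPLITTING_PARAMS = ModelParams(epsilon=1.0)


def _default_dt(dx: float) -> float:
    return 0.4 * dx * dx


@dataclass(frozen=True)
class GridSpec:
    """Uniform square lattice with reflective (no-flux) boundaries.

    ``dt`` defaults to ``0.4*dx**2``, which keeps the explicit scheme well
    inside its stability limit for every parameter set shipped with the
    package.  Physical position of cell ``(i, j)`` is ``(j*dx, i*dx)``
    (row-major ``(y, x)`` storage); the stalk grows along +x from the left
    edge.
    """

    nx: int = 200
    ny: int = 200
    dx: float = 0.3
    dt: float | None = None
    boundary: str = "noflux"

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid dimensions must be positive")
        if not (self.dx > 0 and math.isfinite(self.dx)):
            raise ValueError(f"dx must be positive and finite, got {self.dx!r}")
        if self.dt is None:
            object.__setattr__(self, "dt", _default_dt(self.dx))
        if not (self.dt > 0 and math.isfinite(self.dt)):
            raise ValueError(f"dt must be positive and finite, got {self.dt!r}")
        if self.boundary != "noflux":
            raise ValueError("only no-flux boundaries are supported")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def extent(self) -> tuple[float, float]:
        """Physical domain extent (Lx, Ly)."""
        return (self.nx * self.dx, self.ny * self.dx)

    def check_stability(self, p: ModelParams) -> None:
        """Enforce the explicit-scheme diffusion limit dt*Dmax/dx^2 <= 0.25."""
        number = self.dt * p.max_diffusion / (self.dx * self.dx)
        if number > 0.25:
            raise ValueError(
                f"explicit scheme unstable: dt*max(D)/dx^2 = {number:.4g} > 0.25"
            )
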