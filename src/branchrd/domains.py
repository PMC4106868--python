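"""Prescribed Y/S parameter fields for the reduced activator/inhibitor model.

The reduced model treats the differentiated-cell marker ``Y`` and the
substrate ``S`` as designated functions of space and time rather than
dynamical variables.  Every scenario uses a rectangular "YS domain" (the
stalk): high Y/S levels inside the rectangle, low levels outside, with the
rectangle optionally elongating along +x at a fixed cadence to emulate stalk
growth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import GridSpec

__all__ = ["StalkGeometry", "DomainExhausted", "fields_at", "homogeneous_fields"]


class DomainExhausted(RuntimeError):
    """The growing stalk rectangle no longer fits the grid."""

    def __init__(self, step: int, length: int, nx: int):
        self.step = step
        self.length = length
        super().__init__(
            f"domain exhausted at step {step}: stalk length {length} "
            f"exceeds grid extent {nx}"
        )


@dataclass(frozen=True)
class StalkGeometry:
    """A rectangular stalk domain, optionally elongating over time.

    ``placement="edge"`` anchors the stalk at the left boundary (one open
    end, the mirror boundary closes the other); ``placement="centered"``
    centres it in the domain with two open ends.  When ``growth_interval``
    is positive the rectangle gains one grid step of length every
    ``growth_interval`` time steps, the first extension completing at
    ``step == growth_interval``; new cells take the inside levels instantly.

    ``transverse_S`` = (high, low) replaces the inside/outside S levels with
    a landscape that is ``low`` inside the rectangle and ``high`` outside,
    used to study transverse migration of stalk peaks down a substrate
    gradient.
    """

    width: int = 5
    initial_length: int = 10
    placement: str = "edge"
    growth_interval: int = 0
    inside_Y: float = 1.0
    inside_S: float = 0.5
    outside_Y: float = 0.0
    outside_S: float = 0.0
    transverse_S: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.width < 1 or self.initial_length < 1:
            raise ValueError("stalk width and initial_length must be >= 1")
        if self.placement not in ("edge", "centered"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.growth_interval < 0:
            raise ValueError("growth_interval must be >= 0 (0 = stationary)")
        if self.growth_interval and self.placement == "centered":
            raise ValueError("growth is only supported for edge-anchored stalks")
        for name in ("inside_Y", "inside_S", "outside_Y", "outside_S"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def length_at(self, step: int) -> int:
        """Stalk length (grid steps) at a time-step index."""
        if step < 0:
            raise ValueError("step must be >= 0")
        if self.growth_interval == 0:
            return self.initial_length
        return self.initial_length + step // self.growth_interval

    def rect_at(self, g: GridSpec, step: int) -> tuple[int, int, int, int]:
        """Row/column slice bounds (i0, i1, j0, j1) of the rectangle."""
        length = self.length_at(step)
        if self.width > g.ny:
            raise DomainExhausted(step, length, g.ny)
        i0 = (g.ny - self.width) // 2
        i1 = i0 + self.width
        if self.placement == "edge":
            j0, j1 = 0, length
        else:
            j0 = (g.nx - length) // 2
            j1 = j0 + length
        if j1 > g.nx or j0 < 0:
            raise DomainExhausted(step, length, g.nx)
        return i0, i1, j0, j1

    def tip_x(self, g: GridSpec, step: int, dx: float | None = None) -> float:
        """Physical x of the distal (open) end of an edge-anchored stalk."""
        _, _, _, j1 = self.rect_at(g, step)
        return (j1 - 1) * (dx if dx is not None else g.dx)


def fields_at(
    geom: StalkGeometry, g: GridSpec, step: int
) -> tuple[np.ndarray, np.ndarray]:
    """The prescribed (Y, S) fields at a time-step index.

    Raises :class:`DomainExhausted` when the (grown) rectangle overflows the
    grid.
    """
    i0, i1, j0, j1 = geom.rect_at(g, step)
    Y = np.full(g.shape, geom.outside_Y)
    Y[i0:i1, j0:j1] = geom.inside_Y
    if geom.transverse_S is not None:
        high, low = geom.transverse_S
        S = np.full(g.shape, high)
        S[i0:i1, j0:j1] = low
    else:
        S = np.full(g.shape, geom.outside_S)
        S[i0:i1, j0:j1] = geom.inside_S
    return Y, S


def homogeneous_fields(
    g: GridSpec, Y0: float, S0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Spatially uniform Y and S fields (the no-pattern control)."""
    if Y0 < 0 or S0 < 0:
        raise ValueError("levels must be >= 0")
    return np.full(g.shape, float(Y0)), np.full(g.shape, float(S0))
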