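"""Linear stability analysis of the reduced activator/inhibitor subsystem.

With the stalk marker ``Y`` and substrate ``S`` frozen as parameters, the
homogeneous A/H kinetics are

    dA/dt = c*S*A^2/H - mu*A + rhoA*Y
    dH/dt = c*S*A^2   - nu*H + rhoH*Y

Eliminating ``H = (c*S*A^2 + rhoH*Y)/nu`` turns the equilibrium condition
into a cubic in ``A``.  The equilibrium actually visited by the simulations
is the one reached by time integration from the standard initial values
(A, H) = (0.001, 0.01); all roots are reported, but classification and
dispersion use the selected root.

Spatial perturbations ``exp(i k x)`` about an equilibrium grow at the
leading eigenvalue of ``J - diag(Da, Dh) k^2``; sweeping ``k`` gives the
dispersion relation, and the classical Turing conditions (stable kinetics,
a band of unstable wavenumbers at k > 0) classify each (S, Y) pair as
stable / turing / oscillatory / unstable_other / trivial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .params import H_FLOOR, GridSpec, ModelParams

__all__ = [
    "DispersionCurve",
    "RegimeMap",
    "TrivialEquilibriumError",
    "REGIME_CODES",
    "REGIME_LABELS",
    "ah_equilibria",
    "select_equilibrium",
    "ah_jacobian",
    "dispersion",
    "fastest_mode",
    "classify_regime",
    "scan_plane",
    "differentiation_trajectory",
    "turing_ready_map",
]

REGIME_CODES = {
    "stable": 0,
    "turing": 1,
    "oscillatory": 2,
    "unstable_other": 3,
    "trivial": 4,
}
REGIME_LABELS = {v: k for k, v in REGIME_CODES.items()}

#: Re(lambda) within this of zero counts as stable (boundary has measure zero).
_STABLE_TOL = 1e-12


class TrivialEquilibriumError(ValueError):
    """Raised when only the boundary state (A, H) = (0, rhoH*Y/nu) exists."""


# ---------------------------------------------------------------------------
# Equilibria
# ---------------------------------------------------------------------------

def ah_equilibria(S: float, Y: float, p: ModelParams) -> list[tuple[float, float]]:
    """All non-negative real equilibria of the homogeneous A/H kinetics.

    Returns a list of ``(A*, H*)`` pairs sorted by increasing ``A*``.  Each
    root is polished by Newton iteration on the eliminated cubic so that both
    kinetic residuals are < 1e-10.
    """
    if S < 0 or Y < 0:
        raise ValueError("S and Y levels must be non-negative")
    al = p.c * S
    roots: list[float] = []
    if al == 0.0:
        # Linear kinetics: a single equilibrium.
        roots.append(p.rhoA * Y / p.mu)
    else:
        coeffs = np.array(
            [
                -p.mu * al,
                al * (p.nu + p.rhoA * Y),
                -p.mu * p.rhoH * Y,
                p.rhoA * p.rhoH * Y * Y,
            ]
        )
        rts = np.roots(coeffs)
        scale = max(1.0, p.nu / p.mu + p.rhoA * Y / p.mu)
        for r in rts:
            if abs(r.imag) > 1e-9 * scale:
                continue
            a = float(r.real)
            if a < -1e-12 * scale:
                continue
            # Newton polish on the cubic.
            for _ in range(3):
                f = np.polyval(coeffs, a)
                df = np.polyval(np.polyder(coeffs), a)
                if df != 0.0:
                    a -= f / df
            roots.append(max(a, 0.0))
    out = []
    for a in sorted(roots):
        h = (al * a * a + p.rhoH * Y) / p.nu
        if not any(abs(a - a2) <= 1e-8 * max(1.0, a) for a2, _ in out):
            out.append((a, h))
    return out


def _relax(Sv: np.ndarray, Yv: np.ndarray, p: ModelParams,
           a0: float = 1e-3, h0: float = 1e-2, tmax: float = 4e4):
    """Damped time integration of the A/H kinetics from (a0, h0).

    Positivity-preserving (Patankar) Euler with an adaptive step, run per
    (S, Y) point.  Returns (A_end, H_end, converged mask).
    """
    from ._kernels import relax_ah

    Sv = np.ascontiguousarray(np.asarray(Sv, dtype=float).ravel())
    Yv = np.ascontiguousarray(np.asarray(Yv, dtype=float).ravel())
    a, h, conv = relax_ah(
        Sv, Yv, p.c, p.mu, p.nu, p.rhoA, p.rhoH, a0, h0, tmax, H_FLOOR
    )
    return a, h, conv.astype(bool)


def _select_from_relaxed(eqs, a_end, h_end, converged):
    """Pick the equilibrium matching the end point of a relaxation run."""
    nontrivial = [(a, h) for a, h in eqs if a > 1e-9]
    if not nontrivial:
        return None
    if converged:
        best = min(eqs, key=lambda eq: abs(eq[0] - a_end) + abs(eq[1] - h_end))
        return None if best[0] <= 1e-9 else best
    # Not converged (oscillatory orbit): the orbit encircles the non-trivial
    # focus; with several roots pick the nearest to the end point.
    return min(nontrivial, key=lambda eq: abs(eq[0] - a_end) + abs(eq[1] - h_end))


def select_equilibrium(
    S: float, Y: float, p: ModelParams
) -> tuple[float, float] | None:
    """Equilibrium visited from the standard initial values (0.001, 0.01).

    Returns the cubic root nearest to the end point of a damped time
    integration, or ``None`` when the dynamics settle on (or orbit) only the
    trivial boundary state.
    """
    eqs = ah_equilibria(S, Y, p)
    if not any(a > 1e-9 for a, _ in eqs):
        return None
    a_end, h_end, conv = _relax(np.array([S]), np.array([Y]), p)
    return _select_from_relaxed(eqs, float(a_end[0]), float(h_end[0]), bool(conv[0]))


def ah_jacobian(S: float, Y: float, p: ModelParams,
                eq: tuple[float, float] | None = None) -> np.ndarray:
    """Jacobian of the homogeneous A/H kinetics at an equilibrium."""
    if eq is None:
        eq = select_equilibrium(S, Y, p)
        if eq is None:
            raise TrivialEquilibriumError(
                f"only the trivial state exists at (S={S}, Y={Y})"
            )
    a, h = eq
    al = p.c * S
    hh = max(h, H_FLOOR)
    return np.array(
        [
            [2.0 * al * a / hh - p.mu, -al * a * a / (hh * hh)],
            [2.0 * al * a, -p.nu],
        ]
    )


# ---------------------------------------------------------------------------
# Dispersion
# ---------------------------------------------------------------------------

def _leading_real(tr, det):
    """Max real part of the eigenvalues of a 2x2 with given trace/determinant."""
    tr = np.asarray(tr, dtype=float)
    det = np.asarray(det, dtype=float)
    disc = 0.25 * tr * tr - det
    re = np.where(disc >= 0.0, 0.5 * tr + np.sqrt(np.maximum(disc, 0.0)), 0.5 * tr)
    return re


def _growth_of_k2(k2, J, p):
    tr = J[0, 0] + J[1, 1] - (p.Da + p.Dh) * k2
    det = (J[0, 0] - p.Da * k2) * (J[1, 1] - p.Dh * k2) - J[0, 1] * J[1, 0]
    return _leading_real(tr, det)


@dataclass(frozen=True)
class DispersionCurve:
    """Growth rate of spatial modes versus wavenumber about an equilibrium."""

    k: np.ndarray
    growth: np.ndarray
    kstar: float
    lambdastar: float
    S: float
    Y: float
    equilibrium: tuple[float, float]

    @property
    def max_growth(self) -> float:
        return float(self.growth.max())

    @property
    def wavelength(self) -> float:
        """Wavelength 2*pi/k of the fastest-growing mode (space units)."""
        return float(2.0 * np.pi / self.kstar) if self.kstar > 0 else np.inf


def default_kgrid(g: GridSpec | None = None, n: int = 200) -> np.ndarray:
    """k in [0, pi/dx]: zero through the Nyquist wavenumber of the lattice."""
    dx = g.dx if g is not None else 0.3
    return np.linspace(0.0, np.pi / dx, n)


def dispersion(
    S: float,
    Y: float,
    p: ModelParams,
    kgrid: np.ndarray | None = None,
) -> DispersionCurve:
    """Dispersion relation of the A/H subsystem at the selected equilibrium."""
    eq = select_equilibrium(S, Y, p)
    if eq is None:
        raise TrivialEquilibriumError(
            f"regime undefined: only the trivial state exists at (S={S}, Y={Y})"
        )
    if kgrid is None:
        kgrid = default_kgrid()
    kgrid = np.asarray(kgrid, dtype=float)
    J = ah_jacobian(S, Y, p, eq)
    growth = _growth_of_k2(kgrid * kgrid, J, p)
    i = int(np.argmax(growth))
    # refine the maximizer within one grid spacing
    lo = kgrid[max(i - 1, 0)]
    hi = kgrid[min(i + 1, kgrid.size - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda k: -float(_growth_of_k2(k * k, J, p)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-12},
        )
        kstar = float(res.x)
        lamstar = float(-res.fun)
    else:
        kstar, lamstar = float(kgrid[i]), float(growth[i])
    if lamstar < growth[i]:  # numerical guard
        kstar, lamstar = float(kgrid[i]), float(growth[i])
    return DispersionCurve(
        k=kgrid, growth=growth, kstar=kstar, lambdastar=lamstar,
        S=S, Y=Y, equilibrium=eq,
    )


def fastest_mode(S: float, Y: float, p: ModelParams,
                 kmax: float = np.pi / 0.3) -> tuple[float, float]:
    """(k*, lambda*) of the fastest-growing spatial mode, k in (0, kmax]."""
    curve = dispersion(S, Y, p, kgrid=np.linspace(0.0, kmax, 2000))
    return curve.kstar, curve.lambdastar


# ---------------------------------------------------------------------------
# Regime classification
# ---------------------------------------------------------------------------

def _classify_from_equilibrium(
    S: float, Y: float, p: ModelParams, eq: tuple[float, float] | None
) -> str:
    if eq is None:
        return "trivial"
    J = ah_jacobian(S, Y, p, eq)
    tr0 = J[0, 0] + J[1, 1]
    det0 = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
    disc0 = 0.25 * tr0 * tr0 - det0
    re_lead = 0.5 * tr0 + np.sqrt(disc0) if disc0 >= 0 else 0.5 * tr0
    if re_lead > _STABLE_TOL:
        return "oscillatory" if disc0 < 0 else "unstable_other"
    # kinetically stable: Turing iff some k > 0 grows
    b = p.Dh * J[0, 0] + p.Da * J[1, 1]
    if b > 0.0 and b * b > 4.0 * p.Da * p.Dh * det0:
        return "turing"
    return "stable"


def classify_regime(S: float, Y: float, p: ModelParams) -> str:
    """Classify the A/H dynamics at one (S, Y) point.

    Returns one of ``stable``, ``turing``, ``oscillatory``,
    ``unstable_other`` or ``trivial``.
    """
    eq = select_equilibrium(S, Y, p)
    return _classify_from_equilibrium(S, Y, p, eq)


@dataclass(frozen=True)
class RegimeMap:
    """Pointwise regime classification over the (S, Y) plane."""

    s_axis: np.ndarray
    y_axis: np.ndarray
    regime: np.ndarray  # int codes, shape (len(y_axis), len(s_axis))

    def label(self, i: int, j: int) -> str:
        return REGIME_LABELS[int(self.regime[i, j])]

    def mask(self, label: str) -> np.ndarray:
        return self.regime == REGIME_CODES[label]

    def turing_components(self) -> tuple[np.ndarray, int]:
        """Connected components (8-connectivity) of the Turing set."""
        structure = np.ones((3, 3), dtype=int)
        return ndimage.label(self.mask("turing"), structure=structure)

    def lookup(self, S, Y):
        """Nearest-sample regime code for arrays of (S, Y); -1 out of range."""
        S = np.asarray(S, dtype=float)
        Y = np.asarray(Y, dtype=float)
        ds = self.s_axis[1] - self.s_axis[0] if self.s_axis.size > 1 else 1.0
        dy = self.y_axis[1] - self.y_axis[0] if self.y_axis.size > 1 else 1.0
        js = np.rint((S - self.s_axis[0]) / ds).astype(int)
        iy = np.rint((Y - self.y_axis[0]) / dy).astype(int)
        out_of_range = (
            (js < 0) | (js >= self.s_axis.size) | (iy < 0) | (iy >= self.y_axis.size)
        )
        js = np.clip(js, 0, self.s_axis.size - 1)
        iy = np.clip(iy, 0, self.y_axis.size - 1)
        codes = self.regime[iy, js]
        return np.where(out_of_range, -1, codes)

    def to_frame(self):
        """Long-format DataFrame (S, Y, regime) for CSV export."""
        import pandas as pd

        ss, yy = np.meshgrid(self.s_axis, self.y_axis)
        return pd.DataFrame(
            {
                "S": ss.ravel(),
                "Y": yy.ravel(),
                "regime": [REGIME_LABELS[int(c)] for c in self.regime.ravel()],
            }
        )


def scan_plane(
    s_range: tuple[float, float] = (0.0, 1.0),
    y_range: tuple[float, float] = (0.0, 1.2),
    resolution: int | tuple[int, int] = 150,
    p: ModelParams | None = None,
) -> RegimeMap:
    """Classify the A/H dynamics over a lattice of (S, Y) levels.

    Half-open ranges: the first sample sits one grid spacing above the lower
    bound, so S = 0 / Y = 0 degenerate axes are excluded by default.
    """
    if p is None:
        from .params import REDUCED_AH_PARAMS

        p = REDUCED_AH_PARAMS
    if isinstance(resolution, int):
        ns = ny = resolution
    else:
        ns, ny = resolution
    s_axis = s_range[0] + (s_range[1] - s_range[0]) * (np.arange(1, ns + 1) / ns)
    y_axis = y_range[0] + (y_range[1] - y_range[0]) * (np.arange(1, ny + 1) / ny)
    ss, yy = np.meshgrid(s_axis, y_axis)
    codes = classify_points(ss.ravel(), yy.ravel(), p)
    return RegimeMap(s_axis=s_axis, y_axis=y_axis, regime=codes.reshape(ss.shape))


def classify_points(Sflat, Yflat, p: ModelParams) -> np.ndarray:
    """Regime codes for flat arrays of (S, Y) points (batch classify)."""
    Sflat = np.asarray(Sflat, dtype=float).ravel()
    Yflat = np.asarray(Yflat, dtype=float).ravel()
    a_end, h_end, conv = _relax(Sflat, Yflat, p)
    codes = np.empty(Sflat.size, dtype=np.int8)
    for idx in range(Sflat.size):
        S, Y = float(Sflat[idx]), float(Yflat[idx])
        eqs = ah_equilibria(S, Y, p)
        eq = _select_from_relaxed(
            eqs, float(a_end[idx]), float(h_end[idx]), bool(conv[idx])
        )
        codes[idx] = REGIME_CODES[_classify_from_equilibrium(S, Y, p, eq)]
    return codes


#: Inhibitor diffusion used for the transverse-instability wavelength
#: analysis.  The regime-plane geometry is set by the kinetics alone (the
#: diffusion constants enter only the Turing band), while the crescent's
#: fastest-growing wavelengths are quoted for a much longer inhibitor range
#: than the lattice simulations use; see docs/methods.md ("Transverse
#: wavelengths").
TRANSVERSE_ANALYSIS_DH = 2.0


def transverse_analysis_params(p: ModelParams | None = None) -> ModelParams:
    """The A/H parameter set used for crescent-wavelength analysis."""
    if p is None:
        from .params import REDUCED_AH_PARAMS

        p = REDUCED_AH_PARAMS
    return p.with_(Dh=TRANSVERSE_ANALYSIS_DH)


def select_crescent_samples(
    m: RegimeMap, n: int = 3
) -> list[tuple[float, float]]:
    """Deterministically pick (S, Y) pairs spanning the Turing crescent.

    Turing-classified samples are ranked by S; the requested number of pairs
    is taken at evenly spaced quantiles of that ranking (for n = 3: the low-S
    end, the middle and the high-S end of the crescent), using the median-Y
    sample within each selected S column.
    """
    tm = m.mask("turing")
    if not tm.any():
        raise TrivialEquilibriumError("no Turing region in the scanned plane")
    ss, yy = np.meshgrid(m.s_axis, m.y_axis)
    s_vals = ss[tm]
    y_vals = yy[tm]
    order = np.lexsort((y_vals, s_vals))
    s_sorted, y_sorted = s_vals[order], y_vals[order]
    picks = []
    for q in np.linspace(0.0, 1.0, n):
        idx = int(round(q * (s_sorted.size - 1)))
        s_pick = s_sorted[idx]
        ys_here = np.sort(y_sorted[s_sorted == s_pick])
        y_pick = ys_here[ys_here.size // 2]
        picks.append((float(s_pick), float(y_pick)))
    return picks


def differentiation_trajectory(n: int = 201) -> tuple[np.ndarray, np.ndarray]:
    """The (S, Y) path of a differentiating cell: S 1.0 -> 0.1, Y 0 -> 1."""
    tt = np.linspace(0.0, 1.0, n)
    return 1.0 - 0.9 * tt, tt


def trajectory_regimes(p: ModelParams, n: int = 201) -> list[str]:
    """Regime labels along the differentiation trajectory, in order."""
    S, Y = differentiation_trajectory(n)
    codes = classify_points(S, Y, p)
    return [REGIME_LABELS[int(c)] for c in codes]


# ---------------------------------------------------------------------------
# Turing-ready mapping of simulation snapshots
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TuringReadyResult:
    mask: np.ndarray              # boolean, Turing-ready cells
    out_of_range: np.ndarray      # boolean, (S, Y) outside the scanned ranges
    n_turing: int
    strip_extent: float           # transverse extent (space units) of the
                                  # largest Turing component near the tip
    tip_xy: tuple[float, float] | None


def turing_ready_map(state, p: ModelParams, regime_map: RegimeMap,
                     dx: float = 0.3, tip_radius_steps: int = 15) -> TuringReadyResult:
    """Look up each cell's (S, Y) in a regime map; report the tip strip.

    ``state`` is a full-model snapshot with fields ``A``, ``S``, ``Y``.  The
    leading activator peak is the cell of maximal A; the strip metric is the
    transverse (row) extent of the largest connected Turing component whose
    centroid lies within ``tip_radius_steps`` grid steps of that peak.
    """
    codes = regime_map.lookup(state.S, state.Y).reshape(state.S.shape)
    out = codes == -1
    mask = codes == REGIME_CODES["turing"]
    n_turing = int(mask.sum())
    tip_xy = None
    strip = 0.0
    if np.any(state.A > 0):
        i0, j0 = np.unravel_index(int(np.argmax(state.A)), state.A.shape)
        tip_xy = (j0 * dx, i0 * dx)
        if n_turing:
            lab, nlab = ndimage.label(mask, structure=np.ones((3, 3), int))
            best = 0
            for L in range(1, nlab + 1):
                rows, cols = np.nonzero(lab == L)
                ci, cj = rows.mean(), cols.mean()
                if np.hypot(ci - i0, cj - j0) <= tip_radius_steps:
                    size = rows.size
                    if size > best:
                        best = size
                        strip = (rows.max() - rows.min() + 1) * dx
    return TuringReadyResult(
        mask=mask, out_of_range=out, n_turing=n_turing,
        strip_extent=float(strip), tip_xy=tip_xy,
    )
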