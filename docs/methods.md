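# Methods

## Model

The package implements a four-variable reaction–diffusion model of
branching morphogenesis in the Meinhardt net-formation family:

```
∂A/∂t = c·S·A²/H − μ·A + ρ_A·Y + D_A ∇²A
∂H/∂t = c·S·A²   − ν·H + ρ_H·Y + D_H ∇²H
∂S/∂t = c₀ − γ·S − ε·Y·S       + D_S ∇²S
∂Y/∂t = d·A − e·Y + Y²/(1 + f·Y²)
```

`A` is an autocatalytic activator whose self-enhancement requires substrate
`S` and is antagonised by the inhibitor `H` (the `H` in the denominator);
both `A` and `H` are additionally secreted by differentiated cells at rates
`ρ_A`, `ρ_H`. Substrate is produced everywhere at `c₀`, decays at `γ`, and
is consumed by differentiated cells through the stoichiometric sink
`ε·Y·S`. The differentiation marker `Y` is a bistable switch: its sigmoidal
self-activation `Y²/(1+f·Y²)` against linear decay `e·Y` gives two stable
states (≈ 0.11 and ≈ 0.89 at the default `e = 0.1`, `f = 10`), and a
sufficient activator level (`A ≳ 0.33` at `d = 0.008`) flips a cell
irreversibly to the committed state. `Y` does not diffuse — it is a
cell-state label, not a morphogen.

Mechanistically: the leading activator peak depletes `S` beneath itself and
migrates toward fresh substrate; `Y` commits along the path, so the
`Y`-pattern records the trajectory of activator peaks and *is* the branched
tree. The reduced model freezes `Y(x,y,t)` and `S(x,y,t)` as prescribed
parameter fields and integrates only `A`/`H`, which isolates the local
patterning dynamics from stalk growth.

## Parameter calibration

The model's canonical parameter sets circulate as ordered value lists
without symbol labels, so attaching symbols to values is itself a
calibration problem. We fixed the attachment by requiring the package's own
acceptance behaviours, in this priority order: (i) the homogeneous stalk
state `(S, Y) = (0.6, 1.0)` must be linearly stable with a non-positive
dispersion relation, while the inhomogeneous stalk rectangle patterns under
identical constants; (ii) the `(S, Y)` plane must contain oscillatory,
Turing and stable regimes with the differentiation trajectory crossing them
in that order; (iii) the full model must exhibit confined morphogenetic
growth — a seed that neither freezes nor floods the domain with
differentiated tissue.

An exhaustive scan of the admissible assignments (diffusion coefficients
must satisfy `D_H ≫ D_A`; a uniform rest state must not self-ignite, which
requires `ν < 2μ` starting from the standard dilute initial values; the
stalk's baseline activator `ρ_A·Y/μ` must stay below the `Y`-switch
threshold in neighbouring tissue) leaves a single assignment satisfying all
three groups:

| D_A  | D_H  | c    | μ    | ν    | ρ_A  | ρ_H  | γ    | c₀   | ε        | d     | e   | f  | D_S  |
|------|------|------|------|------|------|------|------|------|----------|-------|-----|----|------|
| 0.002| 0.26 | 0.04 | 0.16 | 0.02 | 0.03 | 1e-4 | 0.02 | 0.02 | scenario | 0.008 | 0.1 | 10 | 0.06 |

`ε` is the side-branch/tip-split switch and is set per scenario (0.0025 and
0.025 for sparse/denser side branching, 1.0 for vigorous growth). `c₀/γ = 1`
fixes the undisturbed substrate background at `S = 1`. Units are
nondimensional: lengths in "space units" (one lattice step = 0.3), time in
"time units" (one step = 0.036).

Two alternative attachments are worth recording. Swapping `μ ↔ D_H` order
(`μ = 0.03, ν = 0.26`) makes the inhibitor slave to the activator, so the
uniform rest state ignites from any positive activator level (`dA/dt → ν −
μA > 0`) and the domain floods; it also erases the oscillatory regime
entirely (the kinetic trace `2cSA*/H* − μ − ν` is negative everywhere when
`μ < ν`). Swapping `ν ↔ ρ_A` (`ν = 0.03, ρ_A = 0.02`) makes the control
point `(0.6, 1.0)` Turing-unstable. Both fail the quiescent-control
behaviour and were rejected.

## Transverse wavelengths

The regime-plane *geometry* (which `(S, Y)` pairs are oscillatory, Turing
or stable) depends only on the kinetics. The *wavelength* of the fastest
Turing mode also depends on the diffusion pair. With the lattice-simulation
diffusion (`D_H = 0.26`) the crescent's fastest modes have `k* ≈ 1.0–1.6`
(wavelengths 4–6 space units). The package's transverse-wavelength
analysis (`transverse_analysis_params`, used by `scripts/acceptance.py`)
evaluates the crescent with a longer inhibitor range, `D_H = 2.0`, the
regime in which the analysis is conventionally quoted; there the three
crescent samples give `k* ≈ 0.63–0.95`, i.e. wavelengths of 6.6–9.9 space
units. This is the length a widening tip must reach to support two peaks.
Note `D_H = 2.0` is an *analysis* setting only: at the default lattice
resolution it would violate the explicit-scheme stability limit, so
simulations always use the calibrated table above.

## Numerics

* Explicit forward Euler with a Jacobi update (all fields advance from the
  same time level); four-point Laplacian; no-flux boundaries by mirrored
  (edge-copied) stencil neighbours, which makes the discrete diffusion
  operator exactly conservative.
* `dx = 0.3`, `dt = 0.4·dx²` by default; `GridSpec` enforces the diffusion
  stability limit `dt·max(D)/dx² ≤ 0.25` at run time. With the default
  tables all decay and consumption factors also satisfy `dt·rate < 1`, so
  non-negative states stay non-negative (verified by test).
* The autocatalysis denominator is guarded as `max(H, 1e-8)`; `H = 0`
  arises only in degenerate initial states and the floor sits far below
  every dynamical scale.
* Integrators abort with the offending field and cell if anything goes
  non-finite (checked every 2,000 steps during long runs).
* Determinism: runs are exactly reproducible; the only randomness is the
  optional multiplicative initial perturbation, driven by a recorded seed.

## Equilibria, selection and classification

Eliminating `H = (cS·A² + ρ_H·Y)/ν` reduces the homogeneous A/H equilibrium
condition to a cubic in `A`; roots are polished by Newton iteration to
kinetic residuals below 1e-10. Classification and dispersion use the
equilibrium actually visited by simulations: the root nearest the end point
of a damped (positivity-preserving Patankar–Euler) time integration from
the standard initial values `(A, H) = (0.001, 0.01)`. Non-convergent
(oscillatory) points are matched to the non-trivial focus their orbit
encircles. `Y = 0` (no differentiated cells anywhere) admits only the
boundary state and is labelled `trivial`.

Regimes: `stable` if the leading kinetic eigenvalue has `Re ≤ 0` (a
tolerance of 1e-12 at the boundary counts as stable — the boundary has
measure zero) and no wavenumber grows; `turing` if the kinetics are stable
but `D_H·J₁₁ + D_A·J₂₂ > 2√(D_A·D_H·det J)` opens a band of growing
`k > 0`; `oscillatory` if the leading eigenvalue is complex with positive
real part; `unstable_other` otherwise. The default `k`-grid spans `[0,
π/dx]` (the lattice Nyquist wavenumber) with 200 points; `k*` is refined by
bounded scalar minimisation within one grid spacing. Crescent samples for
wavelength analysis are chosen deterministically: Turing-classified scan
cells at the low-S end, the median-S column and the high-S end of the
crescent, taking the median-Y cell within each column.

At finite scan resolution a few cells at the crescent's thin low-S tip can
detach from the main component; connectivity checks therefore require the
dominant component to hold ≥ 95% of Turing cells.

## Prescribed stalk domains (the synthetic-field generator)

`StalkGeometry` builds the reduced model's parameter fields: a rectangle of
`width × length` lattice steps (default 5 wide), edge-anchored (one open
end; the mirror boundary closes the other) or centred (two open ends), with
`Y = 1` and a scenario-set `S` (0.4–0.6) inside and zeros outside, or a
transverse substrate landscape (S low inside, high outside) for migration
studies. Growth adds one length step every `growth_interval` time steps —
the first extension completing exactly at `step = growth_interval` — and
newly added cells take the inside levels instantly (growth is commanded,
not ramped). The generator emulates the stalk geometry of the decoupled
experiments; it deliberately omits curved or branched stalks, sub-cell
growth, and any feedback of `A` onto `Y`/`S` (that feedback is exactly what
the full model adds back).

What these prescribed-field experiments show therefore applies to the
idealised, noise-free stalk; in full-model tissue the stalk edges are
rough, the levels inhomogeneous, and growth is self-generated.

## Pattern metrics conventions

* Peak detection: 8-neighbour local maxima above a threshold, plateaus
  merged to a single centroid, maxima closer than `min_separation`
  (default 3·dx = 0.9 space units) merged keeping the higher. The default
  threshold is 3× the spatial median (robust to background shifts);
  scenario analyses use 0.25× the frame maximum because the off-stalk
  background is essentially zero. First-appearance calls use 0.5× the
  frame maximum to avoid counting nascent shoulders.
* Tracking: frame-to-frame nearest-neighbour linking within a match radius
  (default 5·dx; scenario analyses of full-model runs use 8·dx to cover
  fast tip motion); one parent linked to two children in
  the next frame is a split; generations count along lineages from the
  founding peak. Snapshot cadence must keep peak motion below the radius.
* Side branches: the `Y` field is binarised at 0.5 (between the switch's
  two stable states), skeletonised, and the main stalk taken as the longest
  geodesic through the skeleton; attached off-path components of ≥ 2
  pixels count as branches. Consequence of the convention: a terminal
  branch longer than the remaining main path is itself absorbed into the
  main path. The laterality score is the fraction of consecutive one-sided
  branches that alternate sides (+1 perfect alternation); opposite-sided
  branches at the same station are reported as symmetric pairs and score 0.
  Thresholds for *calling* a pattern "alternating" are a reporting
  convention, not a model prediction.

## Problem sizes

Development-scale defaults reproduce the canonical geometry (200×200
lattice, 5×80 stalks, growth every 10,000 steps). The test and acceptance
suites run the same experiments desk-scale: grids of 120×40–150×150,
schedules of 4×10⁴–5×10⁵ steps, the growth-speed comparison at a matched
final stalk length of 40 steps, and the regime scan at 150×150 samples.
The scenario driver records the scale of every run in its config output.

## Known limitations

* **Interior-peak suppression by ρ_H.** Raising the differentiated-cell
  inhibitor secretion widens peak spacing monotonically, but under the
  calibrated constants the stalk interior still carries a peak at
  `ρ_H = 4e-4` (suppression requires roughly twice that). The acceptance
  test that pins complete suppression at `ρ_H = 4e-4` fails and is left
  failing: no admissible symbol attachment gives both that suppression
  point and the quiescent homogeneous control.
* **Dichotomous tip splitting in the full model.** At `ε = 1.0` the full
  model grows confined trees whose new tips arise by insertion and
  transverse outgrowth (right-angle side branches) rather than by symmetric
  division of the leading peak; genuinely dichotomous splits require the
  differentiation footprint of a tip (set by `√(D_A/μ)·ln(A_peak/A_flip)`,
  ≈ 1.3 lattice steps here) to approach the transverse Turing
  half-wavelength (≈ 10 steps), which no admissible attachment achieves.
  The tip-splitting acceptance test documents this and fails honestly. The
  transverse instability itself is fully demonstrated in the reduced
  setting (perturbed Turing-point simulations pattern periodically, and
  Turing-ready cells concentrate at growing full-model tips).
* The reduced-model transverse-migration scenarios (substrate landscape)
  record peak offsets but do not reproduce outward migration, for the same
  footprint reason; in the full model the mechanism manifests as actual
  side-branch outgrowth.
* No implicit or adaptive time stepping, no 3-D domains, no GPU kernels;
  single-precision or sub-cell growth is out of scope.
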