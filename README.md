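# branchrd

Reaction–diffusion mechanisms of branching morphogenesis: why growing
epithelial trees (the embryonic lung is the archetype) produce **side
branches** — new buds inserted sequentially along a growing stalk — and
**tip splits** — one growing tip dividing into two — and what switches one
mode into the other.

`branchrd` is a research library for modellers of branching organs and for
pattern-formation theorists. It implements, analyses and quantifies a
four-variable activator–inhibitor–substrate model of branching:

```
∂A/∂t = c·S·A²/H − μ·A + ρ_A·Y + D_A ∇²A      (activator)
∂H/∂t = c·S·A²   − ν·H + ρ_H·Y + D_H ∇²H      (inhibitor)
∂S/∂t = c₀ − γ·S − ε·Y·S       + D_S ∇²S      (substrate)
∂Y/∂t = d·A − e·Y + Y²/(1 + f·Y²)             (differentiation switch)
```

An autocatalytic activator `A`, fuelled by a consumable substrate `S` and
antagonised by a fast-diffusing inhibitor `H`, drives an irreversible,
bistable differentiation marker `Y` (`Y = 1`: committed stalk tissue). The
leading activator peak consumes substrate under itself and migrates toward
fresh substrate; `Y` records its path, so the differentiated pattern *is*
the branched tree.

The package decouples this into two tractable sub-processes and provides
the tools for both:

* **Reduced A/H model on prescribed stalks** (`run_reduced`,
  `StalkGeometry`): `Y(x,y,t)` and `S(x,y,t)` become designated parameter
  fields — rectangular stalks, stationary or elongating at a set cadence.
  This isolates the **longitudinal instability**: a far-from-equilibrium,
  sequential insertion of activator peaks along the stalk that starts at
  its open end. It is *not* a Turing instability — at the stalk's own
  levels (`Y = 1, S = 0.6`) the homogeneous state is linearly stable.
* **Linear stability analytics** (`scan_plane`, `dispersion`,
  `classify_regime`, `turing_ready_map`): equilibria of the A/H kinetics
  (a cubic after eliminating `H`), dispersion relations
  `λ(k) = max Re eig(J − diag(D_A, D_H)k²)`, and the classification of the
  `(S, Y)` plane into **oscillatory / Turing / stable** regimes. A
  differentiating cell (S falling, Y rising) crosses them in exactly that
  order; tips whose cells linger in the Turing crescent are "Turing-ready"
  and split when wide enough — the **transverse instability**.
* **Full 4-variable simulator** (`run_full`): explicit finite differences
  (forward Euler, four-point Laplacian, no-flux boundaries) growing whole
  trees from a small differentiated seed.
* **Pattern metrics** (`detect_peaks`, `peak_spacing`, `track_splits`,
  `count_side_branches`): peak detection with plateau/merge handling,
  spacing statistics, frame-to-frame lineage tracking with split
  generations, and skeleton-based side-branch counting with a left/right
  alternation score.

## Worked example

Quiescence of the homogeneous stalk state, the signature that stalk
patterning is far from equilibrium (`examples/dispersion_control.py`):

```text
equilibrium at (S=0.6, Y=1.0): A* = 0.3072, H* = 0.1183
dispersion: max growth over k in [0, 10.5] = -0.0277 (<= 0: no unstable wavenumber window)
2% random perturbation: max deviation 0.020 -> 4.72e-14
-> the perturbed field returns to equilibrium (well within 1%).
```

Every mode `k` decays (`λ_max < 0`), and a 2%-perturbed simulation of the
same state relaxes to machine precision. Contrast
`examples/stalk_patterning.py`: the *same* A/H constants on an
*inhomogeneous* stalk rectangle produce a peak at the stalk's open end
within 2,000 steps and a periodic train along the stalk —

```text
stalk: 5 x 80 grid steps, open end at x = 23.7 space units
first peak detected at step 2000, x = [23.4]
final pattern: 3 peaks at x = [ 1.2 12.3 23.4]
mean peak spacing: 11.10 space units
```

Other examples: `branching_tree.py` (a full-model tree with side branches,
rendered in ASCII), `growing_stalk_insertion.py` (peak birth always at the
moving tip), `regime_scan.py` (the oscillatory → Turing → stable plane and
crescent wavelengths), `peak_tracking.py` (split-lineage bookkeeping).

A thin CLI mirrors the library for shell use:

```bash
branchrd list-scenarios
branchrd reproduce figS2 --scale reduced --outdir out/
branchrd dispersion -S 0.6 -Y 1.0
branchrd scan-regimes --resolution 150
```

`reproduce` re-runs a registered scenario (the ids follow a figure-style
catalogue, `fig2a` … `figS2`) deterministically, writes HDF5 snapshots,
CSV metrics and a JSON assertion summary, and exits non-zero if a scenario
assertion fails.

## Layout

```
src/branchrd/     params, core (integrators), domains (prescribed stalks),
                  stability, metrics, scenarios, io, cli
examples/         one narrative script per capability
tests/            unit + property suites and tests/test_acceptance.py
docs/methods.md   model, calibration, numerics, conventions, limitations
```
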