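"""Regime plane of the A/H subsystem and the differentiation trajectory.

Classifies the homogeneous A/H dynamics at every (S, Y) level: oscillatory
at high substrate / low differentiation (outside the stalk), a crescent of
Turing-unstable pairs, and a stable region above it (the mature stalk).  A
differentiating cell (S falling, Y rising) crosses oscillatory -> Turing ->
stable; while inside the crescent it is "Turing-ready" and can seed the
transverse instability that splits a widening tip.
"""
import numpy as np

from branchrd import ModelParams, fastest_mode, scan_plane, select_crescent_samples
from branchrd.stability import trajectory_regimes, transverse_analysis_params

p = ModelParams()
m = scan_plane(resolution=100, p=p)
counts = {lbl: int(m.mask(lbl).sum())
          for lbl in ("oscillatory", "turing", "stable")}
print(f"regime counts on a 100x100 (S, Y) lattice: {counts}")

labels = trajectory_regimes(p, 101)
seq = [l for i, l in enumerate(labels) if i == 0 or l != labels[i - 1]]
print("differentiation trajectory (S: 1.0 -> 0.1, Y: 0 -> 1):",
      " -> ".join(seq))

p_tr = transverse_analysis_params(p)
m_tr = scan_plane(resolution=100, p=p_tr)
print("fastest-growing transverse modes across the crescent:")
for S, Y in select_crescent_samples(m_tr, n=3):
    k, lam = fastest_mode(S, Y, p_tr)
    print(f"  (S={S:.2f}, Y={Y:.2f}): k* = {k:.3f}, "
          f"wavelength = {2 * np.pi / k:.1f} space units")
print("-> wavelengths of ~6-10 space units set the stalk width needed "
      "for a tip to support two peaks and split.")
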