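# coroperf

Hybrid simulator of myocardial contrast-agent perfusion: a discrete
coronary arterial tree coupled to a continuum porous-media model of the
heart wall, for first-pass (FP) and late-enhancement (LE) perfusion
read-outs in healthy, ischemic and infarcted tissue.

It is aimed at computational-physiology work on the link between
coronary anatomy (where a stenosis sits, how severe it is) and the
spatio-temporal contrast patterns seen in MRI perfusion exams: a
hypoperfused dark region at first pass, and a bright fibrotic scar that
retains gadolinium at late enhancement.

## Model

* **Vasculature** — three binary arterial trees (LCX, LAD, RCA), one per
  equal-area territory of an annular short-axis slice, generated by
  constrained constructive optimization: terminals are added one at a
  time, each connection optimized to minimize the total intravascular
  volume V = π Σ lₛ rₛ², subject to Poiseuille flow (Rₛ = 8η lₛ/(π rₛ⁴)),
  equal terminal outflows Q_term = Q_perf/N_term, a common terminal
  pressure p_term, and Murray's bifurcation law r₀^γ = r₁^γ + r₂^γ
  (γ = 3). Defaults: Q_perf = 1 mL/min per tree, p_perf = 100 mmHg,
  p_term = 60 mmHg, 355 terminals over the three trees.
* **Stenosis** — a chosen branch has its subtree flow divided by α
  (α = 25 ischemia, 30 infarction) with the root inflow held at Q_perf.
* **Contrast transport** — a Gaussian bolus (peak at 25 s, width 6 s)
  enters the tree roots; intravascular CA follows an explicit
  finite-volume advection-diffusion scheme on the Δx = 0.25 mm node
  graph of the tree; terminals deliver CA to their nearest tissue cell
  (endothelial valve leak plus first-pass extraction of the terminal
  outflow); the interstitium diffuses, clears venously (k_e) and, in
  scar, adsorbs CA into a fibrotic compartment (k_ef) with slow
  clearance (k_f); a 1D advection-diffusion-decay line returns part of
  the CA to the coronary inlets (systemic recirculation with renal
  elimination).

Every transfer is tracked: the mass ledger (tree + tissue + fibrosis
against inflow, venous clearance and microcirculatory washout) closes to
machine precision at every sample time.

## Worked example

```python
from coroperf import ScenarioConfig, assemble, run

shared = dict(n_term_total=90, seed=11)          # scaled-down vasculature
healthy  = ScenarioConfig.healthy(**shared, t_end=60.0)
system   = assemble(healthy)                     # domain, trees, flows, graph
res_h    = run(healthy, system=system)

ischemia = ScenarioConfig.ischemia(**shared, t_end=60.0)   # alpha = 25
res_i    = run(ischemia, system=assemble(ischemia, trees=system.trees))

fp = lambda r: r.series.iloc[(r.series.t - 50).abs().argmin()]
print(f"FP damaged-ROI signal: healthy {fp(res_h).roi_damaged_ce:.3f}, "
      f"ischemia {fp(res_i).roi_damaged_ce:.3f}")
print(f"FP remote-ROI signal:  healthy {fp(res_h).roi_remote_ce:.3f}, "
      f"ischemia {fp(res_i).roi_remote_ce:.3f}")
print(f"mass-ledger residual:  {res_i.ledger.closure_residual.abs().max():.2e}")
```

prints

```
FP damaged-ROI signal: healthy 1.600, ischemia 0.374
FP remote-ROI signal:  healthy 0.877, ischemia 0.877
mass-ledger residual:  1.06e-14
```

The stenosed territory's first-pass signal drops about four-fold while
the remote territory is untouched — the dark hypoperfused region of an
FP exam. An infarction run (`ScenarioConfig.infarction`, α = 30, with a
fibrotic scar in the obstructed territory) run to `t_end=600` inverts
the contrast at late enhancement: the scar's adsorbed compartment keeps
the damaged ROI brighter than the remote one after the rest of the
myocardium has washed out.

There is also a thin CLI (`coroperf grow | flow | run | grid-study |
fixtures`) that writes trees and flow solutions as JSON/CSV/legacy-VTK
files and scenario results (ROI time series, mass ledger, FP/LE field
snapshots) to an output directory; configs are YAML mirrors of
`ScenarioConfig`.

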