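# hepasim

An off-lattice, agent-based simulator of liver tissue, built to study
**liver regeneration after partial hepatectomy (PH)** and the **recurrence
of hepatocellular carcinoma (HCC)** in the remnant liver.  It is aimed at
computational-biology researchers who want a small, fully scriptable
Python implementation of the multicellular-simulator recipe: a voxelized
implicit reaction–diffusion microenvironment with vessel (Dirichlet)
nodes, mechanically interacting spherical cell agents with directed-graph
cycle and death models and three-compartment volume dynamics, and
scenario drivers with calibrated regulation rules.

## The model in brief

* **Substrates.** Oxygen and an abstract injury growth factor GF obey
  ∂ρ/∂t = D∇²ρ − λρ + cell sources/sinks, solved by first-order implicit
  operator splitting (decay, then x/y/z locally-one-dimensional sweeps,
  each a Thomas tridiagonal solve per strip) with zero-flux boundaries.
  Vessels are Dirichlet voxels re-clamped after every sweep; portal triads
  form a hexagonal lattice of vessel columns, and any tagged voxel that
  accumulates ≥ 5 cells becomes a new vessel (angiogenesis).
* **Cells.** Hepatocytes and cancer cells are overdamped spheres with
  piecewise-quadratic adhesion/repulsion forces, Adams–Bashforth position
  updates, Ki-67-based cycle graphs (Ki67− → Ki67+pre → division →
  Ki67+post; 33.6 h / 38.6 h saturated cycle times), apoptosis/necrosis
  death cycles, and fluid/nuclear/cytoplasmic volume ODEs.
* **Regulation.** After a resection of fraction f, hepatocytes secrete GF
  in proportion to f until the liver volume reaches its regrowth set
  point.  GF drives hypertrophy (prompt enlargement, a permanently
  retained 1.35× cap, slow reversal of the excess) below the
  proliferation threshold and cycle entry
  r = (1/t_K−)·clamp((GF−GF_prol)/(GF*−GF_prol), 0, 1) above it, further
  gated by local oxygen.  Cancer cells respond to oxygen only.
* **Growth extrapolation.** Gompertz law V(t) = K·exp[ln(V0/K)·exp(−αt)]
  with the two-point specific growth rate α = ln(V2/V1)/(t2−t1), including
  the closed-form inversion for detection times.

See `docs/methods.md` for assumptions, parameter tables and limitations.

## Worked example

Thirty-percent hepatectomy on the default (0.26 mm) liver:

```python
from hepasim import ScenarioConfig, run_regeneration
from hepasim.config import DAY, HepatectomyConfig, ScheduleConfig
from hepasim.quantify import detect_plateau

cfg = ScenarioConfig(
    hepatectomy=HepatectomyConfig(fraction=0.3, time=60.0),
    schedule=ScheduleConfig(t_end=10 * DAY),
    seed=1,
)
sim = run_regeneration(cfg)
series = sim.series()
post = series[series.t_min > 60.0]
day, level = detect_plateau(post.t_day.values, post.liver_volume.values)
print(f"plateau: {level / sim.v_pre:.3f}-fold of the original volume by day {day:.1f}")
print(f"divisions per remnant hepatocyte: "
      f"{post.cum_divisions.iloc[-1] / sim.n_remnant:.2f}")
```

prints

```
plateau: 0.942-fold of the original volume by day 4.5
divisions per remnant hepatocyte: 0.00
```

i.e. after a 30% resection the simulated liver recovers to ~0.94-fold of
its original volume within ~4–5 days purely by hypertrophy (no division
events), while a 70% resection (`fraction=0.7`) recovers to ~0.72-fold by
day ~7 with both hypertrophy and ~0.5 divisions per remnant hepatocyte —
the hyperplasia-vs-hypertrophy split the model is calibrated to.

The same scenarios are exposed on the command line:

```bash
hepasim regenerate --fraction 0.7 --days 14 --seed 1 --out out_ph70
hepasim recurrence --replicates 5 --seed 1
hepasim sensitivity --replicates 2 --seed 1
hepasim gompertz --alpha "0.053 %/day" --detection-mm 5
```

`regenerate` writes the time series (CSV), final cell snapshots (CSV and
legacy-ASCII VTK), an oxygen field (VTK) and a JSON manifest with the
config hash and seed.

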