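# epiland

Quantitative mapping of Waddington's "epigenetic landscape" for two-gene
fate-decision circuits, from a deterministic path-integral quasi-potential —
plus exact stochastic (Gillespie) population simulations that connect the
landscape's geometry to attractor occupancy.

## Who this is for

Systems biologists studying binary (or binary-plus-progenitor) cell-fate
decisions governed by cross-antagonistic pairs of master regulators (the
PU.1/GATA1 archetype). The package turns a two-gene circuit's kinetic
parameters into a surface whose valleys are the circuit's stable expression
states and whose ridges quantify the barriers to stochastic fate switching —
a predictive, mechanistic reading of the classic landscape metaphor.

## The model

A circuit of two genes with product concentrations `x`, `y`:

    dx/dt = f(x, y) = B_X + fold_XX x^n/(K_DXX^n + x^n)
                          + fold_YX K_DYX^n/(K_DYX^n + y^n) − deg_X x
    dy/dt = g(x, y) = B_Y + fold_YY y^n/(K_DYY^n + y^n)
                          + fold_XY K_DXY^n/(K_DXY^n + x^n) − deg_Y y

(basal expression + Hill self-activation + Hill cross-repression + linear
decay). Two named presets are built in: the classic **bistable** toggle
switch (no autoregulation) and a **tristable** circuit whose autoregulation
stabilizes a third, progenitor-like state.

Because the cross-partials `∂f/∂y ≠ ∂g/∂x`, these circuits are non-gradient
systems and admit no closed-form potential. Instead, along an Euler
trajectory with fixed step `Δt` we accumulate the **quasi-potential**

    ΔV_q = −(f Δx + g Δy) = −(f² + g²) Δt ≤ 0,

a Lyapunov function: strictly decreasing along every non-stationary
trajectory and stationary exactly at steady states. Trajectories launched
from a grid of initial conditions are then aligned — same attractor ⇒ same
final level; adjacent starts in different basins ⇒ same initial level (in
least squares over all separatrix-straddling start pairs) — and linearly
interpolated into the landscape surface. Barrier heights are read off as
ridge minimum minus attractor elevation.

The same circuits run as exact jump processes (direct-method SSA with one
lumped production and one degradation channel per gene), so populations of
simulated "cells" can be placed on the landscape and counted per basin.

## Worked example

Map the bistable toggle switch and print its attractor elevations:

```
$ epiland landscape --preset bistable --out out_bistable
attractor 0: location (0.2233, 2.123) elevation 0.561949
attractor 1: location (2.185, 0.2055) elevation 0
wrote surface to out_bistable
```

The two valleys are the y-dominant state (0.22, 2.12) and the x-dominant
state (2.19, 0.21). With the deepest valley pinned at elevation 0, the
y-dominant valley floor sits 0.56 quasi-potential units higher — escaping it
is correspondingly cheaper than escaping the deeper valley.

Fixed points of the tristable circuit (three attractors, two saddles; A/B
are the differentiated lineages, C the progenitor on the diagonal):

```
$ epiland fixed-points --preset tristable --out out_fp
    stable (A): (0.0160257, 19.984)
    saddle: (3.36173, 16.6383)
    stable (C): (10, 10)
    saddle: (16.6383, 3.36173)
    stable (B): (19.984, 0.0160257)
```

A stochastic population of 200 cells started in attractor B at high
ultrasensitivity (n_H = 10), run to t = 1000:

```
$ epiland ssa --preset tristable --set n_H=10 --cells 200 --t-end 1000 \
      --seed 1 --out out_ssa
occupancy A: 0.5%
occupancy C: 0.0%
occupancy B: 99.5%
occupancy unassigned: 0.0%
```

At n_H = 10 the ridges around B are high (≈31 quasi-potential units) and
almost no cell escapes; rerun with `--set n_H=3` and most of the population
leaks over the much lower ridge into C and onward to A. `epiland hill-sweep`
and `epiland basal-shift` tabulate exactly these comparisons (occupancy,
barrier height and attractor elevation per condition).

As a library:

```python
import epiland as el

p = el.get_preset("tristable")
fan = el.build_trajectory_fan(p)          # 41x41 grid of Euler trajectories
surface = el.interpolate_surface(el.align(fan))
el.barrier_height(surface, 2, 1)          # escape barrier B -> C
```

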