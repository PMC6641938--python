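# spindrift

Matrix-free quantum-mechanical simulation of spatially distributed NMR/MRS
experiments: coupled spin systems evolving together with diffusion, flow,
pulsed field gradients, radiofrequency pulses and first-order chemical
exchange on periodic spatial grids.

## The problem and who this is for

Simulating a magnetic resonance experiment on a *spatially structured*
sample couples two well-understood worlds: classical transport (diffusion
and flow, a Fokker–Planck problem on a grid) and Liouville-space spin
dynamics (dimension 4^N for N spin-1/2 nuclei). Their composite generator
lives on the Kronecker product `space (x) species (x) spin`, whose dimension
— millions even for modest problems — rules out ever forming the operator
as a matrix. The observation this package is built on is that the generator
is always a *short sum of Kronecker products* of small factors,

    G = sum_k a_k(t) · M_k (x) K_k (x) S_k,

and that every algebraic service a simulation needs — application to a
state, transposition, 1-norm estimation, exponential propagation — can be
delivered from matrix–vector products alone, with the Kronecker products
never opened: `[A (x) B] vec(V) = vec(B V Aᵀ)`. Time propagation is
scaled-and-squared truncated Taylor,

    rho(t+dt) = exp(G·dt) rho(t),   dt chosen so ||G·dt||_1 <= 1,
    series truncated at j_max = ceil(Gamma⁻¹(1/eps) − 1)  (18 in double),

with the step norm supplied by Hager's 1-norm estimator (matrix-vector
products only). The package is aimed at magnetic resonance methods people
who need quantitative simulations of diffusion/flow-weighted spectroscopy,
solvent suppression, or localised spectroscopy of coupled spin systems —
problems where treating voxels independently is wrong precisely because
transport couples them.

The library provides, as separate composable modules: the polyadic
(sum-of-Kronecker) linear algebra engine; spin systems and Liouville
superoperators; periodic grids, transport generators and the spatial
Nyquist/finite-difference accuracy calculus; first-order exchange networks;
a pulse-sequence engine (delays, hard/soft pulses, gradients, acquisition);
and canned experiments (pulsed-gradient spin-echo diffusion with
D-recovery, grid-convergence studies, DPFGSE excitation sculpting,
PRESS-style voxel selection) with a small CLI on top.

## Worked example: recovering a diffusion coefficient

The pulsed-gradient spin echo (90° – g·δ – delay – 180° – g·δ) attenuates
with gradient amplitude as the Stejskal–Tanner law
`S(g)/S(0) = exp(−γ²δ²g²D(Δ−δ/3))`. Simulating it end to end — transverse
magnetisation winding into phase spirals under the gradient, diffusing,
refocusing — and fitting the law back recovers the diffusion coefficient
that went into the transport generator:

```python
import numpy as np
from spindrift import StejskalTannerSetup, stejskal_tanner_run

setup = StejskalTannerSetup(npts=2000, stencil=7, g_list=(0.0, 0.1, 0.2, 0.3))
curve = stejskal_tanner_run(setup)
for g, r, a in zip(curve.g_values, curve.ratios, curve.analytic):
    print(f"g = {g:4.2f} T/m   S/S0 = {r:.4f}   analytic {a:.4f}")
print(f"fitted D = {curve.fitted_d:.4e} m^2/s   (r^2 = {curve.r_squared:.6f})")
```

prints

```
g = 0.00 T/m   S/S0 = 1.0000   analytic 1.0000
g = 0.10 T/m   S/S0 = 0.7746   analytic 0.7755
g = 0.20 T/m   S/S0 = 0.3621   analytic 0.3617
g = 0.30 T/m   S/S0 = 0.1028   analytic 0.1015
fitted D = 1.7965e-09 m^2/s   (r^2 = 0.999989)
```

The sample is the default 1.5 cm single-proton phantom (4.6 ppm at
11.74 T), gradient pulses 2 ms, diffusion delay 50 ms, true
D = 18×10⁻¹⁰ m²/s: the simulated ratios track the closed form to a few
parts per thousand on this 2000-point grid, and the weighted log-linear fit
returns D to 0.2%. Refining the grid (`npts=5000`) brings the fit inside
0.1%; `grid_convergence_study` tabulates the monotone error decay against
grid size and stencil order, and `setup.nyquist_report()` gives the spatial
Nyquist requirement that governs it.

The same `Problem`/`Simulation` layer drives the other experiments, e.g.
solvent suppression:

```python
from spindrift.presets import solvent_solute_network
from spindrift.spatial import Grid
from spindrift.experiments import dpfgse_run

net = solvent_solute_network(solute_j=3.0)
result = dpfgse_run(net, Grid((1280,), (0.015,)), mode="suppression")
print(result["amplitudes"])   # solvent crushed ~1000x, solute retained
```

A `spindrift` console command exposes the canned experiments
(`st-run`, `st-converge`, `dpfgse`, `press`, `grid-audit`) over YAML/JSON
configs, writing CSV curves/spectra.

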