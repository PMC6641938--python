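# Methods

`spindrift` simulates magnetic resonance experiments on samples where spin
dynamics is coupled to classical spatial dynamics — diffusion, flow, pulsed
field gradients, chemical exchange. This note records the model, the
numerical choices, and what the shipped tests do and do not demonstrate.

## The composite evolution problem

The state is a flat complex vector over `space (x) species (x) spin`, ordered
`[X][Y][Z][species][spin]` with the last factor fastest. Its equation of
motion is

    d rho/dt = G(t) rho,
    G(t) = sum_k a_k(t) * M_k (x) S_k

where each `M_k` is a per-axis spatial operator (finite-difference or Fourier
differentiation circulant, coordinate diagonal, phantom diagonal) and each
`S_k` a species/spin-block superoperator. The sum is short — a handful of
terms — while the dimension of the operator it represents is the product of
all factor dimensions. The central design commitment is that this sum is
**never opened**: `Polyadic` stores the terms (plus optional prefix/suffix
multiplier chains) and replays them against the state vector term by term.
The state vector itself is kept uncompressed; only generators are
compressed, because tensor-compressed states lose accuracy over long
evolutions while uncompressed states comfortably fit in memory for any
problem a desk machine can time-step.

Column-wise vectorisation fixes all index conventions:
`[A (x) B] vec(V) = vec(B V A^T)`, so with C-ordered reshape the i-th
Kronecker factor acts on axis i of the reshaped state. Multiplication by
identity factors is skipped; identity factors store only their dimension.
Diagonal factors (coordinates, phantoms, Zeeman commutation superoperators,
which are diagonal in the Zeeman product basis) store only their diagonal and
apply as an elementwise broadcast along their own axis — no dimension
reordering at all. The first and last factors of a chain are likewise applied
without axis permutation.

## Time propagation

`expmv(G, x, T)` evaluates `exp(G T) x` without forming the exponential:

1. Estimate `||G||_1` by Hager's method — a lower-bound power-type iteration
   that needs only products with `G` and its adjoint (obtained through the
   stored transpose), one starting column (the normalised all-ones vector)
   and at most 5 sweeps. A lower bound is safe here because the Taylor series
   has infinite convergence radius; the estimate only sets the step size, and
   in practice it lands on the exact maximum column sum for the operators in
   this package (diagonally dominated, nonnegative-pattern factors).
2. Split `T` into `2^n` substeps, `n = ceil(log2(T ||G||_1))` clamped at 0,
   so the scaled generator has 1-norm (hence spectral radius) at most one per
   substep. This prevents the scaling-and-squaring "hump".
3. Per substep, run the truncated Taylor series to order
   `j_max = ceil(Gamma^{-1}(1/eps) - 1)` — 18 for double precision — with an
   early exit once the running term's max-norm falls below `eps` times the
   accumulated sum's.

`optimal_squaring_skip` implements the propagator-squaring trade-off
(`max{0, ceil[log2(N^(alpha-beta)/(k ln 2))]}`) for the explicit-matrix path;
it is exposed for planning but the simulator itself always takes the
matrix-free route, which is the regime this package exists for.

Time-dependent coefficients (gradient ramps, pulse envelopes) are treated as
piecewise constant over event slices; `expmv` is called once per slice. No
Magnus correction is applied — the sequences simulated here are built from
piecewise-constant events.

## Spin dynamics

Spin-1/2 systems only. Hilbert operators are sparse Kronecker products of
Pauli halves; Liouville superoperators act on column-wise vectorised density
matrices (dimension `4^N`, explicit sparse — the spin side is small by
construction; it is the space (x) spin product that is never materialised).
Simulations run in the rotating frame at a configurable transmitter offset;
shifts enter as offsets `omega_n = (delta_n - delta_ref) 1e-6 gamma_n B0`
(rad/s) and scalar couplings as `2 pi J (SxSx + SySy + SzSz)`. Under these
conventions the detected `S+` coherence of a spin at positive offset evolves
as `exp(-i omega t)` and appears at positive frequency of the spectrum axis.

Relaxation is phenomenological (extended Bloch): coherences damp at `r2`,
the longitudinal manifold at `r1` toward thermal equilibrium. The
equilibrium drive is the rank-one term `r1 |vec(rho_eq)><vec(1)|`, which
keeps the equation homogeneous and linear (the drive is proportional to the
conserved trace) — inversion recovery comes out as `1 - 2 exp(-r1 t)`
exactly. Equilibrium is the high-temperature linearised state with the unit
component carried explicitly and per-spin polarisations normalised to one.

## Spatial dynamics

Grids are uniform and periodic (1–3 dimensions), voxel centres at
`x_i = -L/2 + (i + 1/2) h`, gradient origin at the sample centre. Periodic
boundaries are the only supported kind; concentration phantoms should leave
white space at the edges so transport does not fold over.

Derivatives: central finite differences (3/5/7-point, periodic circulants)
or dense Fourier spectral matrices. Diffusion with constant scalar `D` is
`D` times the per-axis second-derivative chain (three terms in 3D, each with
two identity factors); a constant tensor adds the `D_ab d_a d_b` cross terms
(up to nine); a spatially varying scalar field is discretised in the
symmetric product form `d_a · diag(D) · d_a` with the same central stencils
— this choice (over flux-form interface averaging) is exactly conservative,
negative semidefinite, and fits the polyadic prefix/suffix structure in any
dimension. Flow uses the conservative form `-d_a · diag(v_a)` (central
stencils, no upwinding; strongly advective problems should use the spectral
operator or a finer grid). All transport generators annihilate the uniform
functional to round-off: total concentration is conserved by construction.

### Grid planning

Pulsed gradients wind phase spirals; the tightest spiral any coherence can
carry sets the highest spatial frequency `Omega_max = max_n (1 + delta_n
1e-6) gamma_n * A`, with `A` the gradient area. Two readings of `A` are
provided: the *cumulative* `integral |g| dt` over the whole sequence (safe:
it assumes every gradient keeps defocusing some coherence) and the largest
*single event* (the practical bound for well-refocused echoes; the
cumulative bound is deliberately cautious). The grid must satisfy
`Omega_max h < pi` (two points per period); `min_grid_points` rounds the
requirement up to a multiple of ten. On top of Nyquist, finite differences
carry a derivative error on the worst-case spiral of
`1 - sin(Omega h)/(Omega h) ≈ (Omega h)^2/6` for the 3-point stencil and the
analogous exact symbol expressions — order `(Omega h)^(stencil-1)` — for the
wider ones. The practical recipe the convergence study reproduces: use the
7-point stencil, start near twice the Nyquist count, refine until the answer
stops moving. A Nyquist audit runs automatically before gradient events and
logs violations rather than aborting, since convergence studies need the
under-resolved regime.

## Chemical kinetics

First-order exchange networks with frozen concentrations. Species each carry
their own spin system; the concatenated species/spin dimension is
`sum_s 4^(N_s)`, which supports unequal spin counts (e.g. a six-spin
metabolite next to two-spin water, 4096 + 16 = 4112). Exchange itself
requires equal Liouville dimensions (identity spin-state mapping): the
generator is `K (x) I_spin` with `K_ij = k_{j->i}`, columns summing to zero,
so total spin-state amplitude is conserved and equal-shift exchange is
observable-invariant. Slow/fast exchange reproduce the two-line and
coalesced lineshape limits.

## Pulse sequences

Hard pulses are ideal spatially uniform rotations, applied through the small
species/spin propagator (`expm` of a `4^N`-block matrix) with the spatial
identity skipped. Soft pulses offer two routes:

* **timeslice** — piecewise-constant envelope with an explicitly tracked
  carrier phase; each envelope sample is internally subdivided so the
  carrier phase advances at most π/8 per slice (undersampling the carrier is
  the classic failure mode of this route);
* **phase-coordinate** — the RF phase becomes an extra periodic coordinate:
  a spectral `-omega_rf d/dphi` term turns the phase, the state enters as a
  discrete delta on the phase grid (32 points by default) and is summed back
  after the pulse. The turning term is time-independent, which is the point:
  only the envelope needs slicing. Both routes agree to <1% on coupled
  two-spin tests; the single-spin inversion profile matches a dense Bloch
  integration oracle voxel by voxel.

Acquisition evolves the state under the background generator between dwell
points and records `<sigma|rho>`, with sigma the gamma-weighted transverse
detection functional times the coil phantom (uniform by default). Spectra
are FFTs with optional exponential apodization and magnitude mode; the
frequency axis is in Hz, zero at the transmitter, positive offsets at
positive frequencies.

## The canned experiments

**Pulsed-gradient spin echo (Stejskal–Tanner).** 90 – g(δ) – delay – 180 –
g(δ), echo read at the end of the second gradient where the winding
refocuses exactly; attenuation ratios against the zero-gradient echo; `D`
recovered by weighted linear least squares of `ln S` on `g^2` (weights
`S^2`), which linearises `S = S0 exp(-gamma^2 delta^2 g^2 D (Delta -
delta/3))` exactly. Defaults: 1.5 cm single-proton sample, 4.6 ppm at
11.74 T, δ = 2 ms, Δ = 50 ms, D = 18e-10 m²/s, g up to 0.5 T/m. On a
5000-point grid with the 7-point stencil the fitted D is within 0.1% of the
input; the convergence study shows the monotone error decay and the stencil
ordering.

**DPFGSE (excitation sculpting).** 90 – [G1, soft 180 + hard 180, G1] –
[G2, soft 180 + hard 180, G2] – acquire, with the selective pulse a
calibrated 10-point Gaussian (flip angle = envelope integral, exact on
resonance). Species inverted by both 180s are refocused; species inverted
only by the soft pulse (suppression mode) or only untouched (selection mode,
hard pulses off) accumulate the full gradient winding and dephase. Per-spec
gradient amplitudes 0.1/0.15 T/m and 1 ms durations on a 15 mm sample; on a
1280-point grid suppression exceeds 10^3 with 97% solute retention. Note the
ceiling: for these gradient areas the continuum dephasing residual is
`|sin(A)|/A ≈ 8.6e-4`, so ~10^3 is what the printed gradient areas can give.

**PRESS-style voxel selection.** Slice-selective 90 on the first axis
(square or Gaussian envelope under gradient, with a refocusing lobe of half
the pulse area), slice-selective 180s on the remaining axes with 4-step
EXORCYCLE phase cycling replacing crusher gradients — crushers dephase
between voxels and cannot clean a per-voxel amplitude map on desk-scale
grids, while the 4-step cycle also cancels the `~2 delta/omega_1` transverse
leakage a slightly off-resonant 180 creates from Mz. The 2-D hotspot is the
product of the per-axis profiles (off-slice residual <5% with Gaussian
pulses); 1-D localisation on the three-region phantom yields a spectrum
dominated by the selected system's multiplets. 3-D grids are supported by
the data model; shipped tests stop at 2-D to stay desk-scale.

## Problem sizes used in the shipped tests

Chosen as the package's own desk-scale study conditions: the full
diffusion-coefficient recovery runs 10 gradient amplitudes on a 5000-point
1-D grid (state dimension 20,000); the convergence study uses 400–1600
points; DPFGSE runs two species (solvent + J-coupled solute, block dimension
20) on 640–1280 points; PRESS uses 240 points in 1-D and 40×32 in 2-D. The
GABA+water and 3-D PRESS dimension arithmetic (2,056,000 and beyond) is
verified as bookkeeping without time-stepping those states.

## What the tests do and do not show

The synthetic fixtures emulate idealised experiments: rectangular gradients
with no stabilisation delay, ideal hard pulses, uniform coils, single-peak
"solvent", no noise, no B0/B1 maps, no susceptibility structure, periodic
samples. Passing tests therefore demonstrate the correctness of the
matrix-free algebra, the propagator, the transport discretisation, and the
sequence logic against analytic and dense-matrix oracles — not instrument
realism. Phenomenological relaxation ignores cross-relaxation and
interaction-tensor mechanisms entirely; restricted spin bases, tensor-train
state compression, GPU execution and non-periodic boundaries are out of
scope.

## Numerical details worth knowing

* `norm1_estimate` is a lower bound by construction; `expmv` only uses it to
  pick the substep count, and a modest underestimate merely trades Taylor
  terms for substeps.
* The Taylor early exit compares against the accumulated sum's max-norm, so
  strongly substepped generators cost far fewer than 18 terms per substep.
* Degenerate inputs: zero-duration events are identities (zero-duration
  *soft pulses* are rejected — an envelope needs support); zero generators
  propagate exactly; `g = 0` gradient events fall back to plain delays.
* Ties in `min_grid_points` resolve upward (strict inequality
  `Omega h < pi`), then round up to a multiple of 10.
* The spectrum axis mirrors the FFT axis because the detected `S+` coherence
  precesses as `exp(-i omega t)`; this is a convention, fixed in one place.
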