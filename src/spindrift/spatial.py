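"""Periodic spatial grids, differentiation matrices, transport generators,
phantoms, and the Nyquist/finite-difference accuracy planning calculus.

Spatial dynamics (diffusion, flow, field gradients) lives on uniform periodic
grids.  Voxel centres sit at ``x_i = -L/2 + (i + 1/2) h`` with ``h = L/n``, so
the gradient origin is at the sample centre.  Differential operators are
central finite-difference circulants (3/5/7-point stencils) or dense Fourier
spectral matrices; all transport generators conserve total concentration
exactly (the all-ones row functional annihilates them).

The planning calculus answers the question "how many grid points does this
pulse sequence need": gradient pulses wind phase spirals of spatial frequency
up to ``Omega_max = gamma * integral |g| dt`` which must stay below the grid
Nyquist limit (``Omega_max * h < pi``), and the finite-difference derivative
of the worst-case spiral ``exp(-i Omega_max x)`` carries a relative error
``1 - sin(Omega h)/(Omega h) ~ (Omega h)^2/6`` for the 3-point stencil (and
the corresponding higher-order expressions for wider stencils).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .polyadic import LinearFactor, Polyadic

__all__ = [
    "Grid",
    "Phantom",
    "TransportSpec",
    "fd_first_derivative",
    "fd_second_derivative",
    "spectral_derivative",
    "diffusion_generator",
    "flow_generator",
    "gradient_zeeman_generator",
    "nyquist_max_frequency",
    "min_grid_points",
    "fd_relative_error",
]

logger = logging.getLogger("spindrift")

# central finite-difference coefficients (one-sided halves), first derivative
_FD1 = {
    3: np.array([1.0 / 2.0]),
    5: np.array([2.0 / 3.0, -1.0 / 12.0]),
    7: np.array([3.0 / 4.0, -3.0 / 20.0, 1.0 / 60.0]),
}
# second derivative: centre coefficient and one-sided halves
_FD2 = {
    3: (-2.0, np.array([1.0])),
    5: (-5.0 / 2.0, np.array([4.0 / 3.0, -1.0 / 12.0])),
    7: (-49.0 / 18.0, np.array([3.0 / 2.0, -3.0 / 20.0, 1.0 / 90.0])),
}


@dataclass
class Grid:
    """Uniform periodic spatial lattice in one to three dimensions.

    ``npts`` and ``extents`` are per-dimension tuples; ``extents`` are in
    metres.  Coordinates span ``[-L/2, L/2)`` with the gradient zero at the
    centre of the sample.
    """

    npts: tuple[int, ...]
    extents: tuple[float, ...]

    def __init__(self, npts, extents):
        npts = tuple(int(n) for n in np.atleast_1d(npts))
        extents = tuple(float(L) for L in np.atleast_1d(extents))
        if len(npts) != len(extents):
            raise ValueError("npts and extents must have the same length")
        if not 1 <= len(npts) <= 3:
            raise ValueError("grids are supported in 1 to 3 dimensions")
        for n in npts:
            if n < 3:
                raise ValueError("at least 3 points per active dimension")
        for L in extents:
            if L <= 0:
                raise ValueError("extents must be positive")
        self.npts = npts
        self.extents = extents

    @property
    def ndim(self) -> int:
        return len(self.npts)

    @property
    def spacing(self) -> tuple[float, ...]:
        return tuple(L / n for L, n in zip(self.extents, self.npts))

    @property
    def nvox(self) -> int:
        return int(np.prod(self.npts))

    def coords(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along ``axis``: -L/2 + (i+1/2)h."""
        n, L = self.npts[axis], self.extents[axis]
        h = L / n
        return -L / 2 + (np.arange(n) + 0.5) * h


@dataclass
class Phantom:
    """Per-voxel amplitude array: concentration, relaxation amplitude, or
    coil receptivity profile."""

    values: np.ndarray
    role: str = "concentration"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.role not in ("concentration", "relaxation-amplitude", "coil-profile"):
            raise ValueError(f"unknown phantom role {self.role!r}")
        if self.role == "concentration" and np.any(self.values < 0):
            raise ValueError("concentration phantoms must be nonnegative")

    def check_grid(self, grid: Grid):
        if self.values.shape != tuple(grid.npts):
            raise ValueError(
                f"phantom shape {self.values.shape} does not match grid {grid.npts}"
            )

    @property
    def flat(self) -> np.ndarray:
        return self.values.reshape(-1)


def gaussian_phantom(grid: Grid, centre, sigma, role="concentration") -> Phantom:
    """Gaussian bump phantom (product of per-axis Gaussians)."""
    centre = np.atleast_1d(centre)
    sigma = np.atleast_1d(sigma)
    vals = np.ones(grid.npts)
    for ax in range(grid.ndim):
        x = grid.coords(ax)
        g = np.exp(-((x - centre[ax]) ** 2) / (2 * sigma[ax] ** 2))
        shape = [1] * grid.ndim
        shape[ax] = -1
        vals = vals * g.reshape(shape)
    return Phantom(vals, role)


def boxcar_phantom(grid: Grid, lo, hi, role="concentration") -> Phantom:
    """Boxcar (top-hat) region phantom: 1 inside [lo, hi] per axis, else 0."""
    lo = np.atleast_1d(lo)
    hi = np.atleast_1d(hi)
    vals = np.ones(grid.npts)
    for ax in range(grid.ndim):
        x = grid.coords(ax)
        g = ((x >= lo[ax]) & (x <= hi[ax])).astype(float)
        shape = [1] * grid.ndim
        shape[ax] = -1
        vals = vals * g.reshape(shape)
    return Phantom(vals, role)


def save_phantom(phantom: Phantom, grid: Grid, path) -> None:
    """Write a 1-D/2-D phantom as delimited text with a JSON sidecar giving
    the grid extents (metres) and the phantom role."""
    import json
    import pathlib
    path = pathlib.Path(path)
    if phantom.values.ndim > 2:
        raise ValueError("text phantoms are supported in 1-D and 2-D only")
    np.savetxt(path, np.atleast_2d(phantom.values), delimiter=",")
    sidecar = {"extents_m": list(grid.extents), "npts": list(grid.npts),
               "role": phantom.role}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_phantom(path) -> tuple[Phantom, Grid]:
    """Read a phantom written by :func:`save_phantom`."""
    import json
    import pathlib
    path = pathlib.Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    values = np.loadtxt(path, delimiter=",")
    values = values.reshape(tuple(meta["npts"]))
    grid = Grid(tuple(meta["npts"]), tuple(meta["extents_m"]))
    return Phantom(values, meta["role"]), grid


@dataclass
class TransportSpec:
    """Diffusion coefficient/tensor/field and flow velocity.

    ``d`` may be a nonnegative scalar (m^2/s), a symmetric positive
    semidefinite 3x3 (or ndim x ndim) tensor, or a scalar field over the grid.
    ``v`` may be a constant vector (m/s) or a per-axis tuple of velocity
    fields over the grid.
    """

    d: object = 0.0
    v: object = None

    def validate(self, grid: Grid):
        d = np.asarray(self.d, dtype=float)
        if d.ndim == 0:
            if d < 0:
                raise ValueError("scalar diffusion coefficient must be nonnegative")
        elif d.ndim == 2:
            if d.shape[0] != d.shape[1] or d.shape[0] != grid.ndim:
                raise ValueError("diffusion tensor must be ndim x ndim")
            if not np.allclose(d, d.T):
                raise ValueError("diffusion tensor must be symmetric")
            if np.min(np.linalg.eigvalsh(d)) < -1e-15 * max(1.0, np.max(np.abs(d))):
                raise ValueError("diffusion tensor must be positive semidefinite")
        elif d.shape != tuple(grid.npts):
            raise ValueError("diffusion field shape must match the grid")


# ---------------------------------------------------------------------------
# Differentiation matrices
# ---------------------------------------------------------------------------

def _circulant(n: int, offsets_coeffs: dict[int, float]) -> sp.csr_matrix:
    rows, cols, vals = [], [], []
    i = np.arange(n)
    for off, c in offsets_coeffs.items():
        if c == 0.0:
            continue
        rows.append(i)
        cols.append((i + off) % n)
        vals.append(np.full(n, c))
    return sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )


def fd_first_derivative(npts: int, h: float, stencil: int = 3) -> sp.csr_matrix:
    """Central finite-difference d/dx on a periodic grid (rows sum to zero)."""
    if stencil not in _FD1:
        raise ValueError("stencil must be one of 3, 5, 7")
    if npts <= stencil:
        raise ValueError("need more grid points than the stencil width")
    coeffs = {}
    for k, c in enumerate(_FD1[stencil], start=1):
        coeffs[k] = c / h
        coeffs[-k] = -c / h
    return _circulant(npts, coeffs)


def fd_second_derivative(npts: int, h: float, stencil: int = 3) -> sp.csr_matrix:
    """Central finite-difference d^2/dx^2 on a periodic grid (symmetric,
    rows sum to zero, negative semidefinite)."""
    if stencil not in _FD2:
        raise ValueError("stencil must be one of 3, 5, 7")
    if npts <= stencil:
        raise ValueError("need more grid points than the stencil width")
    centre, halves = _FD2[stencil]
    coeffs = {0: centre / h**2}
    for k, c in enumerate(halves, start=1):
        coeffs[k] = c / h**2
        coeffs[-k] = c / h**2
    return _circulant(npts, coeffs)


def spectral_derivative(npts: int, L: float, order: int = 1) -> np.ndarray:
    """Dense Fourier spectral differentiation matrix on a periodic grid.

    Exact for every frequency resolvable below Nyquist.  For odd derivatives
    on even grids the (sign-ambiguous) Nyquist mode is zeroed, which keeps the
    matrix real and antisymmetric.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    k = 2.0 * np.pi * np.fft.fftfreq(npts, d=L / npts)
    if order == 1:
        sym = 1j * k
        if npts % 2 == 0:
            sym[npts // 2] = 0.0
    else:
        sym = -(k**2)
    F = np.fft.fft(np.eye(npts), axis=0)
    D = np.fft.ifft(sym[:, None] * F, axis=0)
    return np.real(D) if order in (1, 2) else D


# ---------------------------------------------------------------------------
# Transport generators (spatial-only polyadics)
# ---------------------------------------------------------------------------

def _axis_factors(grid: Grid, axis: int, op) -> list:
    """Wrap a one-axis operator into the grid's factor chain with identities."""
    facs = []
    for ax in range(grid.ndim):
        if ax == axis:
            facs.append(LinearFactor.from_matrix(op))
        else:
            facs.append(LinearFactor.identity(grid.npts[ax]))
    return facs


def _deriv(grid: Grid, axis: int, order: int, stencil) -> object:
    n = grid.npts[axis]
    h = grid.spacing[axis]
    if stencil == "spectral":
        return spectral_derivative(n, grid.extents[axis], order)
    if order == 1:
        return fd_first_derivative(n, h, stencil)
    return fd_second_derivative(n, h, stencil)


def _grad_polyadic(grid: Grid, axis: int, stencil) -> Polyadic:
    return Polyadic([(1.0, _axis_factors(grid, axis, _deriv(grid, axis, 1, stencil)))])


def diffusion_generator(grid: Grid, transport: TransportSpec,
                        stencil=3) -> Polyadic:
    """Fokker-Planck diffusion generator ``div(D grad c)`` as a polyadic.

    Constant isotropic ``D`` gives one ``D d^2/dx_a^2`` term per dimension
    (two identity factors each in 3D); a constant tensor gives up to
    ``ndim**2`` terms ``D_ab d/dx_a d/dx_b``; a spatially varying scalar field
    is discretised in the conservative divergence form ``d/dx_a D(r) d/dx_a``
    with the full-grid diagonal field sandwiched between first-derivative
    chains.  Total concentration is conserved exactly.
    """
    transport.validate(grid)
    d = np.asarray(transport.d, dtype=float)
    if d.ndim == 0:
        if float(d) == 0.0:
            return Polyadic.zeros(grid.nvox)
        terms = []
        for ax in range(grid.ndim):
            terms.append((float(d), _axis_factors(grid, ax, _deriv(grid, ax, 2, stencil))))
        return Polyadic(terms)
    if d.ndim == 2:
        terms = []
        for a in range(grid.ndim):
            for b in range(grid.ndim):
                if d[a, b] == 0.0:
                    continue
                if a == b:
                    terms.append((d[a, a], _axis_factors(grid, a, _deriv(grid, a, 2, stencil))))
                else:
                    facs = []
                    for ax in range(grid.ndim):
                        if ax in (a, b):
                            facs.append(LinearFactor.from_matrix(_deriv(grid, ax, 1, stencil)))
                        else:
                            facs.append(LinearFactor.identity(grid.npts[ax]))
                    terms.append((d[a, b], facs))
        if not terms:
            return Polyadic.zeros(grid.nvox)
        return Polyadic(terms)
    # spatially varying scalar field: sum_a  grad_a . diag(D) . grad_a
    diag_d = LinearFactor.diagonal(d.reshape(-1).astype(complex))
    parts = []
    for ax in range(grid.ndim):
        g = _grad_polyadic(grid, ax, stencil)
        parts.append(Polyadic([(1.0, [diag_d])], prefix=[g], suffix=[g]))
    gen = parts[0]
    for p in parts[1:]:
        gen = gen + p
    return gen


def flow_generator(grid: Grid, transport: TransportSpec, stencil=3) -> Polyadic:
    """Advection generator ``-div(v c)`` as a polyadic.

    Constant velocity gives ``-v_a d/dx_a`` per axis; velocity fields give the
    conservative form ``-d/dx_a diag(v_a)``.  Central stencils are used (no
    upwinding); a log note is emitted for strongly advective setups where the
    user may want a finer grid.
    """
    v = transport.v
    if v is None:
        return Polyadic.zeros(grid.nvox)
    terms = []
    parts = []
    v_arrs = [np.asarray(vi, dtype=float) for vi in np.atleast_1d(v)] \
        if not np.isscalar(v) else [np.asarray(v, dtype=float)]
    if len(v_arrs) != grid.ndim:
        raise ValueError("one velocity component per grid dimension is required")
    for ax, va in enumerate(v_arrs):
        if va.ndim == 0:
            if float(va) == 0.0:
                continue
            terms.append((-float(va), _axis_factors(grid, ax, _deriv(grid, ax, 1, stencil))))
        else:
            if va.shape != tuple(grid.npts):
                raise ValueError(f"velocity field shape mismatch on axis {ax}")
            g = _grad_polyadic(grid, ax, stencil)
            diag_v = LinearFactor.diagonal(va.reshape(-1).astype(complex))
            parts.append(Polyadic([(-1.0, [diag_v])], prefix=[g]))
    if not terms and not parts:
        return Polyadic.zeros(grid.nvox)
    gen = Polyadic(terms) if terms else None
    for p in parts:
        gen = p if gen is None else gen + p
    logger.debug("flow generator built with central stencils (no upwinding)")
    return gen


def gradient_zeeman_generator(grid: Grid, g, spin_superop,
                              axes: tuple[int, ...] | None = None) -> Polyadic:
    """Pulsed-field-gradient generator, ``-i sum_a g_a [diag(x_a) (x) Gz]``.

    ``g`` is the gradient amplitude per axis (T/m); ``spin_superop`` is the
    commutation superoperator of the shift-corrected Zeeman Hamiltonian per
    unit field, ``sum_n (1 + delta_n 1e-6) gamma_n Sz(n)`` (rad/s/T), already
    including any species block structure.  The generator vanishes at the grid
    centre where the coordinates are zero.
    """
    g = np.atleast_1d(np.asarray(g, dtype=float))
    if axes is None:
        axes = tuple(range(len(g)))
    sdim = spin_superop.shape[0]
    # Zeeman commutation superoperators are diagonal in the product basis;
    # store them as bare diagonals so their application is elementwise
    spin_factor = LinearFactor.from_matrix(spin_superop)
    m = sp.csr_matrix(spin_superop)
    if (m - sp.diags(m.diagonal())).nnz == 0:
        spin_factor = LinearFactor.diagonal(m.diagonal())
    terms = []
    for g_a, ax in zip(g, axes):
        if g_a == 0.0:
            continue
        facs = []
        for a in range(grid.ndim):
            if a == ax:
                facs.append(LinearFactor.diagonal(grid.coords(a).astype(complex)))
            else:
                facs.append(LinearFactor.identity(grid.npts[a]))
        facs.append(spin_factor)
        terms.append((-1j * g_a, facs))
    if not terms:
        return Polyadic.zeros(grid.nvox * sdim)
    return Polyadic(terms)


# ---------------------------------------------------------------------------
# Nyquist and finite-difference accuracy planning
# ---------------------------------------------------------------------------

def nyquist_max_frequency(gradient_events, system, mode: str = "cumulative") -> float:
    """Worst-case spatial frequency (rad/m) wound by a gradient record.

    ``gradient_events`` is an iterable of ``(amplitude_T_per_m, duration_s)``
    pairs along one axis.  Every gradient is assumed to keep defocusing some
    coherence, so the safe bound accumulates ``|g| dt`` over the whole record
    (``mode="cumulative"``); ``mode="single-event"`` uses the largest single
    event instead — the practical bound for well-refocused echo sequences,
    where the cumulative reading can be overly cautious.
    """
    if mode not in ("cumulative", "single-event"):
        raise ValueError("mode must be 'cumulative' or 'single-event'")
    areas = [abs(g) * dt for g, dt in gradient_events]
    if not areas:
        return 0.0
    area = sum(areas) if mode == "cumulative" else max(areas)
    if mode == "cumulative" and len(areas) > 1:
        logger.debug(
            "cumulative gradient winding bound in use; pass mode='single-event' "
            "for the practical echo-sequence bound"
        )
    gmax = 0.0
    for n in range(system.nspins):
        gmax = max(gmax, abs((1.0 + system.shifts_ppm[n] * 1e-6) * system.gamma(n)))
    return gmax * area


def min_grid_points(omega_max: float, L: float) -> int:
    """Smallest grid point count (multiple of 10) with ``omega_max * h < pi``."""
    if omega_max < 0 or L <= 0:
        raise ValueError("omega_max must be nonnegative and L positive")
    n_needed = math.floor(omega_max * L / math.pi) + 1
    return max(10, 10 * math.ceil(n_needed / 10))


def _fd1_symbol_error(omega_h: float, stencil: int) -> float:
    """Exact relative error of the FD first derivative on exp(-i Omega x)."""
    if omega_h == 0.0:
        return 0.0
    num = 0.0
    for k, c in enumerate(_FD1[stencil], start=1):
        num += 2.0 * c * math.sin(k * omega_h)
    return abs(1.0 - num / omega_h)


def fd_relative_error(omega_max: float, h: float, stencil: int = 3) -> float:
    """Worst-case relative error of the finite-difference first derivative
    acting on the tightest gradient spiral ``exp(-i Omega_max x)``.

    For the 3-point stencil this is ``1 - sin(Omega h)/(Omega h) ~
    (Omega h)^2 / 6``; wider stencils follow the analogous exact symbol
    expression, of order ``(Omega h)^(stencil - 1)``.
    """
    if stencil not in _FD1:
        raise ValueError("stencil must be one of 3, 5, 7")
    return _fd1_symbol_error(abs(omega_max) * h, stencil)


def fd_error_order(stencil: int) -> int:
    """Approximation order of the given central stencil."""
    return {3: 2, 5: 4, 7: 6}[stencil]


def nyquist_audit(grid: Grid, gradient_events_per_axis, system,
                  mode: str = "cumulative") -> list[dict]:
    """Check each grid axis against the Nyquist bound; returns audit records
    and logs a warning for every violated axis."""
    report = []
    for ax, events in enumerate(gradient_events_per_axis):
        omega = nyquist_max_frequency(events, system, mode=mode)
        n_min = min_grid_points(omega, grid.extents[ax])
        ok = grid.npts[ax] * math.pi > omega * grid.extents[ax]
        rec = {"axis": ax, "omega_max": omega, "n_min": n_min,
               "npts": grid.npts[ax], "ok": bool(ok)}
        if not ok:
            logger.warning(
                "axis %d: grid of %d points violates the spatial Nyquist "
                "condition (needs >= %d for Omega_max = %.3g rad/m)",
                ax, grid.npts[ax], n_min, omega,
            )
        report.append(rec)
    return report
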