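"""Assembly of the full space (x) species (x) spin evolution generator and
execution of event-list pulse sequences (delays, hard and soft pulses,
gradient events, acquisition).

The composite state vector is ordered ``[X][Y][Z][species][spin]`` with the
last factor varying fastest (inherited from the column-wise vec convention of
:mod:`spindrift.polyadic`).  The species/spin part is a concatenation of the
per-species Liouville spaces (dimension ``sum_s 4**N_s``), represented by
block sparse matrices; the spatial part is never opened — every term of the
evolution generator is a Kronecker chain of per-axis operators and one
species/spin block.

Sign conventions: generators are stored pre-multiplied by ``-i`` for coherent
parts (relaxation, transport and kinetics enter real), so propagation is
uniformly ``state <- exp(G dt) state``.  The spectrum frequency axis is in Hz
with zero at the transmitter; a spin with positive offset appears at positive
frequency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import liouville as lv
from .kinetics import ReactionNetwork, kinetics_generator
from .polyadic import LinearFactor, Polyadic, expmv, kron_apply, norm1_estimate
from .spatial import (Grid, Phantom, TransportSpec, diffusion_generator,
                      flow_generator, gradient_zeeman_generator, nyquist_audit,
                      spectral_derivative)

logger = logging.getLogger("spindrift")

__all__ = [
    "Problem", "Simulation", "spectrum",
    "Delay", "HardPulse", "SoftPulse", "GradientPulse", "Acquire",
    "run_events",
]


# ---------------------------------------------------------------------------
# Problem description
# ---------------------------------------------------------------------------

@dataclass
class Problem:
    """A spatially distributed spin dynamics problem.

    Parameters
    ----------
    network : the chemical species (possibly just one) with their spin systems
        and exchange rates.
    grid : periodic spatial grid, or ``None`` for a purely spectroscopic
        (single-voxel) problem.
    transport : diffusion/flow specification, or ``None``.
    concentrations : per-species concentration, each a scalar or a
        :class:`~spindrift.spatial.Phantom` over the grid.
    r1, r2 : per-species phenomenological relaxation rates (s^-1).
    transmitter_ppm : rotating-frame transmitter offset, in ppm.
    stencil : finite-difference stencil (3, 5, 7) or ``"spectral"``.
    coil_phantom : receptivity profile used in detection (uniform if None).
    b1_phantom : RF field profile over the grid (uniform if None, 1-D only).
    relaxation_phantoms : optional list of ``(Phantom, superop)`` pairs adding
        spatially weighted relaxation mechanisms, ``diag(Phi) (x) R_k``.
    """

    network: ReactionNetwork
    grid: Grid | None = None
    transport: TransportSpec | None = None
    concentrations: list | None = None
    r1: list | float = 0.0
    r2: list | float = 0.0
    transmitter_ppm: float = 0.0
    stencil: object = 7
    coil_phantom: Phantom | None = None
    b1_phantom: Phantom | None = None
    relaxation_phantoms: list | None = None

    def __post_init__(self):
        ns = self.network.nspecies
        if np.isscalar(self.r1):
            self.r1 = [float(self.r1)] * ns
        if np.isscalar(self.r2):
            self.r2 = [float(self.r2)] * ns
        if self.concentrations is None:
            self.concentrations = [1.0] * ns
        if len(self.concentrations) != ns:
            raise ValueError("one concentration (scalar or phantom) per species")
        for c in self.concentrations:
            if isinstance(c, Phantom) and self.grid is not None:
                c.check_grid(self.grid)

    # -- dimensions --------------------------------------------------------
    @property
    def nspace(self) -> int:
        return self.grid.nvox if self.grid is not None else 1

    @property
    def sdim(self) -> int:
        """Species (x) spin block dimension, sum of 4**N_s."""
        return self.network.total_dim

    @property
    def total_dim(self) -> int:
        return self.nspace * self.sdim

    @property
    def space_shape(self) -> tuple[int, ...]:
        return tuple(self.grid.npts) if self.grid is not None else ()

    # -- block (species x spin) operators -----------------------------------
    def _blockdiag(self, mats) -> sp.csr_matrix:
        return sp.block_diag([sp.csr_matrix(m) for m in mats], format="csr")

    def background_block(self) -> sp.csr_matrix:
        """Block-diagonal ``-iH_s + R_s`` plus the exchange generator."""
        blocks = []
        for s, system in enumerate(self.network.systems):
            H = lv.hamiltonian_isotropic(system, self.transmitter_ppm)
            L = -1j * H
            if self.r1[s] > 0 or self.r2[s] > 0:
                L = L + lv.relaxation_phenomenological(system, self.r1[s], self.r2[s])
            blocks.append(L)
        L = self._blockdiag(blocks)
        if self.network.has_exchange:
            K = kinetics_generator(self.network)
            L = L + sp.csr_matrix(K.to_dense())
        return L.tocsr()

    def gradient_block(self) -> sp.csr_matrix:
        """Commutation superoperator of the per-unit-field Zeeman Hamiltonian,
        ``sum_n (1 + delta_n 1e-6) gamma_n Sz(n)``, block per species."""
        blocks = []
        for system in self.network.systems:
            h = sp.csr_matrix((system.hilbert_dim,) * 2, dtype=complex)
            for n in range(system.nspins):
                w = (1.0 + system.shifts_ppm[n] * 1e-6) * system.gamma(n)
                h = h + w * lv.single_spin_operator(system, n, "z")
            blocks.append(lv.commutation_superoperator(h))
        return self._blockdiag(blocks)

    def rf_blocks(self, species: list[int] | None = None):
        """Commutation superoperators of the gamma-weighted total Sx and Sy."""
        cx, cy = [], []
        gmax = max(abs(s.gamma(n)) for s in self.network.systems
                   for n in range(s.nspins))
        for si, system in enumerate(self.network.systems):
            if species is not None and si not in species:
                z = sp.csr_matrix((system.liouville_dim,) * 2, dtype=complex)
                cx.append(z)
                cy.append(z)
                continue
            hx = sp.csr_matrix((system.hilbert_dim,) * 2, dtype=complex)
            hy = hx.copy()
            for n in range(system.nspins):
                w = system.gamma(n) / gmax
                hx = hx + w * lv.single_spin_operator(system, n, "x")
                hy = hy + w * lv.single_spin_operator(system, n, "y")
            cx.append(lv.commutation_superoperator(hx))
            cy.append(lv.commutation_superoperator(hy))
        return self._blockdiag(cx), self._blockdiag(cy)

    # -- states -------------------------------------------------------------
    def _conc_flat(self, s: int) -> np.ndarray:
        c = self.concentrations[s]
        if isinstance(c, Phantom):
            return c.flat
        return float(c) * np.ones(self.nspace)

    def initial_state(self, spec: str = "equilibrium") -> np.ndarray:
        """Composite initial state ``sum_s  Phi_s (x) rho_s``."""
        out = np.zeros(self.total_dim, dtype=complex)
        offset = 0
        for s, system in enumerate(self.network.systems):
            rho = lv.state(system, spec)
            block = np.zeros(self.sdim, dtype=complex)
            block[offset:offset + system.liouville_dim] = rho
            out += np.kron(self._conc_flat(s), block)
            offset += system.liouville_dim
        return out

    def detection_state(self, spec: str = "uniform-transverse") -> np.ndarray:
        """Detection functional ``Phi_coil (x) sigma`` (conjugate-dot contract)."""
        coil = (self.coil_phantom.flat if self.coil_phantom is not None
                else np.ones(self.nspace))
        out = np.zeros(self.total_dim, dtype=complex)
        offset = 0
        for system in self.network.systems:
            sig = lv.detection(system, spec)
            block = np.zeros(self.sdim, dtype=complex)
            block[offset:offset + system.liouville_dim] = sig
            out += np.kron(coil, block)
            offset += system.liouville_dim
        return out


def _space_identities(problem: Problem) -> list[LinearFactor]:
    if problem.grid is None:
        return []
    return [LinearFactor.identity(n) for n in problem.grid.npts]


def _extend_spatial(poly: Polyadic, sdim: int) -> Polyadic:
    """Append an identity species/spin factor to a spatial-only polyadic."""
    eye = LinearFactor.identity(sdim)
    if not poly.prefix and not poly.suffix:
        return Polyadic([(c, list(facs) + [eye]) for c, facs in poly.terms])
    return Polyadic([(1.0, [LinearFactor("polyadic", poly, poly.nrows, poly.ncols),
                            eye])])


def assemble_generator(problem: Problem, gradients=None, rf=None) -> Polyadic:
    """Assemble the full evolution generator as one polyadic.

    ``gradients`` is a per-axis amplitude vector in T/m (or ``None``);
    ``rf`` is ``(omega1_rad_s, phase_rad)`` for a spatially uniform (or
    ``b1_phantom``-weighted) transverse RF field, or ``None``.  Kronecker
    products are never opened: the result is a short sum of factor chains.
    """
    sp_ids = _space_identities(problem)
    bb = problem.background_block()
    if bb.nnz == 0:
        # empty coherent/relaxation physics: keep a zero term so the
        # generator has the right dimensions, at no application cost
        terms = [(0.0, sp_ids + [LinearFactor.from_matrix(bb)])]
    else:
        if problem.sdim <= 64:
            bb = bb.toarray()
        terms = [(1.0, sp_ids + [LinearFactor.from_matrix(bb)])]
    gen = Polyadic(terms)
    if problem.grid is not None and problem.transport is not None:
        diff = diffusion_generator(problem.grid, problem.transport, problem.stencil)
        gen = gen + _extend_spatial(diff, problem.sdim)
        if problem.transport.v is not None:
            gen = gen + _extend_spatial(
                flow_generator(problem.grid, problem.transport, problem.stencil),
                problem.sdim)
    if problem.relaxation_phantoms:
        for phantom, rk in problem.relaxation_phantoms:
            diag = LinearFactor.diagonal(phantom.flat.astype(complex))
            gen = gen + Polyadic([(1.0, [diag, sp.csr_matrix(rk)])])
    if gradients is not None and np.any(np.asarray(gradients) != 0.0):
        if problem.grid is None:
            raise ValueError("gradients require a spatial grid")
        gen = gen + gradient_zeeman_generator(
            problem.grid, gradients, problem.gradient_block())
    if rf is not None:
        omega1, phase = rf
        if omega1 != 0.0:
            cx, cy = problem.rf_blocks()
            crf = math.cos(phase) * cx + math.sin(phase) * cy
            if problem.b1_phantom is not None:
                b1 = LinearFactor.diagonal(problem.b1_phantom.flat.astype(complex))
                gen = gen + Polyadic([(-1j * omega1, [b1, crf])])
            else:
                gen = gen + Polyadic([(-1.0j * omega1, sp_ids + [crf])])
    return gen


# ---------------------------------------------------------------------------
# The simulation driver
# ---------------------------------------------------------------------------

class Simulation:
    """Stateful driver: holds the current composite state vector and elapsed
    time, and executes pulse-sequence events against a :class:`Problem`."""

    def __init__(self, problem: Problem, initial: str | np.ndarray = "equilibrium"):
        self.problem = problem
        if isinstance(initial, str):
            self.state = problem.initial_state(initial)
        else:
            self.state = np.asarray(initial, dtype=complex).copy()
        if self.state.shape[0] != problem.total_dim:
            raise ValueError("initial state length does not match the problem")
        self.time = 0.0
        self._background = None
        self._background_norm = None
        self._gradient_log: list[tuple[float, float]] = []

    # -- generator caches ---------------------------------------------------
    @property
    def background(self) -> Polyadic:
        if self._background is None:
            self._background = assemble_generator(self.problem)
            self._background_norm = norm1_estimate(self._background)
        return self._background

    def invalidate(self):
        self._background = None
        self._background_norm = None

    # -- events -------------------------------------------------------------
    def delay(self, dt: float):
        """Free evolution under the background generator."""
        if dt < 0:
            raise ValueError("delay must be nonnegative")
        if dt == 0:
            return self
        g = self.background
        self.state = expmv(g, self.state, dt, norm_est=self._background_norm)
        self.time += dt
        return self

    def hard_pulse(self, axis: str = "x", flip: float = math.pi / 2,
                   species: list[int] | None = None):
        """Ideal, spatially uniform rotation ``exp(-i flip Comm(S_axis))``.

        Applied through the small species/spin propagator only — the spatial
        part is an identity and is skipped.
        """
        phase = {"x": 0.0, "y": math.pi / 2, "-x": math.pi, "-y": -math.pi / 2}
        if axis not in phase:
            raise ValueError(f"unknown pulse axis {axis!r}")
        if flip == 0.0:
            return self
        cx, cy = self.problem.rf_blocks(species)
        crf = math.cos(phase[axis]) * cx + math.sin(phase[axis]) * cy
        u = spla.expm((-1j * flip) * crf.tocsc())
        facs = _space_identities(self.problem) + [LinearFactor.from_matrix(u.tocsr())]
        self.state = kron_apply(facs, self.state)
        return self

    def gradient_pulse(self, g, duration: float, rf=None):
        """Evolution with pulsed field gradients on (background included).

        ``g`` is the per-axis gradient amplitude in T/m; ``rf`` optionally
        adds a concurrent constant RF field ``(omega1, phase)``.  A spatial
        Nyquist audit of the accumulated gradient record runs first.
        """
        if duration <= 0:
            raise ValueError("gradient duration must be positive")
        g = np.atleast_1d(np.asarray(g, dtype=float))
        self._gradient_log.append((float(np.max(np.abs(g))), float(duration)))
        if self.problem.grid is not None:
            events = [[(gi, dt) for gi, dt in self._gradient_log]] * self.problem.grid.ndim
            nyquist_audit(self.problem.grid, events,
                          self.problem.network.systems[0], mode="single-event")
        gen = assemble_generator(self.problem, gradients=g, rf=rf)
        self.state = expmv(gen, self.state, duration)
        self.time += duration
        return self

    # -- soft pulses ---------------------------------------------------------
    def soft_pulse(self, envelope, offset_hz: float, duration: float,
                   phase: float = 0.0, method: str = "timeslice",
                   gradients=None, nphi: int = 32):
        """Shaped pulse at a carrier offset from the transmitter.

        ``envelope`` holds nutation-frequency samples omega1(t) in rad/s
        (piecewise constant).  Two equivalent treatments are available:

        * ``timeslice`` — the carrier phase ``2 pi offset t + phase`` is
          tracked explicitly and the RF Hamiltonian re-assembled per slice;
        * ``phase-coordinate`` — the RF phase is promoted to an extra periodic
          coordinate with a spectral ``-omega_rf d/dphi`` turning term, the
          state entering as a delta on the phase grid and being summed back
          afterwards.
        """
        envelope = np.asarray(envelope, dtype=float)
        if envelope.size < 2:
            raise ValueError("envelope must be sampled at 2 or more points")
        if duration <= 0:
            raise ValueError("soft pulse duration must be positive")
        if method == "timeslice":
            return self._soft_pulse_timeslice(envelope, offset_hz, duration,
                                              phase, gradients)
        if method == "phase-coordinate":
            return self._soft_pulse_phase_coord(envelope, offset_hz, duration,
                                                phase, gradients, nphi)
        raise ValueError(f"unknown soft pulse method {method!r}")

    def _soft_pulse_timeslice(self, envelope, offset_hz, duration, phase0,
                              gradients):
        nsl = envelope.size
        dt = duration / nsl
        w = 2 * math.pi * offset_hz
        # each envelope sample is subdivided so the carrier phase advances by
        # at most pi/8 per slice; the envelope itself stays piecewise constant
        nsub = max(1, math.ceil(abs(w) * dt / (math.pi / 8)))
        dts = dt / nsub
        t = 0.0
        for amp in envelope:
            for _ in range(nsub):
                ph = phase0 + w * (t + 0.5 * dts)
                gen = assemble_generator(self.problem, gradients=gradients,
                                         rf=(float(amp), ph))
                self.state = expmv(gen, self.state, dts)
                t += dts
            self.time += dt
        return self

    def _soft_pulse_phase_coord(self, envelope, offset_hz, duration, phase0,
                                gradients, nphi):
        prob = self.problem
        w = 2 * math.pi * offset_hz
        phi = phase0 + 2 * math.pi * np.arange(nphi) / nphi
        dphi = spectral_derivative(nphi, 2 * math.pi, order=1)
        cx, cy = prob.rf_blocks()
        sp_ids = _space_identities(prob)
        eye_spin = LinearFactor.identity(prob.sdim)
        eye_phi = LinearFactor.identity(nphi)

        base = assemble_generator(prob, gradients=gradients)
        terms = [(1.0, [eye_phi,
                        LinearFactor("polyadic", base, base.nrows, base.ncols)])]
        # RF phase turning: elements translate along phi at +omega_rf
        terms.append((-w, [LinearFactor.from_matrix(dphi)] + sp_ids + [eye_spin]))
        fixed = terms
        # state enters as a delta on the phase grid (slice 0 carries phase0)
        delta = np.zeros(nphi)
        delta[0] = 1.0
        aug = np.kron(delta, self.state).astype(complex)
        nsl = envelope.size
        dt = duration / nsl
        diag_cos = LinearFactor.diagonal(np.cos(phi).astype(complex))
        diag_sin = LinearFactor.diagonal(np.sin(phi).astype(complex))
        for amp in envelope:
            terms = list(fixed)
            if amp != 0.0:
                terms.append((-1j * float(amp),
                              [diag_cos] + sp_ids + [LinearFactor.from_matrix(cx)]))
                terms.append((-1j * float(amp),
                              [diag_sin] + sp_ids + [LinearFactor.from_matrix(cy)]))
            gen = Polyadic(terms)
            aug = expmv(gen, aug, dt)
            self.time += dt
        self.state = aug.reshape(nphi, -1).sum(axis=0)
        return self

    # -- acquisition ---------------------------------------------------------
    def acquire(self, npoints: int, dwell: float,
                detection: np.ndarray | None = None) -> np.ndarray:
        """Record the FID ``<sigma|rho(t0 + k dwell)>`` under the background
        generator."""
        if dwell <= 0:
            raise ValueError("dwell time must be positive")
        sigma = (self.problem.detection_state() if detection is None
                 else np.asarray(detection, dtype=complex))
        g = self.background
        fid = np.empty(npoints, dtype=complex)
        for k in range(npoints):
            if k > 0:
                self.state = expmv(g, self.state, dwell,
                                   norm_est=self._background_norm)
                self.time += dwell
            fid[k] = np.vdot(sigma, self.state)
        return fid

    def expectation(self, detection: np.ndarray) -> complex:
        return complex(np.vdot(detection, self.state))


def spectrum(fid: np.ndarray, dwell: float, apodization_hz: float = 0.0,
             magnitude: bool = False):
    """Fourier transform of an FID.

    Returns ``(freq_hz, spec)`` with the frequency axis in Hz, zero at the
    transmitter; a spin with positive offset from the transmitter appears at
    positive frequency.  ``apodization_hz`` applies exponential line
    broadening; ``magnitude`` returns the magnitude-mode spectrum.
    """
    fid = np.asarray(fid, dtype=complex)
    n = fid.size
    t = np.arange(n) * dwell
    apod = np.exp(-math.pi * apodization_hz * t)
    data = fid * apod
    data = data.copy()
    data[0] *= 0.5  # first-point scaling removes the baseline offset
    spec = np.fft.fftshift(np.fft.fft(data))
    freq = np.fft.fftshift(np.fft.fftfreq(n, d=dwell))
    # the detected S+ coherence evolves as exp(-i Omega t): mirror the axis so
    # that a positive offset from the transmitter appears at positive frequency
    freq, spec = -freq[::-1], spec[::-1]
    return freq, (np.abs(spec) if magnitude else spec)


# ---------------------------------------------------------------------------
# Declarative event lists
# ---------------------------------------------------------------------------

@dataclass
class Delay:
    duration: float


@dataclass
class HardPulse:
    axis: str = "x"
    flip: float = math.pi / 2
    species: list[int] | None = None


@dataclass
class SoftPulse:
    envelope: object
    offset_hz: float
    duration: float
    phase: float = 0.0
    method: str = "timeslice"
    gradients: object = None


@dataclass
class GradientPulse:
    g: object
    duration: float
    rf: object = None


@dataclass
class Acquire:
    npoints: int
    dwell: float


def run_events(problem: Problem, events: list,
               initial: str | np.ndarray = "equilibrium"):
    """Execute an ordered event list; returns ``(simulation, fids)``."""
    sim = Simulation(problem, initial)
    fids = []
    for ev in events:
        if isinstance(ev, Delay):
            sim.delay(ev.duration)
        elif isinstance(ev, HardPulse):
            sim.hard_pulse(ev.axis, ev.flip, ev.species)
        elif isinstance(ev, SoftPulse):
            sim.soft_pulse(ev.envelope, ev.offset_hz, ev.duration, ev.phase,
                           ev.method, ev.gradients)
        elif isinstance(ev, GradientPulse):
            sim.gradient_pulse(ev.g, ev.duration, ev.rf)
        elif isinstance(ev, Acquire):
            fids.append(sim.acquire(ev.npoints, ev.dwell))
        else:
            raise TypeError(f"unknown event {ev!r}")
    return sim, fids
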