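"""Spin systems and their Liouville-space superoperators.

Spin-1/2 systems are described by isotope labels, chemical shifts (ppm),
scalar couplings (Hz) and the magnet field (T).  Hilbert-space operators are
built as sparse Kronecker products of Pauli halves; Liouville-space
superoperators act on column-wise vectorised density matrices (dimension
``4**N``).  Simulations are performed in the rotating frame at a configurable
transmitter offset, with chemical shifts entering as frequency offsets
relative to it.

Sign conventions
----------------
The rotating-frame offset of spin ``n`` is

    omega_n = (delta_n - delta_ref) * 1e-6 * gamma_n * B0     [rad/s]

and coherent evolution is generated by ``-i H`` with ``H`` the commutation
superoperator of ``h = sum_n omega_n Sz(n) + 2 pi sum_{n<k} J_nk S(n).S(k)``.
Under this convention the ``S+`` coherence of a spin with positive offset
acquires phase ``exp(-i omega t)``, and a positive chemical shift (relative to
the transmitter) appears at a positive frequency of the spectrum axis
produced by :func:`spindrift.sequence.spectrum`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

__all__ = [
    "GAMMA",
    "SpinSystem",
    "single_spin_operator",
    "commutation_superoperator",
    "hamiltonian_isotropic",
    "relaxation_phenomenological",
    "state",
    "detection",
]

# magnetogyric ratios, rad s^-1 T^-1
GAMMA = {
    "1H": 2.6752218744e8,
    "19F": 2.518148e8,
    "31P": 1.08394e8,
    "13C": 6.728284e7,
    "29Si": -5.3190e7,
    "15N": -2.7126e7,
}

_HALF = 0.5
_SIGMA = {
    "x": np.array([[0.0, 1.0], [1.0, 0.0]], dtype=complex) * _HALF,
    "y": np.array([[0.0, -1.0j], [1.0j, 0.0]], dtype=complex) * _HALF,
    "z": np.array([[1.0, 0.0], [0.0, -1.0]], dtype=complex) * _HALF,
    "+": np.array([[0.0, 1.0], [0.0, 0.0]], dtype=complex),
    "-": np.array([[0.0, 0.0], [1.0, 0.0]], dtype=complex),
    "e": np.eye(2, dtype=complex),
}


@dataclass
class SpinSystem:
    """A liquid-state spin-1/2 system at a given magnet field.

    Parameters
    ----------
    isotopes : list of isotope labels, e.g. ``["1H", "1H"]``
    shifts_ppm : chemical shifts, one per spin
    j_hz : symmetric scalar-coupling matrix in Hz (zero diagonal)
    field_t : magnet induction B0 in tesla
    """

    isotopes: list[str]
    shifts_ppm: list[float]
    j_hz: np.ndarray | None = None
    field_t: float = 11.74

    def __post_init__(self):
        n = len(self.isotopes)
        if n < 1:
            raise ValueError("a spin system needs at least one spin")
        if len(self.shifts_ppm) != n:
            raise ValueError("one chemical shift per spin is required")
        for iso in self.isotopes:
            if iso not in GAMMA:
                raise ValueError(f"unknown isotope {iso!r}")
        if self.j_hz is None:
            self.j_hz = np.zeros((n, n))
        self.j_hz = np.asarray(self.j_hz, dtype=float)
        if self.j_hz.shape != (n, n):
            raise ValueError("J-coupling matrix shape must be (nspins, nspins)")
        if not np.allclose(self.j_hz, self.j_hz.T):
            raise ValueError("J-coupling matrix must be symmetric")
        if np.any(np.diag(self.j_hz) != 0):
            raise ValueError("self-couplings J_nn must be zero")

    @property
    def nspins(self) -> int:
        return len(self.isotopes)

    @property
    def hilbert_dim(self) -> int:
        return 2 ** self.nspins

    @property
    def liouville_dim(self) -> int:
        return 4 ** self.nspins

    def gamma(self, n: int) -> float:
        return GAMMA[self.isotopes[n]]

    def offset_rad(self, n: int, transmitter_ppm: float = 0.0) -> float:
        """Rotating-frame offset of spin ``n`` in rad/s."""
        return (self.shifts_ppm[n] - transmitter_ppm) * 1e-6 * self.gamma(n) * self.field_t

    @classmethod
    def from_dict(cls, cfg: dict) -> "SpinSystem":
        """Build from a config block: isotopes, shifts (ppm), J (Hz), B0 (T)."""
        return cls(
            isotopes=list(cfg["isotopes"]),
            shifts_ppm=list(cfg["shifts_ppm"]),
            j_hz=np.asarray(cfg.get("j_hz")) if cfg.get("j_hz") is not None else None,
            field_t=float(cfg.get("field_t", 11.74)),
        )


def single_spin_operator(system: SpinSystem, n: int, axis: str) -> sp.csr_matrix:
    """Hilbert-space operator ``I (x) ... (x) S_axis (x) ... (x) I`` at slot n.

    ``axis`` is one of ``x, y, z, +, -``; ``n`` is zero-based.
    """
    if not 0 <= n < system.nspins:
        raise ValueError(f"spin index {n} out of range for {system.nspins} spins")
    if axis not in ("x", "y", "z", "+", "-"):
        raise ValueError(f"unknown axis {axis!r}")
    op = sp.identity(1, dtype=complex, format="csr")
    for k in range(system.nspins):
        blk = _SIGMA[axis] if k == n else _SIGMA["e"]
        op = sp.kron(op, sp.csr_matrix(blk), format="csr")
    return op


def commutation_superoperator(h) -> sp.csr_matrix:
    """Superoperator of ``rho -> h rho - rho h`` on column-wise vec(rho)."""
    h = sp.csr_matrix(h)
    if h.shape[0] != h.shape[1]:
        raise ValueError("Hamiltonian must be square")
    n = h.shape[0]
    eye = sp.identity(n, dtype=complex, format="csr")
    return (sp.kron(eye, h) - sp.kron(h.T, eye)).tocsr()


def vec(rho: np.ndarray) -> np.ndarray:
    """Column-wise stretch of a density matrix into a state vector."""
    return np.asarray(rho, dtype=complex).flatten(order="F")


def unvec(v: np.ndarray) -> np.ndarray:
    n = int(round(np.sqrt(v.size)))
    return np.asarray(v, dtype=complex).reshape(n, n, order="F")


def hamiltonian_isotropic(system: SpinSystem, transmitter_ppm: float = 0.0,
                          frame_offset_hz: float = 0.0) -> sp.csr_matrix:
    """Rotating-frame Hamiltonian commutation superoperator.

    Zeeman offsets relative to the transmitter plus isotropic J couplings
    ``2 pi J_nk (SxSx + SySy + SzSz)`` over all pairs.  ``frame_offset_hz``
    shifts the transmitter by a plain frequency on top of ``transmitter_ppm``.
    """
    h = hamiltonian_hilbert(system, transmitter_ppm, frame_offset_hz)
    return commutation_superoperator(h)


def hamiltonian_hilbert(system: SpinSystem, transmitter_ppm: float = 0.0,
                        frame_offset_hz: float = 0.0) -> sp.csr_matrix:
    """Hilbert-space rotating-frame Hamiltonian (rad/s)."""
    n = system.nspins
    h = sp.csr_matrix((system.hilbert_dim, system.hilbert_dim), dtype=complex)
    for k in range(n):
        w = system.offset_rad(k, transmitter_ppm) - 2 * np.pi * frame_offset_hz
        if w != 0.0:
            h = h + w * single_spin_operator(system, k, "z")
    for a in range(n):
        for b in range(a + 1, n):
            j = system.j_hz[a, b]
            if j == 0.0:
                continue
            for ax in ("x", "y", "z"):
                h = h + 2 * np.pi * j * (
                    single_spin_operator(system, a, ax)
                    @ single_spin_operator(system, b, ax)
                )
    return h.tocsr()


def _equilibrium_rho(system: SpinSystem) -> np.ndarray:
    """High-temperature equilibrium density matrix in unit-polarisation units.

    The identity component is carried explicitly (unit trace) so that
    thermalised relaxation can drive recovery; spin polarisations are scaled
    to one, i.e. ``rho_eq = 2^-N (1 + sum_n 2 Sz(n))``.
    """
    dim = system.hilbert_dim
    rho = np.eye(dim, dtype=complex)
    for n in range(system.nspins):
        rho = rho + 2.0 * single_spin_operator(system, n, "z").toarray()
    return rho / dim


def relaxation_phenomenological(system: SpinSystem, r1: float, r2: float,
                                thermalized: bool = True) -> sp.csr_matrix:
    """Phenomenological (extended Bloch) relaxation superoperator.

    All coherences (off-diagonal density matrix elements in the Zeeman product
    basis) are damped at ``r2``; the diagonal (longitudinal) part is damped at
    ``r1`` toward thermal equilibrium.  The equilibrium drive is implemented
    as the rank-one term ``r1 |vec(rho_eq)><vec(1)|``, which keeps the
    equation of motion linear and homogeneous while conserving the trace.
    All eigenvalues have nonpositive real parts.
    """
    if r1 < 0 or r2 < 0:
        raise ValueError("relaxation rates must be nonnegative")
    dim = system.hilbert_dim
    ldim = system.liouville_dim
    if r1 == 0 and r2 == 0:
        return sp.csr_matrix((ldim, ldim), dtype=complex)
    # vec index (i + dim*j) <-> element rho_ij; off-diagonal i != j
    diag = np.full(ldim, -r2, dtype=complex)
    diag_idx = np.arange(dim) * (dim + 1)
    diag[diag_idx] = -r1
    R = sp.diags(diag).tolil()
    if thermalized and r1 > 0:
        rho_eq = _equilibrium_rho(system)
        v_eq = vec(rho_eq)
        v_tr = vec(np.eye(dim))  # <vec(1)| rho = Tr(rho)
        drive = r1 * sp.csr_matrix(np.outer(v_eq, v_tr.conj()))
        R = (R.tocsr() + drive).tolil()
    return R.tocsr()


def state(system: SpinSystem, spec: str, n: int | None = None) -> np.ndarray:
    """Vectorised spin state.

    ``spec`` is one of ``equilibrium``, ``Sz``, ``Sx``, ``Sy``, ``S+``,
    ``S-``; operator specs take an optional spin index ``n`` (all spins
    summed when omitted).
    """
    if spec == "equilibrium":
        return vec(_equilibrium_rho(system))
    axis = {"Sz": "z", "Sx": "x", "Sy": "y", "S+": "+", "S-": "-"}.get(spec)
    if axis is None:
        raise ValueError(f"unknown state spec {spec!r}")
    spins = range(system.nspins) if n is None else [n]
    op = sum(single_spin_operator(system, k, axis).toarray() for k in spins)
    return vec(op)


def detection(system: SpinSystem, spec: str = "uniform-transverse") -> np.ndarray:
    """Detection state, returned as a vector to be used as ``<sigma| rho> =
    sigma^H . rho`` (conjugate-transpose contract).

    ``uniform-transverse`` is the gamma-weighted ``S+`` sum over all spins,
    with weights ``(1 + delta_n 1e-6) gamma_n / gamma_max`` — the receptivity
    weighting of an ideal quadrature coil.
    """
    if spec != "uniform-transverse":
        return state(system, spec)
    gmax = max(abs(system.gamma(n)) for n in range(system.nspins))
    op = np.zeros((system.hilbert_dim,) * 2, dtype=complex)
    for n in range(system.nspins):
        w = (1.0 + system.shifts_ppm[n] * 1e-6) * system.gamma(n) / gmax
        op = op + w * single_spin_operator(system, n, "+").toarray()
    return vec(op)
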