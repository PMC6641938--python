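"""Matrix-free sums of Kronecker products and the linear algebra built on them.

The evolution generators of spatially distributed magnetic resonance problems
are short sums of Kronecker products of small operators (spatial derivative
matrices, exchange rate matrices, spin superoperators).  Opening those products
is never necessary: the action of ``A1 (x) A2 (x) ... (x) AN`` on a vector can
be computed one factor at a time at the cost of a few small matrix products.
This module provides

* :class:`LinearFactor` -- one operand of a Kronecker product (dense, sparse,
  identity-by-dimension-only, or a nested :class:`Polyadic`);
* :class:`Polyadic` -- a stored-but-unevaluated sum of Kronecker products with
  optional prefix/suffix multiplier chains;
* :func:`kron_apply` -- the Kronecker-times-vector primitive;
* :func:`norm1_estimate` -- Hager's 1-norm lower bound from matrix-vector
  products only;
* :func:`expmv` -- scaled-and-squared truncated-Taylor evaluation of
  ``exp(G*t) @ x`` without ever forming ``exp(G*t)``;
* :func:`taylor_terms` and :func:`optimal_squaring_skip` -- the step-count
  calculus behind the propagation routines.

Conventions
-----------
Column-wise vectorisation is used throughout: ``[A (x) B] vec(V) = vec(B V
A^T)``, which means the *last* Kronecker factor indexes the fastest-varying
component of the flat vector.  With NumPy's C-ordered ``reshape`` this makes
factor ``i`` act on axis ``i`` of the reshaped state.
"""

from __future__ import annotations

import json
import math
import numbers
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import gammaln

__all__ = [
    "LinearFactor",
    "Polyadic",
    "kron_apply",
    "poly_apply",
    "norm1_estimate",
    "taylor_terms",
    "expmv",
    "optimal_squaring_skip",
    "EPS_DOUBLE",
]

EPS_DOUBLE = 2.0 ** -52


class LinearFactor:
    """One operand of a Kronecker product.

    ``kind`` is one of ``"dense"``, ``"sparse"``, ``"diagonal"``,
    ``"identity"`` or ``"polyadic"``.  Identity factors store only their
    dimension, never elements; multiplication by them is skipped entirely.
    Diagonal factors store only the diagonal (coordinate operators, phantoms)
    and multiply elementwise.
    """

    __slots__ = ("kind", "payload", "nrows", "ncols")

    def __init__(self, kind: str, payload, nrows: int, ncols: int):
        if kind not in ("dense", "sparse", "diagonal", "identity", "polyadic"):
            raise ValueError(f"unknown factor kind: {kind!r}")
        if nrows < 1 or ncols < 1:
            raise ValueError("factor dimensions must be positive")
        if kind == "identity" and (payload is not None or nrows != ncols):
            raise ValueError("identity factors carry only a dimension")
        self.kind = kind
        self.payload = payload
        self.nrows = int(nrows)
        self.ncols = int(ncols)

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls, n: int) -> "LinearFactor":
        return cls("identity", None, n, n)

    @classmethod
    def diagonal(cls, d) -> "LinearFactor":
        d = np.asarray(d).reshape(-1)
        return cls("diagonal", d, d.size, d.size)

    @classmethod
    def from_matrix(cls, m) -> "LinearFactor":
        if isinstance(m, LinearFactor):
            return m
        if isinstance(m, Polyadic):
            return cls("polyadic", m, m.nrows, m.ncols)
        if sp.issparse(m):
            return cls("sparse", m.tocsr(), m.shape[0], m.shape[1])
        m = np.asarray(m)
        if m.ndim != 2:
            raise ValueError("a linear factor must be a 2-D operator")
        return cls("dense", m, m.shape[0], m.shape[1])

    # -- basic algebra -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Multiply into a (ncols, k) block of columns."""
        if self.kind == "identity":
            return x
        if self.kind == "diagonal":
            return self.payload[:, None] * x
        if self.kind == "polyadic":
            return self.payload.apply(x)
        return self.payload @ x

    @property
    def T(self) -> "LinearFactor":
        if self.kind in ("identity", "diagonal"):
            return self
        if self.kind == "polyadic":
            return LinearFactor("polyadic", self.payload.T, self.ncols, self.nrows)
        return LinearFactor.from_matrix(self.payload.T)

    def conj(self) -> "LinearFactor":
        if self.kind == "identity":
            return self
        if self.kind == "diagonal":
            return LinearFactor.diagonal(np.conj(self.payload))
        if self.kind == "polyadic":
            return LinearFactor("polyadic", self.payload.conj(), self.nrows, self.ncols)
        return LinearFactor.from_matrix(self.payload.conj())

    def to_dense(self) -> np.ndarray:
        if self.kind == "identity":
            return np.eye(self.nrows)
        if self.kind == "diagonal":
            return np.diag(self.payload)
        if self.kind == "polyadic":
            return self.payload.to_dense()
        if self.kind == "sparse":
            return self.payload.toarray()
        return np.asarray(self.payload)

    def describe(self) -> dict:
        return {"kind": self.kind, "shape": [self.nrows, self.ncols]}

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"LinearFactor({self.kind}, {self.nrows}x{self.ncols})"


def _as_factors(factors: Iterable) -> list[LinearFactor]:
    return [LinearFactor.from_matrix(f) for f in factors]


def kron_apply(factors: Sequence, x: np.ndarray) -> np.ndarray:
    """Compute ``[A1 (x) A2 (x) ... (x) AN] @ x`` without opening the product.

    ``x`` may be a flat vector or a (n, k) multicolumn block.  The state is
    reshaped into an N-dimensional array whose i-th axis matches the column
    dimension of the i-th factor (last factor fastest, i.e. column-wise vec);
    each non-identity factor is then contracted into its own axis.

    Raises ``ValueError`` naming the offending factor on dimension mismatch.
    """
    factors = _as_factors(factors)
    x = np.asarray(x)
    single = x.ndim == 1
    if single:
        x = x[:, None]
    ncols_total = math.prod(f.ncols for f in factors)
    if x.shape[0] != ncols_total:
        raise ValueError(
            f"vector length {x.shape[0]} does not match the product of factor "
            f"column dimensions {ncols_total}"
        )
    k = x.shape[1]
    dims = [f.ncols for f in factors]
    n_active = len(factors)
    X = x.reshape(dims + [k])
    for i, f in enumerate(factors):
        if f.kind == "identity":
            continue
        if X.shape[i] != f.ncols:
            raise ValueError(f"dimension mismatch at factor {i}")
        if f.kind == "diagonal":
            # elementwise along its own axis, no reordering at all
            shape = [1] * X.ndim
            shape[i] = f.nrows
            X = X * f.payload.reshape(shape)
            continue
        if i == 0:
            # first factor: already leftmost, no dimension reordering
            rest = X.shape[1:]
            Y = f.apply(X.reshape(f.ncols, -1))
            X = Y.reshape((f.nrows,) + rest)
        elif i == n_active - 1 and k == 1:
            # last factor: contract from the right, no dimension reordering
            lead = X.shape[:-2]
            Y = f.apply(X.reshape(-1, f.ncols).T).T
            X = Y.reshape(lead + (f.nrows, k))
        else:
            X = np.moveaxis(X, i, 0)
            head = X.shape[0]
            rest = X.shape[1:]
            Y = f.apply(np.ascontiguousarray(X.reshape(head, -1)))
            X = np.moveaxis(Y.reshape((f.nrows,) + rest), 0, i)
    out = X.reshape(-1, k)
    return out[:, 0] if single else out


class Polyadic:
    """A sum of Kronecker products, stored unopened.

    ``terms`` is a list of ``(coefficient, [factors])`` pairs; all terms must
    share row and column dimensions.  ``prefix`` and ``suffix`` are optional
    multiplier chains: the represented operator is::

        P1 @ ... @ PN @ ( sum_t  c_t * kron(*factors_t) ) @ Q1 @ ... @ QM

    and a product into a vector simply replays the stored sequence from right
    to left.  Factors may themselves be polyadics, so the object can buffer an
    arbitrary sequence of sums, products, and Kronecker products.
    """

    def __init__(self, terms, prefix=(), suffix=()):
        norm_terms = []
        for t in terms:
            if isinstance(t, (tuple, list)) and len(t) == 2 and isinstance(
                t[0], numbers.Number
            ):
                coeff, facs = t
            else:
                coeff, facs = 1.0, t
            norm_terms.append((complex(coeff), _as_factors(facs)))
        if not norm_terms:
            raise ValueError("a polyadic needs at least one term")
        r0 = math.prod(f.nrows for f in norm_terms[0][1])
        c0 = math.prod(f.ncols for f in norm_terms[0][1])
        for i, (_, facs) in enumerate(norm_terms):
            r = math.prod(f.nrows for f in facs)
            c = math.prod(f.ncols for f in facs)
            if (r, c) != (r0, c0):
                raise ValueError(
                    f"term {i} has dimension {(r, c)}, expected {(r0, c0)}"
                )
        self.terms = norm_terms
        self.prefix = _as_factors(prefix)
        self.suffix = _as_factors(suffix)
        # compose the dimension through the multiplier chains
        rows, cols = r0, c0
        for f in reversed(self.prefix):
            if f.ncols != rows:
                raise ValueError("prefix chain dimensions do not compose")
            rows = f.nrows
        for f in self.suffix:
            if f.nrows != cols:
                raise ValueError("suffix chain dimensions do not compose")
            cols = f.ncols
        self.nrows, self.ncols = rows, cols

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_kron(cls, *factors, coeff=1.0) -> "Polyadic":
        return cls([(coeff, list(factors))])

    @classmethod
    def zeros(cls, nrows: int, ncols: int | None = None) -> "Polyadic":
        ncols = nrows if ncols is None else ncols
        z = sp.csr_matrix((nrows, ncols), dtype=complex)
        return cls([(0.0, [z])])

    # -- properties --------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def is_square(self) -> bool:
        return self.nrows == self.ncols

    # -- application -------------------------------------------------------
    def apply(self, x: np.ndarray) -> np.ndarray:
        """Multiply this operator into a vector or multicolumn block."""
        x = np.asarray(x)
        single = x.ndim == 1
        if single:
            x = x[:, None]
        if x.shape[0] != self.ncols:
            raise ValueError(
                f"vector length {x.shape[0]} does not conform to operator "
                f"column dimension {self.ncols}"
            )
        for f in reversed(self.suffix):
            x = f.apply(x)
        acc = None
        for coeff, facs in self.terms:
            if coeff == 0:
                continue
            y = coeff * kron_apply(facs, x)
            acc = y if acc is None else acc + y
        if acc is None:
            acc = np.zeros((math.prod(f.nrows for f in self.terms[0][1]), x.shape[1]),
                           dtype=complex)
        for f in reversed(self.prefix):
            acc = f.apply(acc)
        return acc[:, 0] if single else acc

    def __matmul__(self, x):
        if isinstance(x, (np.ndarray,)):
            return self.apply(x)
        return NotImplemented

    # -- algebra -----------------------------------------------------------
    def transpose(self) -> "Polyadic":
        """Transpose: factors transposed in place, prefix/suffix swapped."""
        terms = [(c, [f.T for f in facs]) for c, facs in self.terms]
        prefix = [f.T for f in reversed(self.suffix)]
        suffix = [f.T for f in reversed(self.prefix)]
        return Polyadic(terms, prefix=prefix, suffix=suffix)

    @property
    def T(self) -> "Polyadic":
        return self.transpose()

    def conj(self) -> "Polyadic":
        terms = [(np.conj(c), [f.conj() for f in facs]) for c, facs in self.terms]
        return Polyadic(terms, prefix=[f.conj() for f in self.prefix],
                        suffix=[f.conj() for f in self.suffix])

    def __add__(self, other: "Polyadic") -> "Polyadic":
        """Buffered addition: the terms are simply stored, never evaluated."""
        if not isinstance(other, Polyadic):
            return NotImplemented
        if self.shape != other.shape:
            raise ValueError("cannot add polyadics of different shapes")
        a = self._flattened()
        b = other._flattened()
        return Polyadic(a.terms + b.terms)

    def _flattened(self) -> "Polyadic":
        """Absorb prefix/suffix chains by nesting, so terms can be merged."""
        if not self.prefix and not self.suffix:
            return self
        return Polyadic([(1.0, [LinearFactor("polyadic", self, self.nrows, self.ncols)])])

    def __mul__(self, scalar) -> "Polyadic":
        if not isinstance(scalar, numbers.Number):
            return NotImplemented
        if not self.prefix and not self.suffix:
            return Polyadic([(scalar * c, facs) for c, facs in self.terms])
        return Polyadic(
            [(scalar, [LinearFactor("polyadic", self, self.nrows, self.ncols)])]
        )

    __rmul__ = __mul__

    def __neg__(self) -> "Polyadic":
        return self * (-1.0)

    # -- dense materialisation (tests and small problems only) -------------
    def to_dense(self) -> np.ndarray:
        """Open all Kronecker products; for oracle tests on small operators."""
        inner = (math.prod(f.nrows for f in self.terms[0][1]),
                 math.prod(f.ncols for f in self.terms[0][1]))
        acc = np.zeros(inner, dtype=complex)
        for coeff, facs in self.terms:
            m = np.array([[1.0 + 0j]])
            for f in facs:
                m = np.kron(m, f.to_dense())
            acc = acc + coeff * m
        for f in reversed(self.prefix):
            acc = f.to_dense() @ acc
        for f in self.suffix:
            acc = acc @ f.to_dense()
        return acc

    # -- introspection ------------------------------------------------------
    def describe(self) -> dict:
        """JSON-serialisable dump of the term/dimension structure."""
        return {
            "shape": [self.nrows, self.ncols],
            "n_terms": len(self.terms),
            "prefix": [f.describe() for f in self.prefix],
            "suffix": [f.describe() for f in self.suffix],
            "terms": [
                {
                    "coeff": [t[0].real, t[0].imag],
                    "factors": [f.describe() for f in t[1]],
                }
                for t in self.terms
            ],
        }

    def describe_json(self) -> str:
        return json.dumps(self.describe())

    def max_factor_dimension(self) -> int:
        """Largest single-factor dimension ever materialised by this operator."""
        dims = [0]
        for _, facs in self.terms:
            for f in facs:
                if f.kind == "polyadic":
                    dims.append(f.payload.max_factor_dimension())
                elif f.kind != "identity":
                    dims.append(max(f.nrows, f.ncols))
        for f in self.prefix + self.suffix:
            if f.kind == "polyadic":
                dims.append(f.payload.max_factor_dimension())
            elif f.kind != "identity":
                dims.append(max(f.nrows, f.ncols))
        return max(dims)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Polyadic({self.nrows}x{self.ncols}, {len(self.terms)} terms)"


def poly_apply(P: Polyadic, x: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`Polyadic.apply`."""
    return P.apply(x)


def aspolyadic(op) -> Polyadic:
    """Wrap a plain matrix (dense or sparse) as a single-term polyadic."""
    if isinstance(op, Polyadic):
        return op
    return Polyadic.from_kron(op)


# ---------------------------------------------------------------------------
# 1-norm estimation (Hager's algorithm on matrix-vector products only)
# ---------------------------------------------------------------------------

def norm1_estimate(P, max_iter: int = 5) -> float:
    """Hager's lower-bound estimate of the matrix 1-norm.

    Uses only products with ``P`` and its (conjugate) transpose, obtained via
    :meth:`Polyadic.transpose`, so the operator is never opened.  The returned
    value is ``||P x||_1`` for some ``||x||_1 = 1`` and therefore never exceeds
    the exact 1-norm; for diagonal and for elementwise-nonnegative operators
    the estimate is exact.  One starting vector (the normalised all-ones
    column) and at most ``max_iter`` forward/transpose sweeps are used.
    """
    P = aspolyadic(P)
    if not P.is_square:
        raise ValueError("1-norm estimation requires a square operator")
    n = P.ncols
    Pt = P.transpose()

    def adjoint_apply(v):
        # P^H v = conj(P^T conj(v)); implemented through the stored transpose
        return np.conj(Pt.apply(np.conj(v)))

    x = np.ones(n, dtype=complex) / n
    est = 0.0
    for _ in range(max_iter):
        y = P.apply(x)
        est_new = float(np.sum(np.abs(y)))
        est = max(est, est_new)
        absy = np.abs(y)
        xi = np.where(absy > 0, y / np.where(absy > 0, absy, 1.0), 1.0)
        z = adjoint_apply(xi)
        j = int(np.argmax(np.abs(z)))
        if np.abs(z[j]) <= np.real(np.vdot(z, x)) + 1e-14 * np.abs(z[j]):
            break
        x = np.zeros(n, dtype=complex)
        x[j] = 1.0
    return est


# ---------------------------------------------------------------------------
# Taylor truncation order and the propagation routine
# ---------------------------------------------------------------------------

def taylor_terms(eps: float = EPS_DOUBLE) -> int:
    """Truncation order of the scaled Taylor series, ``ceil(Gamma^-1(1/eps) - 1)``.

    For a generator scaled to spectral radius <= 1 the magnitude of the j-th
    Taylor term is bounded by 1/j!, so the series may be cut at the order where
    1/j! drops below machine precision.  Inverting the gamma function on its
    increasing branch gives 18 terms for double precision.
    """
    if not (0.0 < eps < 1.0):
        raise ValueError("eps must lie strictly between 0 and 1")
    target = -math.log(eps)  # solve gammaln(x) = log(1/eps), x >= 2
    lo, hi = 2.0, 2.0
    while gammaln(hi) < target:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if gammaln(mid) < target:
            lo = mid
        else:
            hi = mid
    return max(1, math.ceil(hi - 1.0))


def expmv(G, x: np.ndarray, T: float, eps: float = EPS_DOUBLE,
          norm_est: float | None = None) -> np.ndarray:
    """Evaluate ``exp(G*T) @ x`` by scaled truncated-Taylor substepping.

    ``G`` is the already-signed generator (any ``-i`` factors are folded in by
    the caller).  The interval is split into ``2^n`` substeps with ``n =
    ceil(log2(T * ||G||_1))`` (clamped at zero) so that the scaled generator
    has 1-norm at most one; each substep runs the truncated Taylor series of
    :func:`taylor_terms` order with an early exit once the running term is
    negligible against the accumulated sum.

    ``norm_est`` lets the caller reuse a previously computed 1-norm estimate.
    """
    G = aspolyadic(G)
    if not G.is_square:
        raise ValueError("expmv requires a square generator")
    x = np.asarray(x, dtype=complex)
    if x.shape[0] != G.ncols:
        raise ValueError("state length does not match generator dimension")
    if T < 0:
        raise ValueError("propagation duration must be nonnegative")
    if T == 0:
        return x.copy()
    if norm_est is None:
        norm_est = norm1_estimate(G)
    scale = T * norm_est
    n = max(0, math.ceil(math.log2(scale))) if scale > 0 else 0
    nsteps = 2 ** n
    dt = T / nsteps
    jmax = taylor_terms(eps)
    y = x.copy()
    for _ in range(nsteps):
        acc = y.copy()
        term = y
        for j in range(1, jmax + 1):
            term = (dt / j) * G.apply(term)
            acc += term
            if np.max(np.abs(term)) <= eps * max(np.max(np.abs(acc)), 1e-300):
                break
        y = acc
    return y


def optimal_squaring_skip(N: int, k: int = 1, alpha_minus_beta: float = 1.0) -> int:
    """Optimal number of propagator squarings to replace by propagator-vector
    products, ``max(0, ceil(log2(N^(alpha-beta) / (k ln 2))))``.

    ``N`` is the matrix dimension, ``k`` the number of state columns being
    propagated, and ``alpha - beta`` the gap between the cost exponents of
    matrix-matrix and matrix-vector products (about 1 for sparse operators).
    Relevant only when an explicit (openable) matrix representation is used.
    """
    if N < 1 or k < 1:
        raise ValueError("N and k must be positive integers")
    val = (N ** alpha_minus_beta) / (k * math.log(2.0))
    if val <= 1.0:
        return max(0, math.ceil(math.log2(val))) if val > 0 else 0
    return max(0, math.ceil(math.log2(val)))
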