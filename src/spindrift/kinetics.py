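"""First-order chemical exchange generators in block (species x spin) form.

A reaction network is a set of chemical species, each carrying its own spin
system, connected by first-order rate constants ``k_ij`` (s^-1) for the
process i -> j.  The state vector concatenates the spin states of all
species; coherent evolution is block-diagonal, and exchange couples the
blocks through the rate-matrix generator ``K`` Kroneckered with the spin-space
identity.  Only magnetisation-conserving exchange is supported: species must
share the same Liouville dimension and spin states map one-to-one (identity
mapping), so the generator columns sum to zero and the total spin-state
amplitude is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .liouville import SpinSystem
from .polyadic import LinearFactor, Polyadic

__all__ = ["ReactionNetwork", "exchange_rate_matrix", "kinetics_generator",
           "concatenate_species"]


@dataclass
class ReactionNetwork:
    """Labelled species, each with its own spin system, plus first-order
    exchange rates ``rates[i, j] = k_{i->j}`` in s^-1 (zero diagonal)."""

    names: list[str]
    systems: list[SpinSystem]
    rates: np.ndarray | None = None

    def __post_init__(self):
        ns = len(self.names)
        if len(self.systems) != ns:
            raise ValueError("one spin system per species is required")
        if self.rates is None:
            self.rates = np.zeros((ns, ns))
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (ns, ns):
            raise ValueError("rate matrix shape must be (nspecies, nspecies)")
        off = self.rates[~np.eye(ns, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("exchange rates must be nonnegative")

    @property
    def nspecies(self) -> int:
        return len(self.names)

    @property
    def liouville_dims(self) -> list[int]:
        return [s.liouville_dim for s in self.systems]

    @property
    def total_dim(self) -> int:
        """Concatenated species (x) spin dimension, sum of 4**N_s."""
        return sum(self.liouville_dims)

    @property
    def has_exchange(self) -> bool:
        return bool(np.any(self.rates != 0))


def exchange_rate_matrix(rates: np.ndarray) -> np.ndarray:
    """Population-space exchange generator from the rate table.

    ``K[i, j] = k_{j->i}`` for i != j and ``K[j, j] = -sum_i k_{j->i}``;
    columns sum to zero, so total population is conserved."""
    rates = np.asarray(rates, dtype=float)
    ns = rates.shape[0]
    off = rates[~np.eye(ns, dtype=bool)]
    if np.any(off < 0):
        raise ValueError("exchange rates must be nonnegative")
    K = rates.T.copy()
    np.fill_diagonal(K, 0.0)
    K -= np.diag(np.sum(rates - np.diag(np.diag(rates)), axis=1))
    return K


def kinetics_generator(network: ReactionNetwork) -> Polyadic:
    """Exchange generator ``K (x) I_spin`` over the concatenated state.

    Requires all species to share the same Liouville dimension (identity
    spin-state mapping between species).
    """
    dims = network.liouville_dims
    if len(set(dims)) != 1:
        raise ValueError(
            "exchange requires all species to share the same Liouville "
            "dimension (identity spin-state mapping)"
        )
    K = exchange_rate_matrix(network.rates)
    return Polyadic([(1.0, [sp.csr_matrix(K.astype(complex)),
                            LinearFactor.identity(dims[0])])])


def concatenate_species(generators: list, kinetics: Polyadic | None = None) -> Polyadic:
    """Diagonal concatenation of per-species evolution generators, plus the
    exchange coupling, all as one polyadic over species (x) spin.

    ``generators`` is one square generator per species (sparse matrix, dense
    matrix, or polyadic), all sharing the same dimension; the block-diagonal
    part is stored as ``E_ss (x) L_s`` with ``E_ss`` the single-entry species
    selector.  ``kinetics`` (from :func:`kinetics_generator`) is added as-is.
    """
    ns = len(generators)
    if ns == 0:
        raise ValueError("at least one species generator is required")
    gens = [g if isinstance(g, Polyadic) else Polyadic.from_kron(g)
            for g in generators]
    dim = gens[0].nrows
    for i, g in enumerate(gens):
        if g.shape != (dim, dim):
            raise ValueError(f"species generator {i} has mismatched dimension")
    if ns == 1:
        out = gens[0]
    else:
        terms = []
        for s, g in enumerate(gens):
            e = sp.csr_matrix(([1.0 + 0j], ([s], [s])), shape=(ns, ns))
            terms.append((1.0, [LinearFactor.from_matrix(e),
                                LinearFactor("polyadic", g, dim, dim)]))
        out = Polyadic(terms)
    if kinetics is not None:
        if kinetics.shape != out.shape:
            raise ValueError("kinetics generator dimension mismatch")
        out = out + kinetics
    return out
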