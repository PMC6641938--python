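"""Ready-made sample definitions used by the worked examples and the tests.

These presets encode the standard benchmark scenarios of spatially
distributed NMR simulation: a water-like single-proton sample for pulsed
field gradient diffusion experiments, a trio of weakly coupled two-spin
systems laid out in three regions of a 1-D sample for localised
spectroscopy, and a solvent + solute pair for excitation-sculpting solvent
suppression.
"""

from __future__ import annotations

import numpy as np

from .kinetics import ReactionNetwork
from .liouville import SpinSystem
from .spatial import Grid, boxcar_phantom

__all__ = [
    "water_like_system",
    "single_proton_sample",
    "two_spin_systems_abc",
    "three_region_sample",
    "solvent_solute_network",
    "gaussian_envelope",
]


def water_like_system(shift_ppm: float = 4.6, field_t: float = 11.74) -> SpinSystem:
    """Single proton at the water chemical shift (4.6 ppm at 11.74 T)."""
    return SpinSystem(["1H"], [shift_ppm], field_t=field_t)


def single_proton_sample(npts: int = 1000, length_m: float = 0.015,
                         shift_ppm: float = 4.6, field_t: float = 11.74):
    """1.5 cm single-proton sample on a 1-D periodic grid.

    Returns ``(network, grid)``; the concentration is uniform (the sample
    fills the grid, which is legitimate for periodic pulsed-gradient echoes
    because the phase spirals wrap consistently)."""
    network = ReactionNetwork(["water"], [water_like_system(shift_ppm, field_t)])
    grid = Grid((npts,), (length_m,))
    return network, grid


def two_spin_systems_abc(field_t: float = 11.74) -> list[SpinSystem]:
    """The three weakly coupled two-spin systems used in the localisation
    examples: A (+/-1 ppm, J = 30 Hz), B (+/-3 ppm, J = 10 Hz),
    C (+/-2 ppm, J = 20 Hz)."""
    systems = []
    for d, j in ((1.0, 30.0), (3.0, 10.0), (2.0, 20.0)):
        systems.append(SpinSystem(["1H", "1H"], [d, -d],
                                  j_hz=np.array([[0.0, j], [j, 0.0]]),
                                  field_t=field_t))
    return systems


def three_region_sample(npts: int = 300, length_m: float = 0.015,
                        field_t: float = 11.74):
    """Three spin systems concentrated in three adjacent regions of a 1-D
    sample, with white space at the edges to keep the periodic boundary from
    folding transport over.

    Returns ``(network, grid, phantoms)`` where ``phantoms[k]`` is the
    concentration profile of system k (A left, B centre, C right)."""
    grid = Grid((npts,), (length_m,))
    systems = two_spin_systems_abc(field_t)
    network = ReactionNetwork(["A", "B", "C"], systems)
    L = length_m
    edges = [(-0.40 * L, -0.15 * L), (-0.10 * L, 0.10 * L), (0.15 * L, 0.40 * L)]
    phantoms = [boxcar_phantom(grid, lo, hi) for lo, hi in edges]
    return network, grid, phantoms


def solvent_solute_network(field_t: float = 11.74,
                           solvent_ppm: float = 4.6,
                           solute_ppm: tuple = (1.0, 3.0),
                           solute_j: float = 7.0) -> ReactionNetwork:
    """Solvent (single abundant proton) plus a J-coupled two-spin solute,
    the standard setting for excitation-sculpting suppression tests.

    Species 0 is the solvent; species 1 the solute."""
    solvent = SpinSystem(["1H"], [solvent_ppm], field_t=field_t)
    j = np.array([[0.0, solute_j], [solute_j, 0.0]])
    solute = SpinSystem(["1H", "1H"], list(solute_ppm), j_hz=j, field_t=field_t)
    return ReactionNetwork(["solvent", "solute"], [solvent, solute])


def gaussian_envelope(npoints: int = 10, truncation: float = 0.02) -> np.ndarray:
    """Unit-peak Gaussian envelope samples truncated at the given fraction."""
    sigma = 1.0 / np.sqrt(-2.0 * np.log(truncation))
    t = np.linspace(-1.0, 1.0, npoints)
    return np.exp(-(t**2) / (2 * sigma**2))
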