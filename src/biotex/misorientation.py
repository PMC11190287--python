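"""Uncorrelated misorientation distributions and the M-index.

The M-index measures fabric strength as half the integrated absolute
difference between the observed uncorrelated misorientation-angle
distribution and the theoretical random (Mackenzie-type) distribution for
the crystal symmetry: 0 for a random fabric, approaching 1 for a single
crystal.  The random reference is estimated once per symmetry by seeded
Monte Carlo (one implementation path for any symmetry group) and cached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .orientation import (
    CrystalSymmetry,
    Orientation,
    misorientation_angle,
    random_uniform_orientations,
)

__all__ = [
    "MisorientationHistogram",
    "uncorrelated_misorientation_hist",
    "mackenzie_reference",
    "m_index",
]


@dataclass
class MisorientationHistogram:
    """Binned misorientation-angle distribution (probability mass per bin)."""

    bin_edges: np.ndarray   # degrees, uniform width, covering [0, 180]
    density: np.ndarray     # per-bin probability mass, sums to 1
    n_pairs: int
    kind: str               # "observed-uncorrelated" | "theoretical-random"

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def mass_beyond(self, angle_deg: float) -> float:
        """Total probability mass in bins entirely above ``angle_deg``."""
        return float(self.density[self.bin_edges[:-1] >= angle_deg].sum())


def _hist(angles: np.ndarray, bin_width: float, n_pairs: int,
          kind: str) -> MisorientationHistogram:
    edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    counts, _ = np.histogram(angles, bins=edges)
    return MisorientationHistogram(
        bin_edges=edges,
        density=counts / counts.sum(),
        n_pairs=n_pairs,
        kind=kind,
    )


def uncorrelated_misorientation_hist(
    orientations: Orientation,
    sym: CrystalSymmetry,
    n_pairs: int = 10**5,
    seed: int = 0,
    bin_width: float = 1.0,
) -> MisorientationHistogram:
    """Histogram of misorientation angles between random distinct pairs.

    Pairs are drawn from individual measurement points (pixels), not
    reconstructed grains, and the pair count is capped for tractability.
    """
    n = len(orientations)
    if n < 2:
        raise ValueError("need at least 2 orientations for pair statistics")
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n, size=n_pairs)
    j = rng.integers(0, n - 1, size=n_pairs)
    j = np.where(j >= i, j + 1, j)  # distinct indices, uniform over pairs
    ang = misorientation_angle(orientations[i], orientations[j], sym)
    return _hist(np.atleast_1d(ang), bin_width, n_pairs,
                 "observed-uncorrelated")


_REF_CACHE: dict = {}


def mackenzie_reference(sym: CrystalSymmetry, bin_width: float = 1.0,
                        n_mc: int = 10**6, seed: int = 0
                        ) -> MisorientationHistogram:
    """Random-pair misorientation density for the symmetry (Monte Carlo).

    The misorientation-angle distribution of two independent Haar-uniform
    orientations under the crystal symmetry; for the hexagonal Laue class
    its support ends near 93.8 degrees.  Cached per argument set.
    """
    key = (sym.name, sym.order, bin_width, n_mc, seed)
    if key not in _REF_CACHE:
        o1 = random_uniform_orientations(n_mc, seed)
        o2 = random_uniform_orientations(n_mc, seed + 1)
        ang = misorientation_angle(o1, o2, sym)
        _REF_CACHE[key] = _hist(np.atleast_1d(ang), bin_width, n_mc,
                                "theoretical-random")
    return _REF_CACHE[key]


def m_index(observed: MisorientationHistogram,
            reference: MisorientationHistogram) -> float:
    """M = 1/2 * sum over bins of |reference - observed| (in [0, 1])."""
    if (observed.bin_edges.shape != reference.bin_edges.shape
            or not np.allclose(observed.bin_edges, reference.bin_edges)):
        raise ValueError("histograms must share identical binning")
    return float(0.5 * np.abs(reference.density - observed.density).sum())
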