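"""Kernel-density orientation distribution functions and texture indices.

The ODF is a de la Vallee Poussin kernel density on SO(3),

    f(g) = sum_i w_i * (1/|G|) * sum_{s in G} psi_kappa(omega(g, g_i s)),

with psi_kappa(omega) = C(kappa) * cos^{2 kappa}(omega / 2) normalized to unit
mass under the normalized Haar measure, and the crystal point group G applied
by right multiplication.  ``kappa`` is set so the kernel falls to half its
peak at the requested halfwidth (half width at half maximum in misorientation
angle, the convention of the texture-analysis literature).

The Texture Index is TI = integral of f(g)^2 dg; it equals 1 for the uniform
distribution and grows with preferred orientation.  Pole figures are the
analogous spherical kernel densities of a crystal-direction family in the
specimen frame, normalized to multiples of uniform density (MUD); pfJ is the
integral of MUD^2 over the sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import betaln

from .orientation import (
    CrystalSymmetry,
    MillerDirectionFamily,
    Orientation,
    qcanonical,
    qmul,
)

__all__ = [
    "ODFModel",
    "PoleDensity",
    "TextureSummary",
    "kappa_from_halfwidth",
    "kernel_constant",
    "build_odf",
    "texture_index",
    "pole_density",
    "pfj",
    "summarize_texture",
]


# ---------------------------------------------------------------------------
# kernel parameters
# ---------------------------------------------------------------------------

def kappa_from_halfwidth(halfwidth_deg: float) -> float:
    """Shape parameter solving cos^{2 kappa}(hw / 2) = 1/2.

    ``halfwidth_deg`` is the half width at half maximum of the kernel as a
    function of (mis)orientation angle.
    """
    if not 0.0 < halfwidth_deg < 90.0:
        raise ValueError("halfwidth must lie in (0, 90) degrees")
    h = np.radians(halfwidth_deg) / 2.0
    return float(np.log(0.5) / (2.0 * np.log(np.cos(h))))


def kernel_constant(kappa: float) -> float:
    """C(kappa) normalizing psi over SO(3): pi / (2 B(kappa + 1/2, 3/2))."""
    return float(np.pi / 2.0 * np.exp(-betaln(kappa + 0.5, 1.5)))


def _kernel_cutoff(kappa: float, tail: float = 1e-3) -> float:
    """Angle (radians) beyond which cos^{2k}(w/2) < tail (relative)."""
    # cos^{2k}(w/2) = exp(2k ln cos(w/2)); solve exactly
    c = np.exp(np.log(tail) / (2.0 * kappa))
    return float(2.0 * np.arccos(max(c, 0.0)))


# ---------------------------------------------------------------------------
# quadrature grid on the fundamental Euler-angle box
# ---------------------------------------------------------------------------

_GRID_CACHE: dict = {}


def _fz_euler_box(sym: CrystalSymmetry) -> tuple:
    """Euler-angle box (phi1, Phi, phi2 extents, degrees) covering each
    symmetry orbit once (a.e.).  For hexagonal 622 this is the standard
    0..360 x 0..90 x 0..60 region; the fallback is the full Euler space.
    """
    if sym.order == 12:
        return (360.0, 90.0, 60.0)
    if sym.order == 1:
        return (360.0, 180.0, 360.0)
    return (360.0, 180.0, 360.0 / (sym.order / (2 if sym.order % 2 == 0 else 1)))


def so3_quadrature(sym: CrystalSymmetry, resolution_deg: float = 2.0):
    """Deterministic equal-measure quadrature over the fundamental zone.

    Returns (quaternions (M, 4), weights (M,) summing to 1).  Cell midpoints
    of a Bunge Euler-angle grid, weighted by sin(Phi) — the exact Haar
    density in Euler angles — so boundary cells carry their true measure.
    """
    key = (sym.name, sym.order, round(resolution_deg, 6))
    if key in _GRID_CACHE:
        return _GRID_CACHE[key]
    e1, e2, e3 = _fz_euler_box(sym)
    n1 = max(int(round(e1 / resolution_deg)), 1)
    n2 = max(int(round(e2 / resolution_deg)), 1)
    n3 = max(int(round(e3 / resolution_deg)), 1)
    phi1 = (np.arange(n1) + 0.5) * (e1 / n1)
    Phi = (np.arange(n2) + 0.5) * (e2 / n2)
    phi2 = (np.arange(n3) + 0.5) * (e3 / n3)
    g1, g2, g3 = np.meshgrid(phi1, Phi, phi2, indexing="ij")
    angles = np.column_stack([g1.ravel(), g2.ravel(), g3.ravel()])
    quats = Orientation.from_euler(angles).quat
    # left-rotate by a fixed generic rotation: still a fundamental domain
    # (left multiplication commutes with the right symmetry action) but the
    # distorted cells near the Euler gimbal locus no longer coincide with
    # special orientations such as the identity
    from .orientation import _axis_angle_quat

    r0 = _axis_angle_quat(np.array([1.0, 2.0, 3.0]), 0.5877)
    quats = qcanonical(qmul(r0[None, :], quats))
    w = np.sin(np.radians(angles[:, 1]))
    w /= w.sum()
    _GRID_CACHE[key] = (quats, w)
    return quats, w


def _tree_for_nodes(quats: np.ndarray, key) -> cKDTree:
    cache_key = ("tree",) + key
    if cache_key in _GRID_CACHE:
        return _GRID_CACHE[cache_key]
    tree = cKDTree(quats)
    _GRID_CACHE[cache_key] = tree
    return tree


# ---------------------------------------------------------------------------
# ODF model
# ---------------------------------------------------------------------------

@dataclass
class ODFModel:
    """Symmetrized kernel-density ODF with unit total mass.

    Attributes
    ----------
    orientations : Orientation
        Kernel centers g_i.
    weights : ndarray
        Component weights, summing to 1 - uniform_fraction.
    halfwidth : float
        Kernel half width at half maximum, degrees.
    symmetry : CrystalSymmetry
    uniform_fraction : float
        Optional uniform (random-texture) portion of the mass.
    """

    orientations: Orientation
    weights: np.ndarray
    halfwidth: float
    symmetry: CrystalSymmetry
    uniform_fraction: float = 0.0
    kappa: float = field(init=False)

    def __post_init__(self):
        self.kappa = kappa_from_halfwidth(self.halfwidth)
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        total = w.sum()
        if total <= 0 and self.uniform_fraction == 0:
            raise ValueError("ODF must carry positive mass")
        if total > 0:
            w = w / total * (1.0 - self.uniform_fraction)
        self.weights = w

    # -- symmetrized kernel centers -----------------------------------------

    def _copies(self):
        """All symmetry copies of the centers, weights divided by |G|."""
        s = self.symmetry.quats
        copies = qcanonical(
            qmul(self.orientations.quat[:, None, :], s[None, :, :])
        ).reshape(-1, 4)
        w = np.repeat(self.weights / self.symmetry.order, self.symmetry.order)
        return copies, w

    def evaluate(self, quats: np.ndarray) -> np.ndarray:
        """f(g) at scalar-first quaternions (m, 4) (dense evaluation)."""
        quats = qcanonical(np.atleast_2d(quats))
        copies, w = self._copies()
        C = kernel_constant(self.kappa)
        out = np.full(quats.shape[0], float(self.uniform_fraction))
        # evaluate the power only inside the kernel's effective support
        thresh = np.cos(_kernel_cutoff(self.kappa) / 2.0)
        chunk = max(1, int(4e7) // max(copies.shape[0], 1))
        for i in range(0, quats.shape[0], chunk):
            dots = np.abs(quats[i:i + chunk] @ copies.T)  # |cos(omega/2)|
            np.clip(dots, 0.0, 1.0, out=dots)
            if thresh > 0.2:
                rows, cols = np.nonzero(dots > thresh)
                vals = C * dots[rows, cols] ** (2.0 * self.kappa) * w[cols]
                np.add.at(out, i + rows, vals)
            else:
                out[i:i + chunk] += C * (dots ** (2.0 * self.kappa)) @ w
        return out

    def _evaluate_on_grid(self, nodes: np.ndarray, tree: cKDTree) -> np.ndarray:
        """Sparse evaluation at grid nodes using the kernel's compact support."""
        copies, w = self._copies()
        kappa = self.kappa
        cutoff = _kernel_cutoff(kappa)
        if cutoff > np.pi / 2:  # broad kernel: sparse search pointless
            return self.evaluate(nodes)
        # chordal radius in quaternion space: |q1 - q2| = 2 sin(omega/4)
        r = 2.0 * np.sin(cutoff / 4.0)
        # duplicate centers close to the w=0 seam so each node sees the
        # representative in its own sign half
        seam = np.abs(copies[:, 0]) < np.sin(cutoff / 2.0) + 0.05
        pts = np.vstack([copies, -copies[seam]])
        wts = np.concatenate([w, w[seam]])
        # drop symmetry copies with no quadrature node in kernel range
        # (most copies lie far from the fundamental-zone node region)
        d, _ = tree.query(pts, k=1, distance_upper_bound=r)
        near = np.isfinite(d)
        pts, wts = pts[near], wts[near]
        if pts.shape[0] == 0:
            return np.full(nodes.shape[0], float(self.uniform_fraction))
        data_tree = cKDTree(pts)
        pairs = tree.sparse_distance_matrix(
            data_tree, max_distance=r, output_type="ndarray"
        )
        C = kernel_constant(kappa)
        omega_half = 2.0 * np.arcsin(np.clip(pairs["v"] / 2.0, 0.0, 1.0))
        vals = C * np.cos(omega_half) ** (2.0 * kappa) * wts[pairs["j"]]
        out = np.bincount(pairs["i"], weights=vals, minlength=nodes.shape[0])
        out += float(self.uniform_fraction)
        return out

    def mass(self, resolution_deg: float = None) -> float:
        """Quadrature total mass (should be 1 within 0.5%)."""
        res = resolution_deg or min(2.0, self.halfwidth / 2.0)
        nodes, w = so3_quadrature(self.symmetry, res)
        tree = _tree_for_nodes(nodes, (self.symmetry.name, self.symmetry.order,
                                       round(res, 6)))
        return float(w @ self._evaluate_on_grid(nodes, tree))


def build_odf(orientations: Orientation, sym: CrystalSymmetry,
              halfwidth: float = 4.0, weights=None) -> ODFModel:
    """Kernel-density ODF from measured orientations (equal weights)."""
    if len(orientations) < 1:
        raise ValueError("at least one orientation is required")
    if weights is None:
        weights = np.full(len(orientations), 1.0 / len(orientations))
    return ODFModel(orientations=orientations, weights=np.asarray(weights),
                    halfwidth=halfwidth, symmetry=sym)


# ---------------------------------------------------------------------------
# Texture Index
# ---------------------------------------------------------------------------

def texture_index(odf: ODFModel, method: str = "quadrature",
                  resolution_deg: float = None) -> float:
    """TI = integral of f(g)^2 over the normalized Haar measure.

    ``method='quadrature'`` integrates f^2 on a deterministic grid in the
    fundamental zone at resolution <= halfwidth/2.  ``method='series'``
    evaluates the same integral in closed form through the kernel
    autocorrelation (pairwise over components); the two agree within the
    quadrature error and serve as mutual checks.
    """
    if method == "series":
        return _texture_index_series(odf)
    if method != "quadrature":
        raise ValueError(f"unknown method {method!r}")
    res = resolution_deg or min(2.0, odf.halfwidth / 2.0)
    nodes, w = so3_quadrature(odf.symmetry, res)
    tree = _tree_for_nodes(nodes, (odf.symmetry.name, odf.symmetry.order,
                                   round(res, 6)))
    f = odf._evaluate_on_grid(nodes, tree)
    return float(w @ f**2)


_AUTOCORR_CACHE: dict = {}


def _kernel_autocorrelation(kappa: float):
    """Interpolant of A(theta) = (psi * psi)(r_theta) via Chebyshev series.

    psi has character coefficients psi_l = int psi chi_l d(Haar); convolution
    gives A(theta) = sum_l psi_l^2 / (2l + 1) * chi_l(theta).
    """
    key = round(kappa, 9)
    if key in _AUTOCORR_CACHE:
        return _AUTOCORR_CACHE[key]
    lmax = min(int(5.0 * np.sqrt(kappa)) + 25, 2000)
    # Gauss-Legendre quadrature on omega in [0, pi]
    x, gw = np.polynomial.legendre.leggauss(2048)
    omega = (x + 1.0) * (np.pi / 2.0)
    gw = gw * (np.pi / 2.0)
    C = kernel_constant(kappa)
    psi = C * np.cos(omega / 2.0) ** (2.0 * kappa)
    haar = (2.0 / np.pi) * np.sin(omega / 2.0) ** 2
    ls = np.arange(lmax + 1)
    # chi_l(omega) = sin((2l+1) omega/2) / sin(omega/2)
    sin_half = np.sin(omega / 2.0)
    chi = np.sin(np.outer(2 * ls + 1, omega / 2.0)) / sin_half[None, :]
    coeff = chi @ (psi * haar * gw)  # psi_l
    theta = np.linspace(0.0, np.pi, 6001)
    sin_t = np.sin(theta / 2.0)
    sin_t[0] = 1.0  # chi_l(0) handled analytically below
    chi_t = np.sin(np.outer(2 * ls + 1, theta / 2.0)) / sin_t[None, :]
    chi_t[:, 0] = 2 * ls + 1
    a = (coeff**2 / (2 * ls + 1)) @ chi_t
    interp = (theta, a)
    _AUTOCORR_CACHE[key] = interp
    return interp


def _texture_index_series(odf: ODFModel) -> float:
    q = odf.orientations.quat
    n = q.shape[0]
    if n > 4000:
        raise ValueError("series method is quadratic in components; "
                         "use method='quadrature' for large inputs")
    theta_grid, a_grid = _kernel_autocorrelation(odf.kappa)
    s = odf.symmetry.quats * np.array([1.0, -1.0, -1.0, -1.0])
    w = odf.weights
    u = odf.uniform_fraction
    total = u**2 + 2.0 * u * (1.0 - u)
    m = qmul(qconj_rows(q)[:, None, :], q[None, :, :]).reshape(-1, 4)
    # cos(omega/2) for every symmetry product of every pair
    dots = np.clip(np.abs(m @ s.T), 0.0, 1.0)
    ang = 2.0 * np.arccos(dots)  # (n*n, order)
    # cross term of two symmetrized kernels: mean of A over the one-sided
    # symmetry products (the two-sided double sum collapses by conjugation
    # invariance of the rotation angle)
    A = np.interp(ang, theta_grid, a_grid).mean(axis=1).reshape(n, n)
    return float(total + w @ A @ w)


def qconj_rows(q: np.ndarray) -> np.ndarray:
    out = q.copy()
    out[:, 1:] *= -1.0
    return out


_MC_CACHE: dict = {}


def texture_index_mc(odf: ODFModel, n_samples: int = 10**6,
                     seed: int = 0) -> float:
    """Monte-Carlo TI: mean of f(g)^2 over Haar samples (oracle-grade).

    The Haar sample set (and its KD-tree, used to exploit the kernel's
    compact support) is cached per (n_samples, seed) so repeated checks
    against the same sample set are cheap.
    """
    from .orientation import random_uniform_orientations

    key = (n_samples, seed)
    if key not in _MC_CACHE:
        if len(_MC_CACHE) > 4:
            _MC_CACHE.clear()
        g = random_uniform_orientations(n_samples, seed)
        _MC_CACHE[key] = (g.quat, cKDTree(g.quat))
    quats, tree = _MC_CACHE[key]
    f = odf._evaluate_on_grid(quats, tree)
    return float(np.mean(f**2))


# ---------------------------------------------------------------------------
# pole figures
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int = 16384) -> np.ndarray:
    """Near-uniform spherical Fibonacci lattice (equal-area weights 1/n)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class PoleDensity:
    """Spherical kernel density of a direction family, in MUD units."""

    nodes: np.ndarray      # (m, 3) unit vectors, equal-area
    mud: np.ndarray        # (m,) multiples of uniform density
    family: MillerDirectionFamily
    halfwidth: float

    @property
    def max_mud(self) -> float:
        return float(self.mud.max())

    def upper_hemisphere(self):
        """Stereographic upper-hemisphere export (azimuth, polar, MUD).

        Antipodal symmetry makes the lower hemisphere redundant.
        """
        keep = self.nodes[:, 2] >= 0.0
        xyz = self.nodes[keep]
        az = np.degrees(np.arctan2(xyz[:, 1], xyz[:, 0])) % 360.0
        polar = np.degrees(np.arccos(np.clip(xyz[:, 2], -1.0, 1.0)))
        return az, polar, self.mud[keep]


def pole_density(orientations, family: MillerDirectionFamily,
                 sym: CrystalSymmetry = None, halfwidth: float = 4.0,
                 grid_n: int = 16384, weights=None) -> PoleDensity:
    """MUD-normalized spherical KDE of a crystal-direction family.

    Accepts an :class:`ODFModel` (components + weights) or an
    :class:`Orientation` set (equal weights).  All symmetry-equivalent
    directions are mapped to the specimen frame, antipodally symmetrized,
    and smoothed with a spherical de la Vallee Poussin kernel of the given
    halfwidth (HWHM).  The uniform distribution evaluates to 1.
    """
    uniform = 0.0
    if isinstance(orientations, ODFModel):
        odf = orientations
        sym = odf.symmetry
        ori, w = odf.orientations, odf.weights
        halfwidth = halfwidth or odf.halfwidth
        uniform = odf.uniform_fraction
    else:
        ori = orientations
        if sym is None:
            raise ValueError("sym is required with raw orientations")
        w = (np.full(len(ori), 1.0 / len(ori)) if weights is None
             else np.asarray(weights, dtype=float) / np.sum(weights))
    hkl = family.vectors(sym)                      # (m, 3) crystal frame
    dirs = ori.rotate(hkl).reshape(-1, 3)          # specimen frame
    dw = np.repeat(w / hkl.shape[0], hkl.shape[0])
    # antipodal symmetrization: both hemispheres, half weight each
    dirs = np.vstack([dirs, -dirs])
    dw = np.concatenate([dw, dw]) / 2.0
    if dirs.shape[0] > 65536:
        # accumulate weights on a fine auxiliary lattice (~0.9 deg spacing,
        # well under the kernel halfwidth) to bound the density cost
        aux = fibonacci_sphere(49152)
        _, idx = cKDTree(aux).query(dirs)
        dw = np.bincount(idx, weights=dw, minlength=aux.shape[0])
        keep = dw > 0
        dirs, dw = aux[keep], dw[keep]

    kappa = kappa_from_halfwidth(halfwidth)
    nodes = fibonacci_sphere(grid_n)
    cutoff = _kernel_cutoff(kappa)
    mud = np.full(grid_n, uniform)
    if cutoff < np.pi / 2:
        r = 2.0 * np.sin(cutoff / 2.0)
        node_tree = cKDTree(nodes)
        pairs = node_tree.sparse_distance_matrix(
            cKDTree(dirs), max_distance=r, output_type="ndarray"
        )
        cos_t = 1.0 - pairs["v"] ** 2 / 2.0
        vals = (kappa + 1.0) * ((1.0 + cos_t) / 2.0) ** kappa * dw[pairs["j"]]
        mud = mud + np.bincount(pairs["i"], weights=vals, minlength=grid_n)
    else:
        chunk = max(1, int(4e7) // max(dirs.shape[0], 1))
        for i in range(0, grid_n, chunk):
            cos_t = np.clip(nodes[i:i + chunk] @ dirs.T, -1.0, 1.0)
            mud[i:i + chunk] += (
                (kappa + 1.0) * ((1.0 + cos_t) / 2.0) ** kappa
            ) @ dw
    return PoleDensity(nodes=nodes, mud=mud, family=family,
                       halfwidth=halfwidth)


def pfj(density: PoleDensity) -> float:
    """Pole-figure texture index: integral of MUD^2 over the sphere."""
    return float(np.mean(density.mud**2))


# ---------------------------------------------------------------------------
# region summary
# ---------------------------------------------------------------------------

@dataclass
class TextureSummary:
    """Scalar texture indices for one map region."""

    ti: float
    pfj_c: float
    pfj_a: float
    max_mud: float
    area_um2: float
    n_orientations: int


_C_AXIS = MillerDirectionFamily.from_string("0001")
_A_AXIS = MillerDirectionFamily.from_string("11-20")


def summarize_texture(orientations: Orientation, sym: CrystalSymmetry,
                      halfwidth: float = 4.0, area_um2: float = float("nan"),
                      grid_n: int = 8192) -> TextureSummary:
    """TI, pfJ (c and a axes) and peak MUD for a set of orientations."""
    odf = build_odf(orientations, sym, halfwidth=halfwidth)
    ti = texture_index(odf)
    pd_c = pole_density(orientations, _C_AXIS, sym=sym, halfwidth=halfwidth,
                        grid_n=grid_n)
    pd_a = pole_density(orientations, _A_AXIS, sym=sym, halfwidth=halfwidth,
                        grid_n=grid_n)
    return TextureSummary(
        ti=ti,
        pfj_c=pfj(pd_c),
        pfj_a=pfj(pd_a),
        max_mud=max(pd_c.max_mud, pd_a.max_mud),
        area_um2=area_um2,
        n_orientations=len(orientations),
    )
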