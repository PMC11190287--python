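"""Rotations, crystal symmetry and misorientation arithmetic.

Conventions
-----------
* Quaternions are scalar-first ``(w, x, y, z)`` unit quaternions, canonicalized
  to ``w >= 0`` (q and -q describe the same rotation).
* An :class:`Orientation` is the rotation mapping crystal coordinates into
  specimen coordinates (the convention of texture analysis toolboxes).
* Bunge Euler angles (phi1, Phi, phi2) follow the EBSD vendor convention:
  the Z-X-Z intrinsic sequence describing the specimen-to-crystal transform.
  Files carry degrees; everything internal is quaternions.
* Crystal symmetry acts by right multiplication: ``g ~ g * s`` for the proper
  rotations ``s`` of the crystal point group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Orientation",
    "CrystalSymmetry",
    "MillerDirectionFamily",
    "misorientation_angle",
    "fundamental_zone_project",
    "random_uniform_orientations",
]

_UNIT_TOL = 1e-3  # inputs farther than this from unit norm are rejected


# ---------------------------------------------------------------------------
# low-level quaternion helpers (scalar-first arrays, shape (..., 4))
# ---------------------------------------------------------------------------

def qmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product of scalar-first quaternion arrays (broadcasting)."""
    aw, ax, ay, az = np.moveaxis(a, -1, 0)
    bw, bx, by, bz = np.moveaxis(b, -1, 0)
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def qconj(q: np.ndarray) -> np.ndarray:
    out = np.array(q, copy=True)
    out[..., 1:] *= -1.0
    return out


def qcanonical(q: np.ndarray) -> np.ndarray:
    """Resolve the sign ambiguity: w >= 0, ties broken by first nonzero part."""
    q = np.asarray(q, dtype=float)
    sign = np.sign(q[..., 0])
    # for w == 0 fall back to the first nonzero vector component
    for k in (1, 2, 3):
        sign = np.where(sign == 0, np.sign(q[..., k]), sign)
    sign = np.where(sign == 0, 1.0, sign)
    return q * sign[..., None]


def qangle(q: np.ndarray, degrees: bool = True) -> np.ndarray:
    """Rotation angle of scalar-first quaternions, in [0, 180] degrees."""
    w = np.clip(np.abs(np.asarray(q)[..., 0]), -1.0, 1.0)
    ang = 2.0 * np.arccos(w)
    return np.degrees(ang) if degrees else ang


def qrotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vectors ``v`` (..., 3) by quaternions ``q`` (..., 4)."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    w = q[..., :1]
    u = q[..., 1:]
    cross = np.cross(u, v)
    return v + 2.0 * (w * cross + np.cross(u, cross))


def _axis_angle_quat(axis, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    h = angle_rad / 2.0
    return np.concatenate([[np.cos(h)], np.sin(h) * axis])


# ---------------------------------------------------------------------------
# Orientation container
# ---------------------------------------------------------------------------

class Orientation:
    """A (possibly vectorized) crystal orientation stored as unit quaternions.

    Parameters
    ----------
    quat : array_like, shape (4,) or (n, 4)
        Scalar-first quaternions.  Norms must be within ``1e-3`` of 1; they
        are renormalized and canonicalized (``w >= 0``) on construction.
    """

    __slots__ = ("quat",)

    def __init__(self, quat):
        q = np.atleast_2d(np.asarray(quat, dtype=float))
        if q.ndim != 2 or q.shape[1] != 4:
            raise ValueError("quaternions must have shape (n, 4) scalar-first")
        norms = np.linalg.norm(q, axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError(
                "non-unit quaternion input (|norm - 1| > %g)" % _UNIT_TOL
            )
        self.quat = qcanonical(q / norms[:, None])

    # -- constructors -------------------------------------------------------

    @classmethod
    def identity(cls, n: int = 1) -> "Orientation":
        q = np.zeros((n, 4))
        q[:, 0] = 1.0
        return cls(q)

    @classmethod
    def from_euler(cls, angles, degrees: bool = True) -> "Orientation":
        """Orientations from Bunge Euler angles (phi1, Phi, phi2).

        The Euler triplet defines Bunge's passive specimen-to-crystal
        transform; the stored active crystal-to-specimen rotation is its
        transpose, which equals the intrinsic Z-X-Z rotation by the same
        angles.
        """
        ang = np.atleast_2d(np.asarray(angles, dtype=float))
        rot = Rotation.from_euler("ZXZ", ang, degrees=degrees)
        return cls(np.roll(rot.as_quat(), 1, axis=-1))

    # -- accessors ----------------------------------------------------------

    def as_euler(self, degrees: bool = True) -> np.ndarray:
        """Bunge Euler angles (phi1, Phi, phi2), inverse of :meth:`from_euler`."""
        import warnings

        rot = Rotation.from_quat(np.roll(self.quat, -1, axis=-1))
        with warnings.catch_warnings():
            # gimbal lock (Phi = 0) is fine: any (phi1, phi2) split of the
            # z-rotation describes the same orientation
            warnings.simplefilter("ignore", UserWarning)
            ang = rot.as_euler("ZXZ", degrees=degrees)
        period = 360.0 if degrees else 2.0 * np.pi
        return np.mod(ang, period)

    def __len__(self) -> int:
        return self.quat.shape[0]

    def __getitem__(self, item) -> "Orientation":
        return Orientation(np.atleast_2d(self.quat[item]))

    def __mul__(self, other: "Orientation") -> "Orientation":
        return Orientation(qmul(self.quat, other.quat))

    def inv(self) -> "Orientation":
        return Orientation(qconj(self.quat))

    def angle(self, degrees: bool = True) -> np.ndarray:
        """Rotation angle away from the identity."""
        return qangle(self.quat, degrees=degrees)

    def rotate(self, vectors: np.ndarray) -> np.ndarray:
        """Map crystal-frame vectors into the specimen frame."""
        return qrotate(self.quat[:, None, :], np.atleast_2d(vectors)[None, :, :])

    def __repr__(self) -> str:  # pragma: no cover
        return f"Orientation(n={len(self)})"


# ---------------------------------------------------------------------------
# crystal symmetry
# ---------------------------------------------------------------------------

def _hexagonal_622_quats() -> np.ndarray:
    """The 12 proper rotations of point group 622 (hexagonal Laue class)."""
    ops = []
    for k in range(6):  # rotations about the c-axis (z)
        ops.append(_axis_angle_quat([0.0, 0.0, 1.0], k * np.pi / 3.0))
    for k in range(6):  # two-fold axes in the basal plane, every 30 degrees
        th = k * np.pi / 6.0
        ops.append(_axis_angle_quat([np.cos(th), np.sin(th), 0.0], np.pi))
    return qcanonical(np.array(ops))


@dataclass(frozen=True)
class CrystalSymmetry:
    """A crystal point group given by its proper rotations, plus the lattice.

    The default lattice parameters are those of fluorapatite
    (a = 9.37 A, c = 6.88 A); both are overridable.
    """

    name: str = "apatite 6/mmm"
    a: float = 9.37
    c: float = 6.88
    _quats: tuple = field(default=None, repr=False, compare=False)

    @classmethod
    def hexagonal(cls, a: float = 9.37, c: float = 6.88,
                  name: str = "apatite 6/mmm") -> "CrystalSymmetry":
        return cls(name=name, a=a, c=c,
                   _quats=tuple(map(tuple, _hexagonal_622_quats())))

    @classmethod
    def triclinic(cls, a: float = 1.0, c: float = 1.0,
                  name: str = "triclinic") -> "CrystalSymmetry":
        return cls(name=name, a=a, c=c, _quats=((1.0, 0.0, 0.0, 0.0),))

    @property
    def quats(self) -> np.ndarray:
        """Proper rotations as an (order, 4) array; identity first."""
        if self._quats is None:
            return _hexagonal_622_quats()
        return np.asarray(self._quats, dtype=float)

    @property
    def order(self) -> int:
        return self.quats.shape[0]

    def is_group(self, tol: float = 1e-10) -> bool:
        """Table check: closure under composition and identity membership."""
        q = self.quats
        if not np.allclose(q[0], [1.0, 0.0, 0.0, 0.0], atol=tol):
            return False
        prod = qcanonical(qmul(q[:, None, :], q[None, :, :]))  # (n, n, 4)
        dots = np.abs(np.einsum("ijk,lk->ijl", prod, q))
        return bool(np.all(dots.max(axis=-1) > 1.0 - tol))

    def __hash__(self):
        return hash((self.name, self.a, self.c, self.order))


# ---------------------------------------------------------------------------
# Miller-Bravais direction families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MillerDirectionFamily:
    """A 4-index Miller-Bravais direction <uvtw> and its symmetric orbit."""

    u: int
    v: int
    t: int
    w: int

    def __post_init__(self):
        if self.u + self.v + self.t != 0:
            raise ValueError("Miller-Bravais indices require u + v + t = 0")

    @classmethod
    def from_string(cls, text: str) -> "MillerDirectionFamily":
        """Parse compact notation such as '0001', '10-10' or '11-20'."""
        digits = []
        i = 0
        s = text.strip().strip("<>")
        while i < len(s):
            if s[i] == "-":
                digits.append(-int(s[i + 1]))
                i += 2
            else:
                digits.append(int(s[i]))
                i += 1
        if len(digits) != 4:
            raise ValueError(f"cannot parse Miller-Bravais direction {text!r}")
        return cls(*digits)

    def cartesian(self, sym: CrystalSymmetry) -> np.ndarray:
        """Unit vector of the direction in the crystal Cartesian frame."""
        a, c = sym.a, sym.c
        a1 = a * np.array([1.0, 0.0, 0.0])
        a2 = a * np.array([-0.5, np.sqrt(3.0) / 2.0, 0.0])
        a3 = a * np.array([-0.5, -np.sqrt(3.0) / 2.0, 0.0])
        cz = c * np.array([0.0, 0.0, 1.0])
        v = self.u * a1 + self.v * a2 + self.t * a3 + self.w * cz
        return v / np.linalg.norm(v)

    def vectors(self, sym: CrystalSymmetry, tol: float = 1e-8) -> np.ndarray:
        """Symmetry-equivalent unit vectors of the family (crystal frame)."""
        v0 = self.cartesian(sym)
        orbit = qrotate(sym.quats, v0[None, :])
        keep = []
        for v in orbit:
            if not any(np.allclose(v, u, atol=tol) for u in keep):
                keep.append(v)
        return np.array(keep)

    def __str__(self) -> str:  # pragma: no cover
        return f"<{self.u}{self.v}{self.t}{self.w}>"


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _sym_cos_half(m: np.ndarray, sym: CrystalSymmetry) -> np.ndarray:
    """max_s |Re(m * s)| for quaternions m (n, 4): cos(omega_min / 2).

    Right multiplication by all group elements suffices for the angle:
    the rotation angle is conjugation-invariant, so
    angle(s1 * m * s2) = angle(m * s2 * s1) and the two-sided orbit of
    angles equals the one-sided one.
    """
    s = sym.quats * np.array([1.0, -1.0, -1.0, -1.0])
    dots = np.abs(m @ s.T)  # (n, order): |w(m * s)|
    return np.clip(dots.max(axis=-1), -1.0, 1.0)


def misorientation_angle(o1: Orientation, o2: Orientation,
                         sym: CrystalSymmetry, degrees: bool = True):
    """Symmetry-reduced misorientation angle between paired orientations.

    Returns the minimum rotation angle over all symmetry-equivalent
    products ``s1 * o1^-1 * o2 * s2``; a scalar if both inputs are scalar.
    """
    m = qmul(qconj(o1.quat), o2.quat)
    ang = 2.0 * np.arccos(_sym_cos_half(m, sym))
    if degrees:
        ang = np.degrees(ang)
    return float(ang[0]) if ang.shape == (1,) else ang


def fundamental_zone_project(o: Orientation, sym: CrystalSymmetry) -> Orientation:
    """Symmetry-equivalent representative with the smallest rotation angle.

    Idempotent; ties resolve to the earliest symmetry operation (identity
    first), so an already-projected orientation maps to itself.
    """
    copies = qcanonical(qmul(o.quat[:, None, :], sym.quats[None, :, :]))
    w = np.abs(copies[..., 0])
    best = np.argmax(np.round(w, 12), axis=1)  # round: deterministic ties
    return Orientation(copies[np.arange(len(o)), best])


def random_uniform_orientations(n: int, seed: int) -> Orientation:
    """``n`` orientations drawn from the Haar (uniform) measure on SO(3)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1)[:, None]
    return Orientation(q)


@lru_cache(maxsize=8)
def symmetry_copy_quats(sym: CrystalSymmetry):
    """Cached (order, 4) array of group quaternions (identity first)."""
    return sym.quats
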