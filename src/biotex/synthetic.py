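"""Synthetic EBSD maps and Raman spectra with known ground truth.

The generator emulates the texture archetypes of conodont hyaline tissue:
apatite c-axes concentrated near the functional (X, occlusal) axis with a
taxon-dependent angular dispersion, and rotation about the c-axis ranging
from a uniform girdle (over the 60-degree hexagonal period), through a
dispersed unimodal spread, to tight clusters (including a 3-cluster case).
Orientations are organized into spatially coherent elongated patches whose
long axes need not follow the crystallographic c-axis, and a fraction of
pixels is left non-indexed, either at random or preferentially along patch
borders (mimicking the beam-damage pattern that makes inferred grain
boundaries trace missing data).

Every generator is a pure function of (recipe, seed) and emits its ground
truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import EBSDMap
from .orientation import CrystalSymmetry, Orientation, qcanonical, qmul
from .raman import RamanSpectrum

__all__ = ["TextureRecipe", "GroundTruth", "generate_map", "taxon_series",
           "generate_raman"]


@dataclass
class TextureRecipe:
    """Parameters controlling one synthetic texture.

    a_rotation_model is one of:
      * ("girdle",) - uniform rotation about c over the 60-degree period;
      * ("dispersed", sd_deg) - wrapped normal spread about one angle;
      * ("clustered", centers_deg, weights, sd_deg) - mixture of wrapped
        normal clusters (the 3-cluster case of some taxa).
    """

    c_axis_mean_direction: tuple = (1.0, 0.0, 0.0)   # specimen X (occlusal)
    c_dispersion: float = 10.0                       # angular sd, degrees
    a_rotation_model: tuple = ("girdle",)
    patch_length: float = 12.0                       # pixels
    patch_width: float = 4.0                         # pixels
    patch_axis_deg: float = 0.0                      # elongation axis vs x
    patch_noise: float = 3.0                         # within-patch sd, deg
    unindexed_fraction: float = 0.25
    unindexed_mode: str = "random"                   # "random"|"patch-border"
    lattice: tuple = (9.37, 6.88)

    def __post_init__(self):
        if not 0.0 <= self.unindexed_fraction < 1.0:
            raise ValueError("unindexed_fraction must be in [0, 1)")
        if self.c_dispersion < 0 or self.patch_noise < 0:
            raise ValueError("dispersions must be >= 0")
        if self.a_rotation_model[0] == "clustered":
            w = np.asarray(self.a_rotation_model[2], dtype=float)
            if not np.isclose(w.sum(), 1.0):
                raise ValueError("cluster weights must sum to 1")


@dataclass
class GroundTruth:
    """Per-patch generation parameters and the per-pixel patch id raster."""

    patches: pd.DataFrame
    patch_id: np.ndarray
    recipe: TextureRecipe = field(repr=False, default=None)


def _align_z_to(direction: np.ndarray) -> np.ndarray:
    """Quaternion of the shortest-arc rotation taking +z to ``direction``."""
    d = direction / np.linalg.norm(direction)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, d))
    if c > 1.0 - 1e-12:
        return np.array([1.0, 0.0, 0.0, 0.0])
    if c < -1.0 + 1e-12:
        return np.array([0.0, 1.0, 0.0, 0.0])  # 180 about x
    axis = np.cross(z, d)
    axis /= np.linalg.norm(axis)
    half = np.arccos(np.clip(c, -1.0, 1.0)) / 2.0
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def _sample_c_axis(rng, mean_dir, sd_deg: float, n: int) -> np.ndarray:
    """Fisher-type rotationally symmetric spread about the mean direction."""
    mean_dir = np.asarray(mean_dir, dtype=float)
    mean_dir = mean_dir / np.linalg.norm(mean_dir)
    if sd_deg == 0:
        return np.tile(mean_dir, (n, 1))
    # tangent-plane Gaussian mapped by the exponential map
    t = rng.standard_normal((n, 2)) * np.radians(sd_deg)
    theta = np.linalg.norm(t, axis=1)
    # orthonormal tangent basis
    helper = np.array([0.0, 0.0, 1.0])
    if abs(mean_dir @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(mean_dir, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mean_dir, e1)
    with np.errstate(invalid="ignore"):
        unit_t = np.where(theta[:, None] > 0,
                          (t[:, :1] * e1 + t[:, 1:] * e2)
                          / np.where(theta[:, None] == 0, 1.0,
                                     theta[:, None]),
                          0.0)
    return (np.cos(theta)[:, None] * mean_dir
            + np.sin(theta)[:, None] * unit_t)


def _sample_a_rotation(rng, model: tuple, n: int) -> np.ndarray:
    """Rotation angle about c (degrees), on the 60-degree hexagonal period."""
    kind = model[0]
    if kind == "girdle":
        return rng.uniform(0.0, 60.0, n)
    if kind == "dispersed":
        sd = float(model[1])
        center = rng.uniform(0.0, 60.0)  # one spread per recipe draw
        return np.mod(center + rng.standard_normal(n) * sd, 60.0)
    if kind == "clustered":
        centers = np.asarray(model[1], dtype=float)
        weights = np.asarray(model[2], dtype=float)
        sd = float(model[3])
        which = rng.choice(len(centers), size=n, p=weights)
        return np.mod(centers[which] + rng.standard_normal(n) * sd, 60.0)
    raise ValueError(f"unknown a-rotation model {kind!r}")


def _small_random_rotations(rng, sd_deg: float, n: int) -> np.ndarray:
    """Quaternions of small random rotations (random axis, |N(0, sd)| angle)."""
    if sd_deg == 0:
        q = np.zeros((n, 4))
        q[:, 0] = 1.0
        return q
    axis = rng.standard_normal((n, 3))
    axis /= np.linalg.norm(axis, axis=1)[:, None]
    ang = np.abs(rng.standard_normal(n)) * np.radians(sd_deg)
    half = ang / 2.0
    return np.column_stack([np.cos(half), np.sin(half)[:, None] * axis])


def generate_map(recipe: TextureRecipe, width: int, height: int,
                 step: float = 0.5, seed: int = 0):
    """Synthetic EBSD map plus ground truth.

    The raster is tessellated into elongated patches by anisotropic Voronoi
    seeds (distance stretched along the patch elongation axis); each patch
    draws one c-axis and one a-rotation from the recipe's distributions,
    each pixel adds within-patch orientation noise, and the requested
    fraction of pixels is masked non-indexed.
    """
    rng = np.random.default_rng(seed)
    n_pix = width * height
    n_patches = max(1, int(round(
        n_pix / (recipe.patch_length * recipe.patch_width))))
    seeds = np.column_stack([
        rng.uniform(0, width, n_patches),
        rng.uniform(0, height, n_patches),
    ])
    # anisotropic metric: shrink coordinates along the elongation axis
    alpha = np.radians(recipe.patch_axis_deg)
    rot = np.array([[np.cos(alpha), np.sin(alpha)],
                    [-np.sin(alpha), np.cos(alpha)]])
    stretch = np.array([1.0 / recipe.patch_length, 1.0 / recipe.patch_width])

    def metric(xy):
        return (xy @ rot.T) * stretch[None, :] * (
            (recipe.patch_length + recipe.patch_width) / 2.0)

    yy, xx = np.mgrid[0:height, 0:width]
    pix = np.column_stack([xx.ravel() + 0.5, yy.ravel() + 0.5])
    _, patch_id = cKDTree(metric(seeds)).query(metric(pix))
    patch_id = patch_id.reshape(height, width)

    # per-patch orientation: align z (crystal c) to the drawn direction
    # after spinning by the a-rotation about c
    c_dirs = _sample_c_axis(rng, recipe.c_axis_mean_direction,
                            recipe.c_dispersion, n_patches)
    rhos = _sample_a_rotation(rng, recipe.a_rotation_model, n_patches)
    half = np.radians(rhos) / 2.0
    q_spin = np.column_stack([np.cos(half), np.zeros((n_patches, 2)),
                              np.sin(half)])
    q_align = np.array([_align_z_to(d) for d in c_dirs])
    q_patch = qcanonical(qmul(q_align, q_spin))

    # per-pixel: within-patch noise applied in the specimen frame
    q_pix = q_patch[patch_id.ravel()]
    noise = _small_random_rotations(rng, recipe.patch_noise, n_pix)
    q_pix = qcanonical(qmul(noise, q_pix))

    # non-indexed mask
    n_mask = int(round(recipe.unindexed_fraction * n_pix))
    mask = np.zeros(n_pix, dtype=bool)
    if n_mask > 0:
        if recipe.unindexed_mode == "patch-border":
            border = np.zeros((height, width), dtype=bool)
            border[:, :-1] |= patch_id[:, :-1] != patch_id[:, 1:]
            border[:, 1:] |= patch_id[:, :-1] != patch_id[:, 1:]
            border[:-1, :] |= patch_id[:-1, :] != patch_id[1:, :]
            border[1:, :] |= patch_id[:-1, :] != patch_id[1:, :]
            border_idx = np.flatnonzero(border.ravel())
            rng.shuffle(border_idx)
            take = border_idx[:n_mask]
            mask[take] = True
            rest = n_mask - take.size
            if rest > 0:
                pool = np.flatnonzero(~mask)
                mask[rng.choice(pool, size=rest, replace=False)] = True
        elif recipe.unindexed_mode == "random":
            mask[rng.choice(n_pix, size=n_mask, replace=False)] = True
        else:
            raise ValueError(
                f"unknown unindexed mode {recipe.unindexed_mode!r}")

    phase = np.where(mask, 0, 1).reshape(height, width)
    q_out = q_pix.copy()
    q_out[mask] = [1.0, 0.0, 0.0, 0.0]
    bc = np.where(mask, rng.normal(60.0, 10.0, n_pix),
                  rng.normal(150.0, 15.0, n_pix)).clip(0, 255)
    a0, c0 = recipe.lattice
    emap = EBSDMap(
        orientations=Orientation(q_out),
        phase=phase,
        band_contrast=bc.reshape(height, width),
        step=step,
        phases={1: CrystalSymmetry.hexagonal(a=a0, c=c0)},
    )
    patches = pd.DataFrame({
        "patch_id": np.arange(n_patches),
        "seed_x": seeds[:, 0], "seed_y": seeds[:, 1],
        "c_x": c_dirs[:, 0], "c_y": c_dirs[:, 1], "c_z": c_dirs[:, 2],
        "a_rotation_deg": rhos,
        "qw": q_patch[:, 0], "qx": q_patch[:, 1],
        "qy": q_patch[:, 2], "qz": q_patch[:, 3],
    })
    return emap, GroundTruth(patches=patches, patch_id=patch_id,
                             recipe=recipe)


# ---------------------------------------------------------------------------
# the six-step evolutionary series
# ---------------------------------------------------------------------------

#: Default recipes emulating the six studied taxa ordered by increasing
#: biomineralization control: every dial (c-axis dispersion, a-rotation
#: spread, within-patch noise) tightens strictly along the series.
DEFAULT_SERIES = (
    ("taxon1_coniform_early", TextureRecipe(
        c_dispersion=16.0, a_rotation_model=("girdle",),
        patch_noise=4.0, unindexed_fraction=0.35)),
    ("taxon2_coniform_derived", TextureRecipe(
        c_dispersion=12.0, a_rotation_model=("dispersed", 18.0),
        patch_noise=3.5, unindexed_fraction=0.30)),
    ("taxon3_blade_3cluster", TextureRecipe(
        c_dispersion=9.0, a_rotation_model=(
            "clustered", (10.0, 30.0, 50.0), (1 / 3, 1 / 3, 1 / 3), 6.0),
        patch_noise=3.0, unindexed_fraction=0.30)),
    ("taxon4_blade", TextureRecipe(
        c_dispersion=7.0, a_rotation_model=("dispersed", 10.0),
        patch_noise=2.5, unindexed_fraction=0.25)),
    ("taxon5_platform", TextureRecipe(
        c_dispersion=5.0, a_rotation_model=("dispersed", 6.0),
        patch_noise=2.0, unindexed_fraction=0.20)),
    ("taxon6_platform_derived", TextureRecipe(
        c_dispersion=3.5, a_rotation_model=("dispersed", 3.0),
        patch_noise=1.5, unindexed_fraction=0.15)),
)


def taxon_series(n_taxa: int = 6, schedule=None, seed: int = 0,
                 width: int = 64, height: int = 64, step: float = 0.5):
    """Maps with strictly increasing generated orientation control.

    Returns a list of (name, EBSDMap, GroundTruth).  ``schedule`` may
    override the default recipes; its dispersions must decrease
    monotonically along the series.
    """
    recipes = list(schedule) if schedule is not None else list(
        DEFAULT_SERIES[:n_taxa])
    disp = [r.c_dispersion for _, r in recipes]
    if any(d2 >= d1 for d1, d2 in zip(disp, disp[1:])):
        raise ValueError("dispersion schedule must decrease monotonically")
    out = []
    for k, (name, recipe) in enumerate(recipes):
        emap, truth = generate_map(recipe, width, height, step,
                                   seed=seed * 1000 + k)
        out.append((name, emap, truth))
    return out


# ---------------------------------------------------------------------------
# Raman
# ---------------------------------------------------------------------------

def generate_raman(pcmi: float = 964.0, fwhm: float = 4.5, eta: float = 0.5,
                   snr: float = 50.0, n_points: int = 400,
                   window=(940.0, 985.0), baseline=(50.0, 0.2),
                   amplitude: float = 1000.0, seed: int = 0
                   ) -> RamanSpectrum:
    """Pseudo-Voigt ν1 band + linear baseline + Gaussian noise at ``snr``.

    ``snr`` is peak amplitude over noise standard deviation; ``snr=inf``
    (or <= 0 treated as noiseless) gives the clean profile.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must be in [0, 1]")
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    rng = np.random.default_rng(seed)
    x = np.linspace(window[0], window[1], n_points)
    x_mid = 0.5 * (window[0] + window[1])
    half = fwhm / 2.0
    lor = 1.0 / (1.0 + ((x - pcmi) / half) ** 2)
    gau = np.exp(-4.0 * np.log(2.0) * ((x - pcmi) / fwhm) ** 2)
    y = amplitude * (eta * lor + (1.0 - eta) * gau)
    y += baseline[0] + baseline[1] * (x - x_mid)
    if np.isfinite(snr) and snr > 0:
        y = y + rng.normal(0.0, amplitude / snr, n_points)
    return RamanSpectrum(x, y, specimen="synthetic")
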