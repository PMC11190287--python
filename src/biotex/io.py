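"""Reading and writing vendor EBSD text formats (Oxford CTF, EDAX ANG).

Maps are kept bit-faithful to file content: no filtering, smoothing or
interpolation is ever applied at read time.  Non-indexed pixels (phase 0)
are carried as a mask.  The raster uses the CTF convention: origin top-left,
x rightward, y downward; the specimen frame (X = denticle long axis /
occlusal axis, Y = map north, Z = into the viewing plane) is metadata, not a
pixel transformation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .orientation import CrystalSymmetry, Orientation

__all__ = ["EBSDMap", "read_ctf", "write_ctf", "read_ang", "write_ang",
           "merge_phases", "crop"]

DEFAULT_FRAME = {
    "X": "denticle long axis (occlusal)",
    "Y": "map north",
    "Z": "into viewing plane",
}


class FormatError(ValueError):
    """Raised for malformed EBSD files."""


@dataclass
class EBSDMap:
    """Regular-grid raster of crystal orientations.

    Attributes
    ----------
    orientations : Orientation
        One quaternion per pixel, row-major (y outer, x inner).  Non-indexed
        pixels hold the identity placeholder and are excluded by the mask.
    phase : ndarray of int, shape (height, width)
        0 marks non-indexed pixels.
    band_contrast : ndarray, shape (height, width)
    step : float
        Grid step in micrometres.
    phases : dict
        phase id -> :class:`CrystalSymmetry`.
    frame : dict
        Axis-label metadata (specimen directions).
    """

    orientations: Orientation
    phase: np.ndarray
    band_contrast: np.ndarray
    step: float
    phases: dict
    frame: dict = field(default_factory=lambda: dict(DEFAULT_FRAME))

    def __post_init__(self):
        self.phase = np.asarray(self.phase, dtype=int)
        self.band_contrast = np.asarray(self.band_contrast, dtype=float)
        if self.phase.shape != self.band_contrast.shape:
            raise ValueError("phase and band_contrast shapes differ")
        if len(self.orientations) != self.phase.size:
            raise ValueError("orientation count does not match raster size")

    @property
    def height(self) -> int:
        return self.phase.shape[0]

    @property
    def width(self) -> int:
        return self.phase.shape[1]

    @property
    def indexed(self) -> np.ndarray:
        """Boolean mask of indexed pixels, shape (height, width)."""
        return self.phase > 0

    @property
    def indexed_fraction(self) -> float:
        return float(self.indexed.mean())

    @property
    def area_um2(self) -> float:
        return self.width * self.height * self.step**2

    def indexed_orientations(self) -> Orientation:
        """Orientations of indexed pixels only (row-major order)."""
        return Orientation(self.orientations.quat[self.indexed.ravel()])

    def to_dataframe(self) -> pd.DataFrame:
        """Per-pixel table (x, y in pixels, Euler angles in degrees)."""
        yy, xx = np.mgrid[0:self.height, 0:self.width]
        eu = self.orientations.as_euler()
        return pd.DataFrame({
            "x": xx.ravel(), "y": yy.ravel(),
            "phase": self.phase.ravel(),
            "euler1": eu[:, 0], "euler2": eu[:, 1], "euler3": eu[:, 2],
            "band_contrast": self.band_contrast.ravel(),
            "indexed": self.indexed.ravel(),
        })


# ---------------------------------------------------------------------------
# CTF (Oxford/HKL Channel Text File)
# ---------------------------------------------------------------------------

_CTF_COLUMNS = ("Phase", "X", "Y", "Bands", "Error", "Euler1", "Euler2",
                "Euler3", "MAD", "BC", "BS")


def read_ctf(path) -> EBSDMap:
    """Read an Oxford Instruments Channel Text File.

    Header keys ``XCells``, ``YCells``, ``XStep`` and ``Phases`` are
    required; Euler angles are Bunge convention in degrees; phase 0 rows
    become non-indexed pixels.
    """
    header: dict = {}
    phases: dict = {}
    data_start = None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    if not lines or not lines[0].startswith("Channel Text File"):
        raise FormatError("not a Channel Text File (missing magic line)")
    while i < len(lines):
        line = lines[i].rstrip("\n")
        if line.startswith("Phase\t"):
            data_start = i + 1
            break
        parts = line.split("\t")
        key = parts[0].strip()
        if key in ("XCells", "YCells"):
            header[key] = int(float(parts[1]))
        elif key in ("XStep", "YStep"):
            header[key] = float(parts[1])
        elif key == "Phases":
            n_phases = int(parts[1])
            header["Phases"] = n_phases
            for p in range(1, n_phases + 1):
                phase_line = lines[i + p].rstrip("\n").split("\t")
                lat = [float(v) for v in phase_line[0].split(";")]
                name = phase_line[2] if len(phase_line) > 2 else f"phase{p}"
                phases[p] = CrystalSymmetry.hexagonal(
                    a=lat[0], c=lat[2], name=name)
            i += n_phases
        i += 1
    for key in ("XCells", "YCells", "XStep", "Phases"):
        if key not in header:
            raise FormatError(f"missing required CTF header key: {key}")
    if data_start is None:
        raise FormatError("missing CTF column header line (Phase\\tX\\tY...)")
    w, h = header["XCells"], header["YCells"]
    rows = np.loadtxt(lines[data_start:], ndmin=2)
    if rows.shape[0] != w * h:
        raise FormatError(
            f"truncated CTF: {rows.shape[0]} rows for {w}x{h} grid")
    phase = rows[:, 0].astype(int)
    euler = rows[:, 5:8]
    ori = Orientation.from_euler(euler)
    # placeholder identity for non-indexed pixels
    q = ori.quat.copy()
    q[phase == 0] = [1.0, 0.0, 0.0, 0.0]
    bc = rows[:, 9] if rows.shape[1] > 9 else np.zeros(w * h)
    return EBSDMap(
        orientations=Orientation(q),
        phase=phase.reshape(h, w),
        band_contrast=bc.reshape(h, w),
        step=header["XStep"],
        phases=phases or {1: CrystalSymmetry.hexagonal()},
    )


def write_ctf(emap: EBSDMap, path) -> None:
    """Write a map in CTF dialect (Euler degrees, 8 decimals)."""
    h, w = emap.height, emap.width
    eu = emap.orientations.as_euler()
    phase = emap.phase.ravel()
    eu = np.where(phase[:, None] == 0, 0.0, eu)
    bc = emap.band_contrast.ravel()
    with open(path, "w") as fh:
        fh.write("Channel Text File\n")
        fh.write("Prj\tbiotex synthetic map\n")
        fh.write("JobMode\tGrid\n")
        fh.write(f"XCells\t{w}\nYCells\t{h}\n")
        fh.write(f"XStep\t{emap.step:.4f}\nYStep\t{emap.step:.4f}\n")
        fh.write("AcqE1\t0\nAcqE2\t0\nAcqE3\t0\n")
        fh.write("Euler angles refer to Sample Coordinate system (CS0)!\n")
        fh.write(f"Phases\t{len(emap.phases)}\n")
        for pid in sorted(emap.phases):
            sym = emap.phases[pid]
            fh.write(f"{sym.a:.3f};{sym.a:.3f};{sym.c:.3f}\t"
                     f"90.000;90.000;120.000\t{sym.name}\t9\t194\n")
        fh.write("\t".join(_CTF_COLUMNS) + "\n")
        yy, xx = np.mgrid[0:h, 0:w]
        xs = xx.ravel() * emap.step
        ys = yy.ravel() * emap.step
        for k in range(h * w):
            fh.write(
                f"{phase[k]}\t{xs[k]:.4f}\t{ys[k]:.4f}\t6\t0\t"
                f"{eu[k, 0]:.8f}\t{eu[k, 1]:.8f}\t{eu[k, 2]:.8f}\t"
                f"0.5\t{bc[k]:.1f}\t255\n"
            )


# ---------------------------------------------------------------------------
# ANG (EDAX/TSL)
# ---------------------------------------------------------------------------

def read_ang(path) -> EBSDMap:
    """Read an EDAX/TSL ANG file (square grids only; Euler in radians).

    Rows with phase 0 (or confidence index < 0) become non-indexed pixels.
    """
    header_lines = []
    data_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line)
            elif line.strip():
                data_lines.append(line)
    header_text = "".join(header_lines)
    grid = re.search(r"GRID:\s*(\S+)", header_text)
    if grid and grid.group(1).lower() not in ("sqrgrid", "squaregrid"):
        raise FormatError(f"unsupported ANG grid type: {grid.group(1)!r} "
                          "(only square grids are supported)")
    ncols = re.search(r"NCOLS_ODD:\s*(\d+)", header_text)
    nrows = re.search(r"NROWS:\s*(\d+)", header_text)
    xstep = re.search(r"XSTEP:\s*([\d.eE+-]+)", header_text)
    for name, m in (("NCOLS_ODD", ncols), ("NROWS", nrows), ("XSTEP", xstep)):
        if m is None:
            raise FormatError(f"missing required ANG header key: {name}")
    w, h = int(ncols.group(1)), int(nrows.group(1))
    rows = np.loadtxt(data_lines, ndmin=2)
    if rows.shape[0] != w * h:
        raise FormatError(
            f"truncated ANG: {rows.shape[0]} rows for {w}x{h} grid")
    euler = np.degrees(rows[:, 0:3])
    ci = rows[:, 6]
    phase = rows[:, 7].astype(int)
    phase = np.where(ci < 0, 0, phase)
    ori = Orientation.from_euler(euler)
    q = ori.quat.copy()
    q[phase == 0] = [1.0, 0.0, 0.0, 0.0]
    iq = rows[:, 5]
    return EBSDMap(
        orientations=Orientation(q),
        phase=phase.reshape(h, w),
        band_contrast=iq.reshape(h, w),
        step=float(xstep.group(1)),
        phases={1: CrystalSymmetry.hexagonal()},
    )


def write_ang(emap: EBSDMap, path) -> None:
    """Write a map in the ANG dialect (Euler radians, square grid)."""
    h, w = emap.height, emap.width
    eu = np.radians(emap.orientations.as_euler())
    phase = emap.phase.ravel()
    eu = np.where(phase[:, None] == 0, 0.0, eu)
    iq = emap.band_contrast.ravel()
    ci = np.where(phase == 0, -1.0, 0.9)
    with open(path, "w") as fh:
        fh.write("# TEM_PIXperUM 1.000000\n")
        fh.write("# GRID: SqrGrid\n")
        fh.write(f"# XSTEP: {emap.step:.6f}\n")
        fh.write(f"# YSTEP: {emap.step:.6f}\n")
        fh.write(f"# NCOLS_ODD: {w}\n")
        fh.write(f"# NCOLS_EVEN: {w}\n")
        fh.write(f"# NROWS: {h}\n")
        yy, xx = np.mgrid[0:h, 0:w]
        xs = xx.ravel() * emap.step
        ys = yy.ravel() * emap.step
        for k in range(h * w):
            fh.write(
                f"{eu[k, 0]:.8f} {eu[k, 1]:.8f} {eu[k, 2]:.8f} "
                f"{xs[k]:.4f} {ys[k]:.4f} {iq[k]:.1f} {ci[k]:.1f} "
                f"{phase[k]} 1 1.0\n"
            )


# ---------------------------------------------------------------------------
# map operations
# ---------------------------------------------------------------------------

def merge_phases(emap: EBSDMap, from_id: int, to_id: int) -> EBSDMap:
    """Reassign all pixels of one phase to another (orientations untouched).

    Used to fold hydroxyapatite into apatite before texture analysis; both
    phases must be hexagonal with compatible symmetry (same group order).
    """
    if from_id not in emap.phases:
        return emap  # merging an absent phase is the identity
    if to_id not in emap.phases:
        raise ValueError(f"target phase {to_id} not present")
    if emap.phases[from_id].order != emap.phases[to_id].order:
        raise ValueError("incompatible crystal symmetry between phases")
    phase = np.where(emap.phase == from_id, to_id, emap.phase)
    phases = {pid: sym for pid, sym in emap.phases.items() if pid != from_id}
    return replace(emap, phase=phase, phases=phases)


def crop(emap: EBSDMap, x0: int, y0: int, w: int, h: int) -> EBSDMap:
    """Rectangular sub-map (no resampling; step and frame preserved)."""
    if w <= 0 or h <= 0:
        raise ValueError("crop extent must be positive")
    if x0 < 0 or y0 < 0 or x0 + w > emap.width or y0 + h > emap.height:
        raise ValueError("crop rectangle out of bounds")
    q = emap.orientations.quat.reshape(emap.height, emap.width, 4)
    sub = q[y0:y0 + h, x0:x0 + w].reshape(-1, 4)
    return replace(
        emap,
        orientations=Orientation(sub),
        phase=emap.phase[y0:y0 + h, x0:x0 + w].copy(),
        band_contrast=emap.band_contrast[y0:y0 + h, x0:x0 + w].copy(),
    )
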