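"""Raman ν1-PO4 band quantification and the model II regression screen.

The symmetric phosphate stretching band of apatite (near 964 cm⁻¹) is fit
with a pseudo-Voigt profile over a linear baseline,

    I(v) = A [ eta * L(v; v0, G) + (1 - eta) * G(v; v0, G) ] + b0 + b1 (v - m),

with a shared full width at half maximum G for the Lorentzian and Gaussian
parts.  The fitted center is the peak center at maximum intensity (PCMI);
both PCMI and FWHM shift with diagenetic substitution into the phosphate
site, so the PCMI-FWHM relationship across datasets acts as a diagenesis
screen.  Cross-dataset comparison uses ranged major axis (RMA) regression,
a model II method appropriate when both variables carry error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Model

__all__ = [
    "RamanSpectrum",
    "RamanPeakFit",
    "RegressionFit",
    "load_spectrum",
    "fit_v1_band",
    "rma_regression",
    "compare_slopes",
]


@dataclass
class RamanSpectrum:
    """A single spectrum: strictly increasing wavenumber vs intensity."""

    wavenumber: np.ndarray  # cm^-1, ascending
    intensity: np.ndarray   # arbitrary units
    specimen: str = ""
    position: int = 0

    def __post_init__(self):
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumber.shape != self.intensity.shape:
            raise ValueError("wavenumber and intensity lengths differ")
        if np.any(np.diff(self.wavenumber) <= 0):
            raise ValueError("wavenumber must be strictly increasing")


def load_spectrum(path, specimen: str = "", position: int = 0,
                  sep=None) -> RamanSpectrum:
    """Read a 2-column (wavenumber, intensity) CSV/TSV spectrum."""
    df = pd.read_csv(path, sep=sep, engine="python", comment="#",
                     header=None, names=["wavenumber", "intensity"])
    if isinstance(df.iloc[0, 0], str):  # header row present
        df = df.iloc[1:].astype(float)
    return RamanSpectrum(df["wavenumber"].to_numpy(float),
                         df["intensity"].to_numpy(float),
                         specimen=specimen, position=position)


@dataclass
class RamanPeakFit:
    """Pseudo-Voigt parameters of the ν1-PO4 band."""

    pcmi: float          # peak center at maximum intensity, cm^-1
    fwhm: float          # full width at half maximum, cm^-1
    eta: float           # Lorentzian mixing fraction in [0, 1]
    amplitude: float
    baseline: tuple      # (b0, b1) about the window midpoint
    residual_rms: float
    at_window_edge: bool = False


def _pseudo_voigt(x, amplitude, center, fwhm, eta, b0, b1, x_mid=0.0):
    half = fwhm / 2.0
    lor = 1.0 / (1.0 + ((x - center) / half) ** 2)
    gau = np.exp(-4.0 * np.log(2.0) * ((x - center) / fwhm) ** 2)
    return amplitude * (eta * lor + (1.0 - eta) * gau) + b0 + b1 * (x - x_mid)


def fit_v1_band(spectrum: RamanSpectrum,
                window=(940.0, 985.0)) -> RamanPeakFit:
    """Least-squares pseudo-Voigt + linear-baseline fit inside ``window``.

    Initialization is deterministic: center at the argmax, width from the
    half-maximum crossings, baseline from the window end points.  A peak
    center within one step of the window edge sets ``at_window_edge``.
    """
    lo, hi = window
    if lo < spectrum.wavenumber[0] or hi > spectrum.wavenumber[-1]:
        raise ValueError("fit window outside the spectrum range")
    sel = (spectrum.wavenumber >= lo) & (spectrum.wavenumber <= hi)
    x = spectrum.wavenumber[sel]
    y = spectrum.intensity[sel]
    if x.size < 50:
        raise ValueError("fewer than 50 points across the fit window")
    x_mid = 0.5 * (lo + hi)
    # deterministic initialization
    b0_init = 0.5 * (y[0] + y[-1])
    b1_init = (y[-1] - y[0]) / (x[-1] - x[0])
    resid = y - (b0_init + b1_init * (x - x_mid))
    i_max = int(np.argmax(resid))
    amp_init = max(resid[i_max], 1e-12)
    above = resid > amp_init / 2.0
    fwhm_init = max((above.sum()) * np.median(np.diff(x)), 3 * np.min(np.diff(x)))

    model = Model(_pseudo_voigt, independent_vars=["x"])
    params = model.make_params(
        amplitude=dict(value=amp_init, min=0.0),
        center=dict(value=float(x[i_max]), min=lo, max=hi),
        fwhm=dict(value=float(fwhm_init), min=1e-3, max=(hi - lo)),
        eta=dict(value=0.5, min=0.0, max=1.0),
        b0=b0_init,
        b1=b1_init,
        x_mid=x_mid,
    )
    params["x_mid"].set(vary=False)
    result = model.fit(y, params, x=x)
    rms = float(np.sqrt(np.mean(result.residual**2)))
    if not result.success:
        raise RuntimeError(
            f"pseudo-Voigt fit did not converge (residual rms {rms:.4g})")
    center = float(result.params["center"].value)
    edge_zone = max(2.0 * float(np.median(np.diff(x))),
                    0.02 * (hi - lo))
    return RamanPeakFit(
        pcmi=center,
        fwhm=float(result.params["fwhm"].value),
        eta=float(result.params["eta"].value),
        amplitude=float(result.params["amplitude"].value),
        baseline=(float(result.params["b0"].value),
                  float(result.params["b1"].value)),
        residual_rms=rms,
        at_window_edge=bool(center < lo + edge_zone
                            or center > hi - edge_zone),
    )


# ---------------------------------------------------------------------------
# ranged major axis regression (model II)
# ---------------------------------------------------------------------------

@dataclass
class RegressionFit:
    """Ranged major axis regression y = slope * x + intercept."""

    slope: float
    intercept: float
    r2: float
    n: int
    method: str = "ranged major axis"
    x: np.ndarray = field(default=None, repr=False)
    y: np.ndarray = field(default=None, repr=False)


def _ma_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Major-axis (first principal axis) slope of a scatter."""
    sxx = np.var(x)
    syy = np.var(y)
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    if sxy == 0:
        return 0.0
    return (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)


def rma_regression(x, y) -> RegressionFit:
    """Ranged major axis fit: major axis of range-rescaled data.

    x and y are rescaled by their observed ranges, the major-axis slope of
    the rescaled scatter is computed, and the slope is back-transformed by
    range(y) / range(x).  The line passes through the means; r² is the
    squared Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired observations")
    rx, ry = np.ptp(x), np.ptp(y)
    if rx == 0 or ry == 0:
        raise ValueError("zero range in x or y")
    slope = _ma_slope(x / rx, y / ry) * (ry / rx)
    intercept = y.mean() - slope * x.mean()
    r = np.corrcoef(x, y)[0, 1]
    return RegressionFit(slope=float(slope), intercept=float(intercept),
                         r2=float(r**2), n=int(x.size), x=x, y=y)


def compare_slopes(fit1: RegressionFit, fit2: RegressionFit,
                   alpha: float = 0.05, n_boot: int = 2000,
                   seed: int = 0) -> dict:
    """Bootstrap comparison of two RMA fits (slope and intercept).

    Case-resampling bootstrap (seeded) of each dataset; the difference is
    judged significant when the (1 - alpha) percentile interval of the
    bootstrap differences excludes 0.
    """
    if fit1.x is None or fit2.x is None:
        raise ValueError("fits must carry their data for resampling")
    rng = np.random.default_rng(seed)
    d_slope = np.empty(n_boot)
    d_int = np.empty(n_boot)
    for b in range(n_boot):
        i1 = rng.integers(0, fit1.n, fit1.n)
        i2 = rng.integers(0, fit2.n, fit2.n)
        try:
            f1 = rma_regression(fit1.x[i1], fit1.y[i1])
            f2 = rma_regression(fit2.x[i2], fit2.y[i2])
        except ValueError:       # degenerate resample
            d_slope[b] = np.nan
            d_int[b] = np.nan
            continue
        d_slope[b] = f1.slope - f2.slope
        d_int[b] = f1.intercept - f2.intercept
    qs = [100 * alpha / 2.0, 100 * (1 - alpha / 2.0)]
    s_lo, s_hi = np.nanpercentile(d_slope, qs)
    i_lo, i_hi = np.nanpercentile(d_int, qs)
    return {
        "slope_diff_ci": (float(s_lo), float(s_hi)),
        "intercept_diff_ci": (float(i_lo), float(i_hi)),
        "slopes_differ": bool(s_lo > 0 or s_hi < 0),
        "intercepts_differ": bool(i_lo > 0 or i_hi < 0),
        "alpha": alpha,
    }
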