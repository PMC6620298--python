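"""Undulation-wavelength extraction from sampled beam centerlines.

Buckled beams are observed as 2D projections; a centerline is the sampled
lateral deflection x(z) along the print axis z.  Two independent
estimators extract the dominant undulation wavelength:

* a spectral route — linear detrend, Hann window, periodogram, dominant
  nonzero-frequency peak refined by three-point parabolic interpolation
  in log power;
* a real-space route — mean spacing of consecutive zero crossings of the
  detrended (and lightly smoothed) signal, times two.

Their agreement on the same centerline is the internal consistency check
for the measurement.  Measured wavelengths are regressed against the
beam-theory prediction 2 pi (E I / G')^(1/4) to test the mechanics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.signal import periodogram

from .errors import NoUndulationError, ValidationError

__all__ = [
    "Centerline",
    "RegressionReport",
    "measure_wavelength_fft",
    "measure_wavelength_peaks",
    "regress_lambda",
]

MIN_SAMPLES = 16
SPACING_RTOL = 1e-9
FLAT_VARIANCE = 1e-30  # m^2; below this the line is considered flat
SMOOTH_WINDOW = 5      # samples, moving average before zero-crossing count


@dataclass(frozen=True)
class Centerline:
    """Uniformly sampled 2D beam centerline in meters.

    ``z`` is the axial coordinate (strictly increasing, uniform spacing);
    ``x`` is the lateral deflection at each z.
    """

    z: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "x", x)
        if z.ndim != 1 or x.ndim != 1 or z.size != x.size:
            raise ValidationError("z and x must be 1-D arrays of equal length")
        if z.size < MIN_SAMPLES:
            raise ValidationError(
                f"centerline needs >= {MIN_SAMPLES} samples, got {z.size}"
            )
        if not (np.all(np.isfinite(z)) and np.all(np.isfinite(x))):
            raise ValidationError("centerline contains non-finite values")
        dz = np.diff(z)
        if np.any(dz <= 0):
            raise ValidationError("z must be strictly increasing")
        if np.max(np.abs(dz - dz[0])) > SPACING_RTOL * abs(dz[0]):
            raise ValidationError("z spacing must be uniform")

    @property
    def spacing(self) -> float:
        return float(self.z[1] - self.z[0])

    def detrended(self) -> np.ndarray:
        """Deflection with the OLS best-fit line removed (tilt + offset)."""
        coeffs = np.polyfit(self.z, self.x, 1)
        return self.x - np.polyval(coeffs, self.z)


@dataclass(frozen=True)
class RegressionReport:
    """OLS of measured wavelength on the beam-theory prediction."""

    slope: float
    intercept: float    # m
    r_squared: float
    n: int

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps({"slope": d["slope"], "intercept_m": d["intercept"],
                           "r_squared": d["r_squared"], "n": d["n"]})


# ---------------------------------------------------------------------------
# Spectral estimator
# ---------------------------------------------------------------------------

def measure_wavelength_fft(cl: Centerline) -> float:
    """Dominant undulation wavelength by windowed periodogram, m.

    Linear detrend, Hann window, periodogram; the dominant nonzero-
    frequency bin is refined by three-point parabolic interpolation in
    log power, which removes most of the bin-quantisation error for
    records holding a few periods or more.
    """
    y = cl.detrended()
    if float(np.var(y)) < FLAT_VARIANCE:
        raise NoUndulationError("centerline is flat; no undulation to measure")
    freqs, power = periodogram(y, fs=1.0 / cl.spacing, window="hann",
                               detrend=False)
    # skip the DC bin
    k = 1 + int(np.argmax(power[1:]))
    if power[k] <= 0:
        raise NoUndulationError("no spectral peak above DC")
    # three-point parabolic refinement in log power
    if 1 <= k - 1 and k + 1 < power.size and power[k - 1] > 0 and power[k + 1] > 0:
        la, lb, lc = (math.log(power[k - 1]), math.log(power[k]),
                      math.log(power[k + 1]))
        denom = la - 2.0 * lb + lc
        delta = 0.0 if denom == 0 else 0.5 * (la - lc) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    df = freqs[1] - freqs[0]
    f_peak = freqs[k] + delta * df
    if f_peak <= 0:
        raise NoUndulationError("spectral peak at non-positive frequency")
    return 1.0 / float(f_peak)


# ---------------------------------------------------------------------------
# Real-space estimator
# ---------------------------------------------------------------------------

def measure_wavelength_peaks(cl: Centerline) -> float:
    """Wavelength from zero-crossing spacing of the detrended signal, m.

    The detrended deflection is smoothed with a short moving average to
    suppress sample-level noise, its zero crossings are located by linear
    interpolation, and twice the mean spacing of consecutive crossings is
    returned (a half period separates successive crossings).
    """
    y = cl.detrended()
    if float(np.var(y)) < FLAT_VARIANCE:
        raise NoUndulationError("centerline is flat; no undulation to measure")
    kernel = np.ones(SMOOTH_WINDOW) / SMOOTH_WINDOW
    ys = np.convolve(y, kernel, mode="same")
    s = np.sign(ys)
    # treat exact zeros as the sign of the next nonzero sample
    for i in range(s.size - 2, -1, -1):
        if s[i] == 0:
            s[i] = s[i + 1]
    idx = np.nonzero(s[:-1] * s[1:] < 0)[0]
    if idx.size < 2:
        raise NoUndulationError("fewer than two zero crossings; no undulation")
    # linear interpolation of each crossing position
    z0 = list(cl.z[idx] - ys[idx] * (cl.z[idx + 1] - cl.z[idx])
              / (ys[idx + 1] - ys[idx]))
    # noise blips near the baseline add crossings in close pairs; strip the
    # tightest pair until no spacing is far below the median half-period
    while len(z0) >= 4:
        spacings = np.diff(z0)
        k = int(np.argmin(spacings))
        if spacings[k] >= 0.25 * float(np.median(spacings)):
            break
        del z0[k:k + 2]
    if len(z0) < 2:
        raise NoUndulationError("fewer than two zero crossings; no undulation")
    spacings = np.diff(z0)
    return 2.0 * float(np.mean(spacings))


# ---------------------------------------------------------------------------
# Measured-vs-predicted regression
# ---------------------------------------------------------------------------

def regress_lambda(measured: Sequence[float],
                   predicted: Sequence[float]) -> RegressionReport:
    """OLS of measured wavelengths on beam-theory predictions.

    Beam theory passes when the slope is near 1 with high R^2; the report
    leaves that judgement to the caller.
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape or m.ndim != 1:
        raise ValidationError("measured and predicted must be equal-length 1-D")
    if m.size < 2:
        raise ValidationError(f"regression needs >= 2 points, got {m.size}")
    if np.any(m <= 0) or np.any(p <= 0):
        raise ValidationError("wavelengths must be positive")
    res = stats.linregress(p, m)
    return RegressionReport(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        n=int(m.size),
    )
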