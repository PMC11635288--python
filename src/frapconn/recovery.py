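"""Normalization and single-exponential fitting of FRAP recovery curves.

The raw ROI trace is normalized to the mean of the pre-bleach frames
(pre-bleach level == 1), the bleach frame is discarded, and time is reset so
t = 0 at the first post-bleach frame.  Recovery is modelled as

    I(t) = I0 + (Iinf - I0) * (1 - exp(-k t))

fit by bounded least squares; the half-time is t_half = ln2 / k and the
mobile fraction is (Iinf - I0) / (1 - I0), i.e. the recovered amplitude as a
fraction of the bleached-away signal relative to the pre-bleach level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .series_io import FrapSeries, IntensityTrace

__all__ = ["RecoveryCurve", "FitResult", "build_curve", "fit_single_exponential"]

_K_BOUNDS = (1e-4, 1e3)  # 1/s


@dataclass
class RecoveryCurve:
    """Post-bleach trace normalized to the pre-bleach level."""

    times_s: np.ndarray  # t = 0 at the first post-bleach frame
    normalized_intensity: np.ndarray
    i_pre: float  # pre-bleach mean in raw units
    i_bleach: float  # first post-bleach value, normalized
    n_pre_frames_used: int

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.normalized_intensity = np.asarray(self.normalized_intensity, dtype=float)
        if self.times_s[0] != 0 or np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must start at 0 and increase")


@dataclass
class FitResult:
    """Single-exponential recovery parameters.

    ``t_half_s`` and ``mobile_fraction`` are ``None`` when the optimizer did
    not converge (``converged=False``); downstream classification treats such
    fits as non-recovering.
    """

    rate_k: float | None
    t_half_s: float | None
    plateau: float | None  # Iinf, normalized
    floor: float | None  # I0, normalized
    mobile_fraction: float | None
    r_squared: float | None
    converged: bool


def build_curve(trace: IntensityTrace, series: FrapSeries) -> RecoveryCurve:
    """Normalize a ROI trace into a recovery curve.

    Divides by the mean over all pre-bleach frames, drops the bleach frame,
    and shifts time so the first post-bleach frame is t = 0.
    """
    if len(trace.values) != series.n_frames:
        raise ValueError("trace length does not match series frame count")
    pre = series.pre_bleach_indices
    post = series.post_bleach_indices
    if len(pre) < 1:
        raise ValueError("need >= 1 pre-bleach frame")
    if len(post) < 5:
        raise ValueError(f"need >= 5 post-bleach frames, got {len(post)}")
    i_pre = float(trace.values[pre].mean())
    if i_pre <= 0:
        raise ValueError("pre-bleach mean intensity must be > 0")
    norm = trace.values[post] / i_pre
    times = series.timestamps_s[post] - series.timestamps_s[post[0]]
    return RecoveryCurve(
        times_s=times,
        normalized_intensity=norm,
        i_pre=i_pre,
        i_bleach=float(norm[0]),
        n_pre_frames_used=len(pre),
    )


def _model(t, i0, iinf, k):
    return i0 + (iinf - i0) * (1.0 - np.exp(-k * t))


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    i0 = float(y[0])
    tail = max(int(round(0.1 * len(y))), 1)
    iinf = float(y[-tail:].mean())
    half_level = i0 + 0.5 * (iinf - i0)
    if iinf > i0:
        above = np.nonzero(y >= half_level)[0]
        t_half_guess = float(t[above[0]]) if len(above) and t[above[0]] > 0 else float(t[-1]) / 2
    else:
        t_half_guess = float(t[-1]) / 2
    k0 = np.log(2) / max(t_half_guess, 1e-6)
    return i0, iinf, float(np.clip(k0, *_K_BOUNDS))


def fit_single_exponential(curve: RecoveryCurve) -> FitResult:
    """Least-squares fit of the single-exponential recovery model.

    Returns ``converged=False`` (with absent half-time and mobile fraction)
    when the optimizer fails; a flat curve fits with near-zero amplitude and
    is classified downstream as no recovery.
    """
    t = curve.times_s
    y = curve.normalized_intensity
    if len(np.unique(t)) < 3:
        raise ValueError("need >= 3 distinct post-bleach time points")

    p0 = _initial_guess(t, y)
    lo = [-0.5, -0.5, _K_BOUNDS[0]]
    hi = [2.0, 2.0, _K_BOUNDS[1]]
    p0 = tuple(np.clip(p0, lo, hi))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _model, t, y, p0=p0, bounds=(lo, hi), maxfev=20000
            )
    except (RuntimeError, ValueError):
        return FitResult(None, None, None, None, None, None, converged=False)

    i0, iinf, k = (float(v) for v in popt)
    if k <= 0:
        return FitResult(None, None, None, None, None, None, converged=False)
    resid = y - _model(t, *popt)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    denom = 1.0 - i0  # pre-bleach level is 1 after normalization
    mobile = (iinf - i0) / denom if abs(denom) > 1e-12 else 0.0
    return FitResult(
        rate_k=k,
        t_half_s=float(np.log(2) / k),
        plateau=iinf,
        floor=i0,
        mobile_fraction=float(mobile),
        r_squared=r2,
        converged=True,
    )
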