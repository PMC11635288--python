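"""Connectivity classification and the Connectivity Index (CI).

Two complementary read-outs of vacuolar lumen connectivity:

* **Recovery classes** — a fitted recovery curve is binned by half-time into
  ``fast`` (t1/2 < 2 s), ``medium`` (2 s <= t1/2 < 5 s) and ``slow``
  (t1/2 >= 5 s); measurements with a mobile fraction below 30% (or a failed
  fit) are ``no_recovery``.

* **Connectivity Index** — for vacuoles too small and motile for curve
  fitting, only the frames immediately before (Frame -1) and after (Frame 1)
  the bleach are compared.  With the fractional intensity changes dI of the
  bleached area ``a``, a distant area ``b`` of the same vacuole, and a
  control area ``c`` in a neighboring cell:

      Rel = dI_a - dI_b      (loss difference within the vacuole)
      Ref = dI_a - dI_c      (loss difference across disconnected vacuoles)
      CI  = (Ref - Rel) / Ref

  CI = 1 means a and b are fully connected and mix faster than the frame
  rate; CI = 0 means no exchange.  CI outside [0, 1] indicates a technical
  problem (typically sample drift) and is flagged, not silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .recovery import FitResult
from .series_io import FrapSeries, RoiSet, extract_intensity

__all__ = [
    "ConnectivityClass",
    "CiInputs",
    "CiResult",
    "CutoffResult",
    "classify_recovery",
    "delta_intensity",
    "compute_ci",
    "ci_from_series",
    "calibrate_cutoff",
    "DEFAULT_CI_CUTOFF",
    "MOBILE_FRACTION_MIN",
    "FAST_MAX_S",
    "MEDIUM_MAX_S",
]

DEFAULT_CI_CUTOFF = 0.1
MOBILE_FRACTION_MIN = 0.30  # below this: no recovery
FAST_MAX_S = 2.0  # t1/2 < 2 s: fast
MEDIUM_MAX_S = 5.0  # 2 <= t1/2 < 5 s: medium; >= 5 s: slow
DEFAULT_WEAK_BLEACH_FLOOR = 10.0  # percentage points of |dI_a|


class ConnectivityClass(str, Enum):
    FAST = "fast"
    MEDIUM = "medium"
    SLOW = "slow"
    NO_RECOVERY = "no_recovery"


def classify_recovery(fit: FitResult) -> ConnectivityClass:
    """Bin a recovery fit into the four connectivity classes.

    Boundary semantics are strict: t1/2 = 2 s is medium, t1/2 = 5 s is slow,
    and a mobile fraction of exactly 30% still counts as recovering (only
    fractions strictly below 30% are non-recovering).
    """
    if (
        not fit.converged
        or fit.mobile_fraction is None
        or fit.t_half_s is None
        or fit.mobile_fraction < MOBILE_FRACTION_MIN
    ):
        return ConnectivityClass.NO_RECOVERY
    if fit.t_half_s < FAST_MAX_S:
        return ConnectivityClass.FAST
    if fit.t_half_s < MEDIUM_MAX_S:
        return ConnectivityClass.MEDIUM
    return ConnectivityClass.SLOW


# ---------------------------------------------------------------------------
# Connectivity Index
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CiInputs:
    """Mean ROI intensities at Frame -1 (pre) and Frame 1 (post), a.u."""

    i_a_pre: float
    i_a_post: float
    i_b_pre: float
    i_b_post: float
    i_c_pre: float
    i_c_post: float

    def __post_init__(self) -> None:
        for name in ("i_a_pre", "i_b_pre", "i_c_pre"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("i_a_post", "i_b_post", "i_c_post"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CiResult:
    """The dI -> Rel -> Ref -> CI chain with a QC verdict.

    ``qc_flag`` is ``ok`` when 0 <= ci <= 1 and the bleach was strong enough;
    ``drift_negative`` / ``drift_above_one`` mark CI outside [0, 1] (the
    non-bleached area gained or lost more than physically consistent, usually
    sample drift); ``weak_bleach`` marks a bleached-area drop too shallow to
    quantify.  Flagged results keep their CI value but are excluded from
    summaries by default.
    """

    dI_a: float
    dI_b: float
    dI_c: float
    rel: float
    ref: float
    ci: float
    qc_flag: str  # ok | drift_negative | drift_above_one | weak_bleach

    @property
    def qc_ok(self) -> bool:
        return self.qc_flag == "ok"


def delta_intensity(pre: float, post: float, denominator: str = "pre_frame") -> float:
    """Percent intensity change between Frame -1 and Frame 1.

    ``denominator="pre_frame"`` expresses the change as a percentage of the
    pre-bleach intensity (the percent reading of "% of this area intensity
    before photobleaching"); ``"post_frame"`` divides by the post-bleach
    intensity instead.
    """
    if denominator == "pre_frame":
        den = pre
    elif denominator == "post_frame":
        den = post
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if den == 0:
        raise ZeroDivisionError("zero denominator in delta_intensity")
    return (post - pre) * 100.0 / den


def compute_ci(
    inputs: CiInputs,
    denominator: str = "pre_frame",
    weak_bleach_floor: float = DEFAULT_WEAK_BLEACH_FLOOR,
) -> CiResult:
    """Evaluate the full CI chain with QC.

    Raises when Ref is zero (no measurable bleach contrast against the
    neighbor-cell control).  A bleached-area drop shallower than
    ``weak_bleach_floor`` percentage points (including an intensity *gain*,
    e.g. swapped frames) is flagged ``weak_bleach``.
    """
    d_a = delta_intensity(inputs.i_a_pre, inputs.i_a_post, denominator)
    d_b = delta_intensity(inputs.i_b_pre, inputs.i_b_post, denominator)
    d_c = delta_intensity(inputs.i_c_pre, inputs.i_c_post, denominator)
    rel = d_a - d_b
    ref = d_a - d_c
    if ref == 0:
        raise ValueError("Ref = 0: no measurable bleach contrast")
    ci = (ref - rel) / ref

    if d_a > -weak_bleach_floor:
        flag = "weak_bleach"
    elif ci < 0:
        flag = "drift_negative"
    elif ci > 1:
        flag = "drift_above_one"
    else:
        flag = "ok"
    return CiResult(dI_a=d_a, dI_b=d_b, dI_c=d_c, rel=rel, ref=ref, ci=ci, qc_flag=flag)


def ci_from_series(
    series: FrapSeries,
    rois: RoiSet,
    denominator: str = "pre_frame",
    pre_frame_mode: str = "single",
    weak_bleach_floor: float = DEFAULT_WEAK_BLEACH_FLOOR,
) -> CiResult:
    """Compute the CI of a FRAP series from its a/b/c measurement areas.

    Frame -1 is the single last pre-bleach frame by default
    (``pre_frame_mode="single"``); ``"mean"`` averages all pre-bleach frames
    instead, which is more robust to noise but deviates from the two-frame
    definition.  Frame 1 is always the first post-bleach frame.
    """
    for name in ("a", "b", "c"):
        if name not in rois:
            raise KeyError(f"RoiSet is missing region {name!r}")
    if pre_frame_mode not in ("single", "mean"):
        raise ValueError(f"unknown pre_frame_mode {pre_frame_mode!r}")

    pre_idx = series.frame_minus_1
    post_idx = series.frame_plus_1
    vals = {}
    for name in ("a", "b", "c"):
        trace = extract_intensity(series, rois[name], region_name=name)
        if pre_frame_mode == "single":
            pre = float(trace.values[pre_idx])
        else:
            pre = float(trace.values[series.pre_bleach_indices].mean())
        vals[name] = (pre, float(trace.values[post_idx]))

    inputs = CiInputs(
        i_a_pre=vals["a"][0],
        i_a_post=vals["a"][1],
        i_b_pre=vals["b"][0],
        i_b_post=vals["b"][1],
        i_c_pre=vals["c"][0],
        i_c_post=vals["c"][1],
    )
    return compute_ci(inputs, denominator=denominator, weak_bleach_floor=weak_bleach_floor)


# ---------------------------------------------------------------------------
# empirical cut-off calibration
# ---------------------------------------------------------------------------


@dataclass
class CutoffResult:
    cutoff: float
    positives: np.ndarray
    negatives: np.ndarray
    alpha: float
    separable: bool


def calibrate_cutoff(
    positive_cis, negative_cis, alpha: float = 0.05
) -> CutoffResult:
    """Estimate the CI cut-off separating connected from disconnected.

    The cut-off is the (1 - alpha) quantile of the negative-control CIs
    (disconnected vacuoles, e.g. neighbor-cell measurements); positives are
    connected controls.  Only QC-passing values should be passed in.  When
    the cut-off reaches the median of the positives the controls are not
    separable and a warning is raised; the pipeline default cut-off (0.1)
    should then be kept.
    """
    pos = np.asarray(list(positive_cis), dtype=float)
    neg = np.asarray(list(negative_cis), dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both control lists must be non-empty")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    cutoff = float(np.quantile(neg, 1.0 - alpha))
    separable = cutoff < float(np.median(pos))
    if not separable:
        warnings.warn(
            "controls not separable: negative-control quantile reaches the "
            "median of the positive controls",
            stacklevel=2,
        )
    return CutoffResult(
        cutoff=cutoff, positives=pos, negatives=neg, alpha=alpha, separable=separable
    )
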