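"""Per-tumor growth rates and the rate-based tumor/control (RTC) response statistic.

The response metric assumes exponential tumor growth: a straight line is fit
to log10 tumor volume against day for each mouse, restricted to measurements
on/after the first dosing day and above the detection limit.  A treated
mouse's growth inhibition is summarized as

    RTC_i = 10 ** ((b_i - mu_C) * rtc_scale_days)

where ``b_i`` is the mouse's log10-volume slope and ``mu_C`` the mean slope
of the same line's control arm, i.e. the fold-change in final volume relative
to the control-arm expectation over a fixed horizon (21 days by default).
RTC < 1 indicates inhibition.  Tumors that regressed to zero after a single
detectable measurement cannot be fit but clearly responded; they receive the
arm-wise 10th-quantile slope.  Tumors that never grew at all (CR*) carry no
usable slope and are instead captured by an exact-binomial enrichment test
per line, whose approximate Z-score is blended with the line's mean log RTC
into a weighted combined trait (80% RTC, 20% CR*).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .config import StudyConfig
from .errors import DegenerateDataError, ImputationError, ValidationError
from .io import GrowthSeries

__all__ = [
    "SlopeEstimate",
    "RTCValue",
    "ResponseClass",
    "fit_log_slope",
    "impute_regressed_slopes",
    "per_mouse_rtc",
    "classify_response",
    "crstar_enrichment_test",
    "combined_response_trait",
    "rtc_table",
    "line_summaries",
]


class ResponseClass(str, Enum):
    """Discrete response categories, ordered from worst to best."""

    non_responder = "non_responder"
    partial_responder = "partial_responder"
    CR = "CR"
    CR_star = "CR_star"

    @property
    def ordinal(self) -> int:
        return ("non_responder", "partial_responder", "CR", "CR_star").index(
            self.value
        )


class SlopeFlag(str, Enum):
    fitted = "fitted"
    imputed_regressed = "imputed_regressed"
    insufficient = "insufficient"


@dataclass
class SlopeEstimate:
    mouse_id: str
    line_id: str
    arm: str
    slope: float  # log10(mm^3) per day; NaN when insufficient
    n_points_used: int
    flag: SlopeFlag


@dataclass
class RTCValue:
    mouse_id: str
    rtc: float
    log_rtc: float
    mu_c: float


def _usable_mask(series: GrowthSeries, config: StudyConfig) -> np.ndarray:
    return (series.days >= config.start_day) & (
        series.volumes >= config.detection_limit
    )


def fit_log_slope(series: GrowthSeries, config: StudyConfig) -> SlopeEstimate:
    """OLS slope of log10(volume) on day.

    Only measurements with ``day >= start_day`` and
    ``volume >= detection_limit`` enter the fit (log of a censored volume is
    undefined).  With fewer than two usable points the estimate is flagged
    ``insufficient`` and the slope is NaN; such series may later qualify for
    quantile imputation (see :func:`impute_regressed_slopes`).
    """
    mask = _usable_mask(series, config)
    n = int(mask.sum())
    if n < 2:
        return SlopeEstimate(
            series.mouse_id, series.line_id, series.arm, math.nan, n,
            SlopeFlag.insufficient,
        )
    x = series.days[mask].astype(float)
    y = np.log10(series.volumes[mask])
    xc = x - x.mean()
    slope = float(xc @ (y - y.mean()) / (xc @ xc))
    return SlopeEstimate(
        series.mouse_id, series.line_id, series.arm, slope, n, SlopeFlag.fitted
    )


def is_regression_pattern(series: GrowthSeries, config: StudyConfig) -> bool:
    """True for tumors that grew once then regressed below detection.

    Qualifying rule: among measurements on/after ``start_day``, exactly one is
    at/above the detection limit and at least one later measurement (all of
    which are sub-limit) exists.
    """
    post = series.days >= config.start_day
    vols = series.volumes[post]
    detected = vols >= config.detection_limit
    if detected.sum() != 1:
        return False
    return int(np.argmax(detected)) < vols.size - 1


def impute_regressed_slopes(
    slopes: list[SlopeEstimate],
    series_by_mouse: dict[str, GrowthSeries],
    config: StudyConfig,
) -> list[SlopeEstimate]:
    """Assign the arm-wise 10th-quantile slope to grew-then-regressed tumors.

    The quantile is computed over fitted slopes separately within each
    treatment arm (linear interpolation between order statistics,
    ``h = (n-1)p + 1``).  Returns a new list; non-qualifying estimates are
    passed through unchanged.

    Raises
    ------
    ImputationError
        If a qualifying mouse sits in an arm with zero fitted slopes.
    """
    q = config.quantile_for_imputation
    arm_fitted: dict[str, list[float]] = {}
    for s in slopes:
        if s.flag is SlopeFlag.fitted:
            arm_fitted.setdefault(s.arm, []).append(s.slope)

    out: list[SlopeEstimate] = []
    for s in slopes:
        if s.flag is SlopeFlag.insufficient and is_regression_pattern(
            series_by_mouse[s.mouse_id], config
        ):
            pool = arm_fitted.get(s.arm, [])
            if not pool:
                raise ImputationError(
                    f"cannot impute slope for mouse {s.mouse_id}: no fitted "
                    f"slopes in arm {s.arm!r}"
                )
            slope = float(np.quantile(pool, q))  # linear interpolation
            out.append(
                SlopeEstimate(
                    s.mouse_id, s.line_id, s.arm, slope, s.n_points_used,
                    SlopeFlag.imputed_regressed,
                )
            )
        else:
            out.append(s)
    return out


def per_mouse_rtc(b_i: float, mu_c: float, config: StudyConfig) -> RTCValue:
    """RTC_i = 10**((b_i - mu_C) * rtc_scale_days); log_rtc stored alongside."""
    if not (math.isfinite(b_i) and math.isfinite(mu_c)):
        raise ValidationError("per_mouse_rtc requires finite slopes")
    log_rtc = (b_i - mu_c) * config.rtc_scale_days
    return RTCValue("", 10.0 ** log_rtc, log_rtc, mu_c)


def classify_response(series: GrowthSeries, config: StudyConfig) -> ResponseClass:
    """Discrete response class from the post-dosing trajectory.

    CR*: never detectable from ``start_day`` onward.  CR: detectable at some
    point but below the limit at the final measurement.  Partial responder:
    final volume below the first post-dosing volume yet still detectable.
    Non-responder otherwise.
    """
    post = series.days >= config.start_day
    if not post.any():
        raise ValidationError(
            f"mouse {series.mouse_id} has no measurement on/after day "
            f"{config.start_day}"
        )
    vols = series.volumes[post]
    limit = config.detection_limit
    if np.all(vols < limit):
        return ResponseClass.CR_star
    if vols[-1] < limit:
        return ResponseClass.CR
    if vols[-1] < vols[0]:
        return ResponseClass.partial_responder
    return ResponseClass.non_responder


def crstar_enrichment_test(
    k_treated: int,
    n_treated: int,
    k_control: int,
    n_control: int,
    pooled_control: tuple[int, int] | None = None,
) -> tuple[float, float]:
    """Exact-binomial enrichment of never-grew (CR*) tumors in the treated arm.

    The null CR* rate ``p0`` is the line's control-arm CR* fraction; when that
    fraction is 0 or 1 the pooled control fraction across all lines is
    substituted with add-one smoothing ``(k+1)/(n+2)``.  Returns the
    upper-tail exact p-value ``P(X >= k_treated | n_treated, p0)`` and the
    large-sample Z approximation ``(k - n p0) / sqrt(n p0 (1 - p0))``.
    """
    if n_treated < 1:
        raise ValidationError("crstar_enrichment_test requires a treated arm")
    p0 = k_control / n_control if n_control > 0 else 0.0
    if p0 in (0.0, 1.0):
        kp, np_ = pooled_control if pooled_control is not None else (
            k_control, n_control
        )
        p0 = (kp + 1) / (np_ + 2)
    p_exact = float(stats.binom.sf(k_treated - 1, n_treated, p0))
    z = (k_treated - n_treated * p0) / math.sqrt(
        n_treated * p0 * (1.0 - p0)
    )
    return p_exact, float(z)


def _standardize(x: np.ndarray) -> np.ndarray:
    # A constant component carries no information across lines; its Z-score
    # vector is defined as 0 so the other component decides the trait.
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def combined_response_trait(
    mean_log_rtc: np.ndarray, crstar_z: np.ndarray, config: StudyConfig
) -> np.ndarray:
    """Weighted blend of the RTC and CR*-enrichment components across lines.

    Both inputs are standardized across lines; the CR* component is
    subtracted so that smaller combined values mean stronger response, the
    polarity of log RTC.  ``combined = w_rtc * Z(mean_log_rtc)
    - w_crstar * Z(crstar_z)``.
    """
    mean_log_rtc = np.asarray(mean_log_rtc, dtype=float)
    crstar_z = np.asarray(crstar_z, dtype=float)
    if mean_log_rtc.size < 2:
        raise DegenerateDataError(
            "combined trait needs at least 2 lines to standardize across"
        )
    return config.w_rtc * _standardize(mean_log_rtc) - config.w_crstar * (
        _standardize(crstar_z)
    )


# ---------------------------------------------------------------------------
# Pipeline drivers

def rtc_table(series: list[GrowthSeries], config: StudyConfig) -> pd.DataFrame:
    """Full per-mouse stage: slopes, imputation, RTC and response class.

    ``mu_C`` for a line is the mean over its control-arm fitted and imputed
    slopes.  Mice without a usable slope (CR* and other insufficient series)
    keep NaN slope/RTC; their response class still records them.
    """
    by_mouse = {s.mouse_id: s for s in series}
    slopes = [fit_log_slope(s, config) for s in series]
    slopes = impute_regressed_slopes(slopes, by_mouse, config)
    slope_by_mouse = {s.mouse_id: s for s in slopes}

    mu_c: dict[str, float] = {}
    for line in sorted({s.line_id for s in series}):
        ctrl = [
            s.slope
            for s in slopes
            if s.line_id == line
            and s.arm == "control"
            and s.flag is not SlopeFlag.insufficient
        ]
        mu_c[line] = float(np.mean(ctrl)) if ctrl else math.nan

    rows = []
    for s in series:
        est = slope_by_mouse[s.mouse_id]
        cls = classify_response(s, config)
        if math.isfinite(est.slope) and math.isfinite(mu_c[s.line_id]):
            val = per_mouse_rtc(est.slope, mu_c[s.line_id], config)
            rtc, log_rtc = val.rtc, val.log_rtc
        else:
            rtc = log_rtc = math.nan
        rows.append(
            (
                s.mouse_id, s.line_id, s.arm, est.slope, est.n_points_used,
                est.flag.value, mu_c[s.line_id], rtc, log_rtc, cls.value,
                cls.ordinal,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mouse_id", "line_id", "arm", "slope", "n_points_used", "flag",
            "mu_c", "rtc", "log_rtc", "response_class", "response_ordinal",
        ],
    )


def line_summaries(per_mouse: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Per-line summary: mean log RTC (treated arm), CR* counts/test, combined trait.

    The pooled control CR* fraction across all lines backs the smoothed null
    rate whenever a line's own control fraction is degenerate.
    """
    is_crstar = per_mouse["response_class"] == ResponseClass.CR_star.value
    ctrl = per_mouse["arm"] == "control"
    pooled = (int(is_crstar[ctrl].sum()), int(ctrl.sum()))

    rows = []
    for line, grp in per_mouse.groupby("line_id", sort=True):
        tre = grp[grp["arm"] == "treated"]
        con = grp[grp["arm"] == "control"]
        k_t = int((tre["response_class"] == ResponseClass.CR_star.value).sum())
        k_c = int((con["response_class"] == ResponseClass.CR_star.value).sum())
        mean_log_rtc = float(tre["log_rtc"].mean())
        if len(tre) >= 1:
            p_exact, z = crstar_enrichment_test(
                k_t, len(tre), k_c, len(con), pooled_control=pooled
            )
        else:
            p_exact, z = math.nan, math.nan
        rows.append(
            (line, mean_log_rtc, len(con), len(tre), k_c, k_t, p_exact, z)
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "line_id", "mean_log_rtc", "n_control", "n_treated",
            "crstar_control", "crstar_treated", "crstar_p", "crstar_z",
        ],
    )
    if len(out) >= 2 and out["mean_log_rtc"].notna().all():
        out["combined_z"] = combined_response_trait(
            out["mean_log_rtc"].to_numpy(), out["crstar_z"].to_numpy(), config
        )
    else:
        out["combined_z"] = math.nan
    return out
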