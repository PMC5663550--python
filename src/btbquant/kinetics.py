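"""In-vitro barrier-chip uptake kinetics.

The chip experiment perfuses fluorescent antibody through the outer
(vascular) compartment and images both compartments every few minutes.
Under unidirectional uptake the compartment sum-intensity ratio

    (C_CC + C_PF) / C_PF  =  k_in * t  +  O_C

is linear in perfusion time ``t`` measured from steady-state onset, with
slope ``k_in`` (the unidirectional uptake transfer constant, 1/min on the
ratio scale) and intercept ``O_C`` (the effective outer-compartment
volume term).  This module extracts ROI traces from image stacks, builds
the ratio series, trims the pre-steady-state frames, and estimates
``k_in`` by ordinary least squares, following the statsmodels convention
of a model object whose :meth:`UptakeKinetics.fit` returns a results
object (:class:`KinEstimate`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats

from .exceptions import (
    ComputationError,
    DegenerateInputError,
    InputError,
    InsufficientDataError,
)

__all__ = [
    "RoiTrace",
    "RatioSeries",
    "KinEstimate",
    "GroupComparison",
    "UptakeKinetics",
    "extract_roi_traces",
    "uptake_ratio",
    "trim_to_steady_state",
    "fit_kin",
    "estimate_steady_state_delay",
    "compare_groups",
]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class RoiTrace:
    """Paired compartment sum-intensity series for one chip.

    ``c_pf`` is the outer-compartment (perfused) ROI sum per frame,
    ``c_cc`` the central-compartment ROI sum.  Times are minutes from
    experiment start.  Duplicate or non-increasing timestamps are rejected
    rather than averaged, to surface acquisition faults.
    """

    times: np.ndarray
    c_pf: np.ndarray
    c_cc: np.ndarray
    device_id: str = ""
    model_label: str = ""  # one of {BBB, BTB, unrestricted} by convention

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        pf = np.asarray(self.c_pf, dtype=float)
        cc = np.asarray(self.c_cc, dtype=float)
        if not (t.shape == pf.shape == cc.shape) or t.ndim != 1:
            raise InputError("times, c_pf, c_cc must be equal-length 1-D series")
        if t.size == 0:
            raise InputError("trace is empty")
        if np.any(np.diff(t) <= 0):
            raise InputError("times must be strictly increasing (no duplicates)")
        if np.any(pf <= 0):
            bad = int(np.flatnonzero(pf <= 0)[0])
            raise InputError(f"c_pf must be > 0 at every frame (frame {bad})")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "c_pf", pf)
        object.__setattr__(self, "c_cc", cc)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"minutes": self.times, "c_pf": self.c_pf, "c_cc": self.c_cc}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, device_id: str = "",
                   model_label: str = "") -> "RoiTrace":
        return cls(
            times=df["minutes"].to_numpy(float),
            c_pf=df["c_pf"].to_numpy(float),
            c_cc=df["c_cc"].to_numpy(float),
            device_id=device_id,
            model_label=model_label,
        )


@dataclass(frozen=True)
class RatioSeries:
    """Uptake-ratio series (C_CC + C_PF)/C_PF with acquisition times."""

    times: np.ndarray
    ratio: np.ndarray
    device_id: str = ""
    model_label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.ratio, dtype=float)
        if t.shape != r.shape or t.ndim != 1:
            raise InputError("times and ratio must be equal-length 1-D series")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "ratio", r)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class KinEstimate:
    """OLS results for one chip: slope k_in, intercept O_C and diagnostics.

    ``kin`` is in 1/min on the ratio scale.  ``p_slope_gt_zero`` is the
    one-sided p-value of the t-test for slope > 0 (df = n_points - 2).
    The published display convention (µL/min/µm²) requires a chamber
    geometry factor that is not derivable from the ratio law alone; use
    :meth:`to_display_units` with a user-supplied factor.
    """

    kin: float
    oc: float
    se_kin: float
    se_oc: float
    n_points: int
    r_squared: float
    p_slope_gt_zero: float
    device_id: str = ""
    model_label: str = ""

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise InsufficientDataError("KinEstimate requires n_points >= 3")
        if self.se_kin < 0:
            raise InputError("se_kin must be >= 0")
        if not (0.0 <= self.p_slope_gt_zero <= 1.0):
            raise InputError("p_slope_gt_zero must lie in [0, 1]")

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Two-sided (1-alpha) confidence interval for k_in."""
        tcrit = sstats.t.ppf(1.0 - alpha / 2.0, self.n_points - 2)
        return (self.kin - tcrit * self.se_kin, self.kin + tcrit * self.se_kin)

    def to_display_units(self, geometry_factor: float) -> float:
        """Rescale k_in by a chamber-geometry factor for display."""
        return self.kin * geometry_factor

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            "Uptake kinetics (OLS on uptake ratio vs steady-state time)",
            "=" * 58,
            f"device: {self.device_id or '-'}    model: {self.model_label or '-'}",
            f"n frames used: {self.n_points}    R^2: {self.r_squared:.4f}",
            f"k_in  = {self.kin:.6g} 1/min  (SE {self.se_kin:.3g}, "
            f"95% CI [{lo:.6g}, {hi:.6g}])",
            f"O_C   = {self.oc:.6g}  (SE {self.se_oc:.3g})",
            f"P(slope > 0): {self.p_slope_gt_zero:.3g}",
        ]
        return "\n".join(lines)

    def to_row(self) -> dict:
        return {
            "device_id": self.device_id,
            "model_label": self.model_label,
            "kin": self.kin,
            "oc": self.oc,
            "se_kin": self.se_kin,
            "n_points": self.n_points,
            "r_squared": self.r_squared,
            "p_slope_gt_zero": self.p_slope_gt_zero,
        }


# ---------------------------------------------------------------------------
# operations


def extract_roi_traces(
    stack: np.ndarray,
    mask: np.ndarray,
    frame_times: Sequence[float],
    outer_label: int = 1,
    central_label: int = 2,
    device_id: str = "",
    model_label: str = "",
) -> RoiTrace:
    """Sum pixel intensities under the outer and central ROI labels per frame.

    Aggregation is the ROI *sum* (the "sum intensity" convention), not the
    mean.  Zero-area ROIs and shape mismatches are input errors.
    """
    stack = np.asarray(stack, dtype=float)
    mask = np.asarray(mask)
    if stack.ndim != 3:
        raise InputError("stack must be (n_frames, height, width)")
    if mask.shape != stack.shape[1:]:
        raise InputError(
            f"mask shape {mask.shape} does not match frame shape {stack.shape[1:]}"
        )
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times.size != stack.shape[0]:
        raise InputError("frame_times length must match number of frames")
    outer = mask == outer_label
    central = mask == central_label
    if not outer.any():
        raise InputError(f"outer label {outer_label} absent from mask")
    if not central.any():
        raise InputError(f"central label {central_label} absent from mask")
    c_pf = stack[:, outer].sum(axis=1)
    c_cc = stack[:, central].sum(axis=1)
    return RoiTrace(
        times=frame_times, c_pf=c_pf, c_cc=c_cc,
        device_id=device_id, model_label=model_label,
    )


def uptake_ratio(trace: RoiTrace) -> RatioSeries:
    """Form the uptake ratio (C_CC + C_PF)/C_PF per frame.

    The ratio is >= 1 whenever the central compartment holds non-negative
    signal; it is invariant to any common rescaling of both compartments
    (illumination/gain invariance).
    """
    if np.any(trace.c_pf <= 0):  # defensive; RoiTrace already enforces
        bad = int(np.flatnonzero(trace.c_pf <= 0)[0])
        raise ComputationError(f"c_pf <= 0 at frame {bad}; ratio undefined")
    ratio = (trace.c_cc + trace.c_pf) / trace.c_pf
    return RatioSeries(
        times=trace.times, ratio=ratio,
        device_id=trace.device_id, model_label=trace.model_label,
    )


def trim_to_steady_state(series: RatioSeries, delay: float = 22.0) -> RatioSeries:
    """Drop frames before steady state and re-origin time to its onset.

    Frames at times >= ``delay`` are retained; the retained times are
    shifted by -delay so t=0 is the start of steady state.
    """
    if delay < 0:
        raise InputError("delay must be >= 0")
    if delay > series.times[-1]:
        raise InputError(
            f"delay {delay} min lies beyond the last frame at {series.times[-1]} min"
        )
    keep = series.times >= delay
    return RatioSeries(
        times=series.times[keep] - delay,
        ratio=series.ratio[keep],
        device_id=series.device_id,
        model_label=series.model_label,
    )


class UptakeKinetics:
    """Linear uptake model for one chip's trimmed ratio series.

    Parameters
    ----------
    series : RatioSeries
        Uptake ratio vs time measured from steady-state onset (see
        :func:`trim_to_steady_state`).

    ``fit()`` runs ordinary least squares of ratio on time and returns a
    :class:`KinEstimate`.
    """

    def __init__(self, series: RatioSeries):
        if len(series) < 3:
            raise InsufficientDataError(
                f"need >= 3 frames to fit, got {len(series)}"
            )
        if np.ptp(series.times) == 0 or np.var(series.times) == 0:
            raise DegenerateInputError("zero variance in time axis")
        self.series = series

    @classmethod
    def from_trace(cls, trace: RoiTrace, delay: float = 22.0) -> "UptakeKinetics":
        """Build the model straight from a trace: ratio, trim, wrap."""
        return cls(trim_to_steady_state(uptake_ratio(trace), delay))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, delay: float = 22.0,
                       device_id: str = "", model_label: str = "") -> "UptakeKinetics":
        """Build from a trace table with columns minutes, c_pf, c_cc."""
        return cls.from_trace(
            RoiTrace.from_frame(df, device_id=device_id, model_label=model_label),
            delay=delay,
        )

    def fit(self) -> KinEstimate:
        t = self.series.times
        y = self.series.ratio
        X = sm.add_constant(t)
        res = sm.OLS(y, X).fit()
        oc, kin = res.params
        se_oc, se_kin = res.bse
        df_resid = int(res.df_resid)
        rss = float(np.sum(res.resid**2))
        scale = float(np.max(np.abs(y))) or 1.0
        # numerically perfect fit: residuals at floating-point noise level
        perfect = np.sqrt(rss / max(df_resid, 1)) <= 1e-10 * scale
        if perfect or se_kin == 0 or not np.isfinite(se_kin):
            slope_tol = 1e-10 * scale / max(float(np.ptp(t)), 1.0)
            p_one = 0.0 if kin > slope_tol else (1.0 if kin < -slope_tol else 0.5)
            se_kin = 0.0 if not np.isfinite(se_kin) else se_kin
        else:
            p_one = float(sstats.t.sf(kin / se_kin, df_resid))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot <= (1e-12 * scale) ** 2 * y.size:
            r2 = 1.0 if perfect else 0.0
        else:
            r2 = float(res.rsquared)
        return KinEstimate(
            kin=float(kin),
            oc=float(oc),
            se_kin=float(se_kin),
            se_oc=float(se_oc) if np.isfinite(se_oc) else 0.0,
            n_points=int(t.size),
            r_squared=r2,
            p_slope_gt_zero=min(max(p_one, 0.0), 1.0),
            device_id=self.series.device_id,
            model_label=self.series.model_label,
        )


def fit_kin(series: RatioSeries) -> KinEstimate:
    """OLS fit of the trimmed uptake-ratio series; see :class:`UptakeKinetics`."""
    return UptakeKinetics(series).fit()


def estimate_steady_state_delay(
    series: RatioSeries,
    candidates: Optional[Sequence[float]] = None,
    min_points_after: int = 3,
) -> float:
    """Estimate the pre-steady-state delay by piecewise-linear changepoint fit.

    For each candidate breakpoint d the model ratio = oc + k*max(0, t-d) is
    fitted by OLS and the residual sum of squares recorded; the candidate
    minimising RSS is returned.  Defaults to trying every observed frame
    time that leaves at least ``min_points_after`` frames in the linear arm.
    """
    t, y = series.times, series.ratio
    if t.size < min_points_after + 2:
        raise InsufficientDataError("too few frames for changepoint estimation")
    if candidates is None:
        candidates = t[: t.size - min_points_after]
    best_d, best_rss = None, np.inf
    for d in candidates:
        x = np.maximum(0.0, t - d)
        if np.count_nonzero(x) < min_points_after or np.var(x) == 0:
            continue
        X = sm.add_constant(x)
        res = sm.OLS(y, X).fit()
        rss = float(np.sum(res.resid**2))
        if rss < best_rss - 1e-12:
            best_rss, best_d = rss, float(d)
    if best_d is None:
        raise DegenerateInputError("no admissible breakpoint candidate")
    return best_d


# ---------------------------------------------------------------------------
# group comparison


@dataclass(frozen=True)
class GroupComparison:
    """Welch t-test and variance-ratio F-test between two groups of k_in.

    Group summaries follow the mean ± S.E.M. display convention.
    """

    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    t_welch: float
    df_welch: float
    p_welch: float
    f_stat: float
    df_num: int
    df_den: int
    p_f: float

    def summary(self) -> str:
        return "\n".join(
            [
                "Group comparison of k_in estimates",
                "=" * 42,
                f"group A: mean {self.mean_a:.6g} ± {self.sem_a:.3g} S.E.M. (n={self.n_a})",
                f"group B: mean {self.mean_b:.6g} ± {self.sem_b:.3g} S.E.M. (n={self.n_b})",
                f"Welch t = {self.t_welch:.4g} (df {self.df_welch:.2f}), p = {self.p_welch:.4g}",
                f"F = {self.f_stat:.4g} (df {self.df_num}, {self.df_den}), p = {self.p_f:.4g}",
            ]
        )

    def to_row(self) -> dict:
        return {
            "mean_a": self.mean_a, "sem_a": self.sem_a, "n_a": self.n_a,
            "mean_b": self.mean_b, "sem_b": self.sem_b, "n_b": self.n_b,
            "t_welch": self.t_welch, "df_welch": self.df_welch,
            "p_welch": self.p_welch, "f_stat": self.f_stat,
            "df_num": self.df_num, "df_den": self.df_den, "p_f": self.p_f,
        }


def _kin_values(estimates: Iterable) -> np.ndarray:
    vals = np.asarray(
        [e.kin if isinstance(e, KinEstimate) else float(e) for e in estimates],
        dtype=float,
    )
    return vals


def compare_groups(estimates_a: Iterable, estimates_b: Iterable) -> GroupComparison:
    """Two-sided Welch t-test plus variance-ratio F-test on k_in values.

    Accepts lists of :class:`KinEstimate` or raw slope values.  The F
    statistic places the larger sample variance in the numerator and the
    two-sided p doubles the upper-tail probability (capped at 1).
    """
    a = _kin_values(estimates_a)
    b = _kin_values(estimates_b)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs >= 2 estimates")

    t_res = sstats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    # Welch–Satterthwaite degrees of freedom
    if va == 0 and vb == 0:
        # degenerate: both groups exactly constant
        df_w = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            t_stat, p_w = 0.0, 1.0
        else:
            t_stat = np.inf if a.mean() > b.mean() else -np.inf
            p_w = 0.0
    else:
        num = (va / a.size + vb / b.size) ** 2
        den = (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
        df_w = float(num / den)
        t_stat, p_w = float(t_res.statistic), float(t_res.pvalue)

    if va >= vb:
        f_stat, dfn, dfd = (va / vb if vb > 0 else np.inf), a.size - 1, b.size - 1
    else:
        f_stat, dfn, dfd = vb / va, b.size - 1, a.size - 1
    if np.isfinite(f_stat):
        p_f = min(1.0, 2.0 * float(sstats.f.sf(f_stat, dfn, dfd)))
    else:
        p_f = 0.0

    return GroupComparison(
        mean_a=float(a.mean()), sem_a=float(sstats.sem(a)), n_a=int(a.size),
        mean_b=float(b.mean()), sem_b=float(sstats.sem(b)), n_b=int(b.size),
        t_welch=t_stat, df_welch=df_w, p_welch=p_w,
        f_stat=float(f_stat), df_num=int(dfn), df_den=int(dfd), p_f=p_f,
    )
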