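"""Quantitative autoradiography calibration and biodistribution accounting.

A phosphor-imager autoradiograph records film intensity, not activity;
co-exposed radioactive standards of known activity (nCi/g) are fitted to
a monotone intensity-response model whose inverse converts tissue pixel
intensities to tissue activity.  Two response forms are supported:

* linear:      I = gain * a + offset   (offset fitted, film background)
* saturating:  I = offset + imax * (1 - exp(-a / scale))

The biodistribution chain converts raw gamma-counter output through
cpm -> nCi -> nCi/g -> %ID/g and tissue/blood ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize

from .exceptions import (
    CalibrationError,
    ComputationError,
    InputError,
    RangeError,
)
from .units import cpm_to_nci, decay_correct_i125, mg_to_g

__all__ = [
    "CalibrationCurve",
    "QarCalibration",
    "OrganSample",
    "fit_calibration",
    "intensity_to_activity",
    "activity_per_gram",
    "percent_id_per_gram",
    "tissue_blood_ratio",
    "tumor_to_brain_fold",
    "biodistribution_table",
]


# ---------------------------------------------------------------------------
# calibration


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted monotone map between autoradiograph intensity and activity.

    Results object of :class:`QarCalibration`; evaluate with
    :meth:`predict` (activity -> intensity) and :meth:`inverse`
    (intensity -> activity).
    """

    standard_activities: np.ndarray
    standard_intensities: np.ndarray
    model_form: str
    fitted_params: Dict[str, float]
    fit_residuals: np.ndarray

    def predict(self, activity) -> np.ndarray:
        a = np.asarray(activity, dtype=float)
        p = self.fitted_params
        if self.model_form == "linear":
            return p["gain"] * a + p["offset"]
        return p["offset"] + p["imax"] * (1.0 - np.exp(-a / p["scale"]))

    def inverse(self, intensity, extrapolate: bool = False) -> np.ndarray:
        """Map measured intensity back to activity (nCi/g).

        Intensities outside the calibrated range raise :class:`RangeError`
        unless ``extrapolate`` is set (linear form only; the saturating
        form cannot be inverted above its asymptote).
        """
        i = np.asarray(intensity, dtype=float)
        lo = float(self.predict(self.standard_activities[0]))
        hi = float(self.predict(self.standard_activities[-1]))
        if not extrapolate:
            tol = 1e-9 * max(abs(lo), abs(hi), 1.0)
            if np.any(i < lo - tol) or np.any(i > hi + tol):
                raise RangeError(
                    f"intensity outside calibrated range [{lo:.4g}, {hi:.4g}]; "
                    "pass extrapolate=True to override"
                )
        p = self.fitted_params
        if self.model_form == "linear":
            return (i - p["offset"]) / p["gain"]
        arg = 1.0 - (i - p["offset"]) / p["imax"]
        if np.any(arg <= 0):
            raise RangeError("intensity at or above the saturating asymptote")
        return -p["scale"] * np.log(arg)

    def summary(self) -> str:
        rms = float(np.sqrt(np.mean(self.fit_residuals**2)))
        pars = ", ".join(f"{k}={v:.6g}" for k, v in self.fitted_params.items())
        return "\n".join(
            [
                "QAR calibration curve",
                "=" * 42,
                f"form: {self.model_form}   standards: {self.standard_activities.size}",
                f"params: {pars}",
                f"RMS residual: {rms:.4g} au over "
                f"[{self.standard_activities[0]:.4g}, "
                f"{self.standard_activities[-1]:.4g}] nCi/g",
            ]
        )


class QarCalibration:
    """Least-squares calibration model over co-exposed activity standards.

    Parameters
    ----------
    standards : DataFrame with columns activity_nCi_per_g, intensity_au,
        or two sequences (activities, intensities).
    model_form : 'linear' (default) or 'saturating'.
    force_zero_offset : fit the linear form through the origin (film
        background assumed already subtracted).
    """

    def __init__(
        self,
        standards: Union[pd.DataFrame, Sequence[float]],
        intensities: Optional[Sequence[float]] = None,
        model_form: str = "linear",
        force_zero_offset: bool = False,
    ):
        if isinstance(standards, pd.DataFrame):
            acts = standards["activity_nCi_per_g"].to_numpy(float)
            ints = standards["intensity_au"].to_numpy(float)
        else:
            acts = np.asarray(standards, dtype=float)
            ints = np.asarray(intensities, dtype=float)
        if acts.size != ints.size:
            raise InputError("activities and intensities must be equal length")
        if acts.size < 2:
            raise CalibrationError("calibration needs >= 2 standards")
        if np.any(np.diff(acts) <= 0):
            raise CalibrationError("standard activities must be strictly increasing")
        if np.ptp(ints) == 0:
            raise CalibrationError("standard intensities are all equal")
        if model_form not in ("linear", "saturating"):
            raise InputError("model_form must be 'linear' or 'saturating'")
        self.activities = acts
        self.intensities = ints
        self.model_form = model_form
        self.force_zero_offset = force_zero_offset

    def fit(self) -> CalibrationCurve:
        a, i = self.activities, self.intensities
        if self.model_form == "linear":
            if self.force_zero_offset:
                gain = float(np.dot(a, i) / np.dot(a, a))
                params = {"gain": gain, "offset": 0.0}
            else:
                gain, offset = np.polyfit(a, i, 1)
                params = {"gain": float(gain), "offset": float(offset)}
            if params["gain"] <= 0:
                raise CalibrationError("fitted linear gain is non-positive")
        else:
            if a.size < 3:
                raise CalibrationError("saturating form needs >= 3 standards")
            imax0 = float(i.max() - i.min()) * 1.5 or 1.0
            p0 = (float(i.min()), imax0, float(np.median(a)))
            try:
                popt, _ = optimize.curve_fit(
                    lambda x, off, imax, scale: off + imax * (1 - np.exp(-x / scale)),
                    a, i, p0=p0, maxfev=20000,
                )
            except RuntimeError as exc:  # pragma: no cover - pathological data
                raise CalibrationError(f"saturating fit did not converge: {exc}")
            params = {
                "offset": float(popt[0]),
                "imax": float(popt[1]),
                "scale": float(popt[2]),
            }
            if params["imax"] <= 0 or params["scale"] <= 0:
                raise CalibrationError("saturating fit is not monotone increasing")
        curve = CalibrationCurve(
            standard_activities=a,
            standard_intensities=i,
            model_form=self.model_form,
            fitted_params=params,
            fit_residuals=np.asarray(i, float) - np.asarray(
                _predict(self.model_form, params, a), float
            ),
        )
        pred = curve.predict(a)
        if np.any(np.diff(pred) <= 0):
            raise CalibrationError("fitted map is not monotone over the standards")
        return curve


def _predict(model_form: str, params: Dict[str, float], activity) -> np.ndarray:
    a = np.asarray(activity, dtype=float)
    if model_form == "linear":
        return params["gain"] * a + params["offset"]
    return params["offset"] + params["imax"] * (1.0 - np.exp(-a / params["scale"]))


def fit_calibration(
    standards: Union[pd.DataFrame, Sequence[float]],
    intensities: Optional[Sequence[float]] = None,
    model_form: str = "linear",
    force_zero_offset: bool = False,
) -> CalibrationCurve:
    """Fit the standards table; see :class:`QarCalibration`."""
    return QarCalibration(
        standards, intensities, model_form=model_form,
        force_zero_offset=force_zero_offset,
    ).fit()


def intensity_to_activity(
    curve: CalibrationCurve, intensity, extrapolate: bool = False
):
    """Convert autoradiograph intensity (au) to tissue activity (nCi/g)."""
    return curve.inverse(intensity, extrapolate=extrapolate)


# ---------------------------------------------------------------------------
# biodistribution accounting


@dataclass(frozen=True)
class OrganSample:
    """One counted organ sample with its derived activity quantities."""

    organ: str
    counts: float
    weight: float  # g
    activity_per_g: float  # nCi/g
    pct_id_per_g: float
    tissue_blood_ratio: float = np.nan

    def __post_init__(self) -> None:
        if self.counts < 0:
            raise InputError("counts must be >= 0")
        if self.weight <= 0:
            raise InputError("weight must be > 0")
        if self.pct_id_per_g < 0:
            raise InputError("pct_id_per_g must be >= 0")


def activity_per_gram(counts: float, weight_g: float, counter_efficiency: float):
    """cpm -> nCi/g for a weighed sample."""
    if np.any(np.asarray(weight_g) <= 0):
        raise ComputationError("weight must be > 0")
    return cpm_to_nci(counts, counter_efficiency) / np.asarray(weight_g, dtype=float)


def percent_id_per_gram(
    counts: float,
    weight_g: float,
    counter_efficiency: float,
    injected_dose: float,
):
    """Percent of injected dose per gram of tissue.

    %ID/g = 100 * (counts / efficiency / weight) / injected_dose.
    """
    if injected_dose <= 0:
        raise ComputationError("injected_dose must be > 0")
    return 100.0 * activity_per_gram(counts, weight_g, counter_efficiency) / injected_dose


def tissue_blood_ratio(tissue_activity_per_g: float, blood_activity_per_g: float):
    """Weight-normalised tissue/blood distribution ratio."""
    if np.any(np.asarray(blood_activity_per_g) <= 0):
        raise ComputationError("blood activity must be > 0")
    return np.asarray(tissue_activity_per_g, dtype=float) / np.asarray(
        blood_activity_per_g, dtype=float
    )


def tumor_to_brain_fold(tumor_pct: float, brain_pct: float) -> float:
    """Fold accumulation in tumor-bearing brain over normal brain (%ID/g ratio)."""
    if brain_pct <= 0:
        raise ComputationError("normal-brain %ID/g must be > 0")
    if tumor_pct < 0:
        raise InputError("tumor %ID/g must be >= 0")
    return tumor_pct / brain_pct


def biodistribution_table(
    counts: pd.DataFrame,
    counter_efficiency: float,
    injected_dose: float,
    blood_organ: str = "blood",
    decay_days: float = 0.0,
) -> pd.DataFrame:
    """Full accounting chain for a counter export (organ, cpm, weight_mg).

    Returns one row per organ with activity_nCi_per_g, pct_id_per_g and
    tissue_blood_ratio (NaN when no blood row is present).  Optional
    ``decay_days`` applies I-125 physical-decay correction back to the
    injection time.
    """
    required = {"organ", "cpm", "weight_mg"}
    if not required.issubset(counts.columns):
        raise InputError(f"counts table must have columns {sorted(required)}")
    weight_g = mg_to_g(counts["weight_mg"].to_numpy(float))
    activity = activity_per_gram(
        counts["cpm"].to_numpy(float), weight_g, counter_efficiency
    )
    if decay_days > 0:
        activity = decay_correct_i125(activity, decay_days)
    pct = 100.0 * activity / injected_dose
    out = pd.DataFrame(
        {
            "organ": counts["organ"].to_numpy(),
            "cpm": counts["cpm"].to_numpy(float),
            "weight_g": weight_g,
            "activity_nCi_per_g": activity,
            "pct_id_per_g": pct,
        }
    )
    blood_rows = out["organ"] == blood_organ
    if blood_rows.any():
        blood_act = float(out.loc[blood_rows, "activity_nCi_per_g"].iloc[0])
        out["tissue_blood_ratio"] = tissue_blood_ratio(
            out["activity_nCi_per_g"].to_numpy(), blood_act
        )
    else:
        out["tissue_blood_ratio"] = np.nan
    return out
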