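"""In-vivo lesion quantification: segmentation, fold change, classification.

Brain metastases are located on the tumor-marker channel (eGFP-type
signal), measured on a co-registered tracer channel (Texas Red or a
calibrated autoradiograph), expressed as fold increase of per-area signal
over normal brain, and sorted into four permeability classes:

    low           fold <  1 + 3*CV        (below mean brain + 3 SD)
    intermediate  cutoff <= fold < 2
    medium        2 <= fold < 4
    high          fold >= 4

where CV is the coefficient of variation of the normal-brain reference
signal — "mean brain + 3 SD" expressed in fold units, since lesion fold
is already normalised by the normal-brain mean.  Interval conventions are
half-open with the upper class winning at each boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sstats
from skimage import filters, measure

from .exceptions import (
    ComputationError,
    InputError,
    InsufficientDataError,
)

PERM_CLASSES = ("low", "intermediate", "medium", "high")

__all__ = [
    "NormalBrainStats",
    "LesionRecord",
    "segment_lesions",
    "lesion_fold_change",
    "resolve_reference_mask",
    "classify_permeability",
    "group_summary",
    "fold_vs_size_correlation",
    "invivo_kin_single_timepoint",
    "invivo_kin_patlak",
]


@dataclass(frozen=True)
class NormalBrainStats:
    """Mean and SD of normal-brain per-area reference signal."""

    mean_signal: float
    sd_signal: float
    n_regions: int = 1

    def __post_init__(self) -> None:
        if self.mean_signal <= 0:
            raise InputError("mean_signal must be > 0")
        if self.sd_signal < 0:
            raise InputError("sd_signal must be >= 0")
        if self.n_regions < 1:
            raise InputError("n_regions must be >= 1")

    @property
    def fold_cutoff(self) -> float:
        """'mean brain + 3 SD' in fold units: 1 + 3*CV."""
        return 1.0 + 3.0 * self.sd_signal / self.mean_signal

    @classmethod
    def from_mask(cls, image: np.ndarray, mask: np.ndarray) -> "NormalBrainStats":
        """Estimate from a labelled reference mask.

        With two or more labelled regions the statistics are computed over
        the per-region mean signals; with a single region they fall back
        to per-pixel statistics within that region.
        """
        image = np.asarray(image, dtype=float)
        mask = np.asarray(mask)
        if mask.shape != image.shape:
            raise InputError("reference mask shape must match image")
        labels = np.unique(mask[mask > 0])
        if labels.size == 0:
            raise InputError("reference mask contains no labelled region")
        if labels.size >= 2:
            means = np.array([image[mask == lab].mean() for lab in labels])
            return cls(
                mean_signal=float(means.mean()),
                sd_signal=float(means.std(ddof=1)),
                n_regions=int(labels.size),
            )
        px = image[mask > 0]
        return cls(
            mean_signal=float(px.mean()),
            sd_signal=float(px.std(ddof=1)) if px.size > 1 else 0.0,
            n_regions=1,
        )


@dataclass(frozen=True)
class LesionRecord:
    """One metastasis: area, fold increase and permeability class."""

    lesion_id: int
    slice_id: str
    area_mm2: float
    fold_increase: float
    perm_class: str
    tracer: str = "125I"

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise InputError("area_mm2 must be > 0")
        if self.fold_increase <= 0:
            raise InputError("fold_increase must be > 0")
        if self.perm_class not in PERM_CLASSES:
            raise InputError(f"unknown perm_class '{self.perm_class}'")


# ---------------------------------------------------------------------------
# segmentation


def segment_lesions(
    marker_image: np.ndarray,
    pixel_size: float,
    threshold: Optional[float] = None,
    min_area_mm2: float = 0.0,
    connectivity: int = 1,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Segment lesions on the tumor-marker channel.

    Thresholds the marker image (Otsu by default), labels connected
    components (4-connectivity by default) and keeps components with area
    at least ``min_area_mm2``.  Returns (label mask, table with columns
    lesion_id, area_px, area_mm2).  An image empty after thresholding
    yields an empty result, not an error.
    """
    img = np.asarray(marker_image, dtype=float)
    if img.ndim != 2:
        raise InputError("marker image must be single-channel 2-D")
    if pixel_size <= 0:
        raise InputError("pixel_size must be > 0")
    if threshold is None:
        if np.ptp(img) == 0:  # constant image: nothing to segment
            return np.zeros(img.shape, np.int32), _empty_lesion_table()
        threshold = float(filters.threshold_otsu(img))
    binary = img > threshold
    labels = measure.label(binary, connectivity=connectivity)
    rows = []
    out = np.zeros_like(labels, dtype=np.int32)
    next_id = 0
    for region in measure.regionprops(labels):
        area_mm2 = region.area * pixel_size**2
        if area_mm2 < min_area_mm2 or region.area == 0:
            continue
        next_id += 1
        out[labels == region.label] = next_id
        rows.append(
            {"lesion_id": next_id, "area_px": int(region.area), "area_mm2": float(area_mm2)}
        )
    table = pd.DataFrame(rows) if rows else _empty_lesion_table()
    return out, table


def _empty_lesion_table() -> pd.DataFrame:
    return pd.DataFrame(columns=["lesion_id", "area_px", "area_mm2"]).astype(
        {"lesion_id": int, "area_px": int, "area_mm2": float}
    )


# ---------------------------------------------------------------------------
# fold change


def resolve_reference_mask(
    reference_mask: np.ndarray,
    lesion_mask: np.ndarray,
    alternate_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Pick a tumor-free reference region.

    If the designated contralateral reference intersects any lesion, fall
    back to the alternate (adjacent-slice) mask; raise if that is missing
    or also tumor-involved.
    """
    ref = np.asarray(reference_mask)
    les = np.asarray(lesion_mask)
    if ref.shape != les.shape:
        raise InputError("reference and lesion masks must have the same shape")
    if not np.any((ref > 0) & (les > 0)):
        return ref
    if alternate_mask is None:
        raise InputError(
            "reference region intersects lesions and no alternate mask supplied"
        )
    alt = np.asarray(alternate_mask)
    if alt.shape != les.shape:
        raise InputError("alternate mask shape mismatch")
    if np.any((alt > 0) & (les > 0)):
        raise InputError("both reference and alternate masks intersect lesions")
    return alt


def lesion_fold_change(
    signal_image: np.ndarray,
    lesion_mask: np.ndarray,
    normal_reference: Union[NormalBrainStats, np.ndarray],
) -> pd.DataFrame:
    """Per-lesion fold increase of per-area signal over normal brain.

    fold = (lesion sum intensity / lesion area) / (reference sum / area);
    with per-pixel areas this is the ratio of mean pixel intensities, so
    it is invariant to global gain rescaling of the signal image.
    """
    img = np.asarray(signal_image, dtype=float)
    les = np.asarray(lesion_mask)
    if les.shape != img.shape:
        raise InputError("lesion mask shape must match signal image")
    if isinstance(normal_reference, NormalBrainStats):
        stats = normal_reference
    else:
        stats = NormalBrainStats.from_mask(img, normal_reference)
    if stats.mean_signal <= 0:
        raise ComputationError("reference mean signal must be > 0")
    rows = []
    for lab in np.unique(les[les > 0]):
        px = img[les == lab]
        rows.append(
            {
                "lesion_id": int(lab),
                "per_area_signal": float(px.mean()),
                "fold_increase": float(px.mean() / stats.mean_signal),
            }
        )
    return pd.DataFrame(rows, columns=["lesion_id", "per_area_signal", "fold_increase"])


# ---------------------------------------------------------------------------
# classification and summaries


def classify_permeability(
    fold: float, stats: Union[NormalBrainStats, float]
) -> str:
    """Assign the four-class permeability label to a fold increase.

    ``stats`` is either :class:`NormalBrainStats` (cutoff 1 + 3*CV) or the
    cutoff itself.  Intervals are half-open with the upper class claiming
    each boundary: high [4, inf), medium [2, 4), intermediate [cutoff, 2),
    low (0, cutoff).
    """
    if not np.isfinite(fold) or fold <= 0:
        raise InputError("fold must be a positive finite number")
    cutoff = stats.fold_cutoff if isinstance(stats, NormalBrainStats) else float(stats)
    if fold >= 4.0:
        return "high"
    if fold >= 2.0:
        return "medium"
    if fold >= cutoff:
        return "intermediate"
    return "low"


def group_summary(records: Union[Iterable[LesionRecord], pd.DataFrame]) -> pd.DataFrame:
    """Per-class mean, sample SD and count of fold increases.

    All four classes appear even when empty (count 0).  A single-member
    class reports SD 0 with ``sd_defined = False`` so summary tables stay
    well-formed.
    """
    df = _records_frame(records)
    if df.empty:
        raise InsufficientDataError("group_summary needs >= 1 record")
    rows = []
    for cls in PERM_CLASSES:
        folds = df.loc[df["perm_class"] == cls, "fold_increase"].to_numpy(float)
        n = folds.size
        rows.append(
            {
                "perm_class": cls,
                "n": int(n),
                "mean_fold": float(folds.mean()) if n else np.nan,
                "sd_fold": float(folds.std(ddof=1)) if n > 1 else (0.0 if n == 1 else np.nan),
                "sd_defined": bool(n > 1),
            }
        )
    return pd.DataFrame(rows)


def fold_vs_size_correlation(
    records: Union[Iterable[LesionRecord], pd.DataFrame]
) -> dict:
    """Pearson and Spearman correlation of fold increase with lesion area.

    Returns a record with r, rho, their p-values and n; a constant series
    makes the correlation undefined, flagged rather than raised.
    """
    df = _records_frame(records)
    if len(df) < 3:
        raise InsufficientDataError("correlation needs >= 3 records")
    x = df["area_mm2"].to_numpy(float)
    y = df["fold_increase"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {
            "pearson_r": np.nan, "pearson_p": np.nan,
            "spearman_rho": np.nan, "spearman_p": np.nan,
            "n": int(len(df)), "defined": False,
        }
    pr = sstats.pearsonr(x, y)
    sr = sstats.spearmanr(x, y)
    return {
        "pearson_r": float(pr.statistic), "pearson_p": float(pr.pvalue),
        "spearman_rho": float(sr.statistic), "spearman_p": float(sr.pvalue),
        "n": int(len(df)), "defined": True,
    }


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = [
        {
            "lesion_id": r.lesion_id,
            "slice_id": r.slice_id,
            "area_mm2": r.area_mm2,
            "fold_increase": r.fold_increase,
            "perm_class": r.perm_class,
            "tracer": r.tracer,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["lesion_id", "slice_id", "area_mm2", "fold_increase", "perm_class", "tracer"],
    )


# ---------------------------------------------------------------------------
# in-vivo transfer constant


def invivo_kin_single_timepoint(
    tissue_conc: float, blood_conc: float, circulation_time: float
) -> float:
    """Single-time-point unidirectional uptake transfer constant (mL/sec/g).

    Under a constant-plasma assumption the apparent distribution volume
    V = tissue_conc/blood_conc (mL/g) grows linearly with exposure time,
    so k_in = V / t.  Concentrations share units (activity per g); time is
    seconds.
    """
    if blood_conc <= 0:
        raise ComputationError("blood concentration must be > 0")
    if circulation_time <= 0:
        raise ComputationError("circulation time must be > 0")
    if tissue_conc < 0:
        raise InputError("tissue concentration must be >= 0")
    return (tissue_conc / blood_conc) / circulation_time


def invivo_kin_patlak(
    tissue_conc: Sequence[float],
    blood_conc: Sequence[float],
    times: Sequence[float],
) -> dict:
    """Multi-time-point graphical (Patlak-style) uptake estimate.

    Regresses the apparent distribution volume V(t) = tissue/blood on
    time; the slope is k_in (mL/sec/g when time is in seconds) and the
    intercept the initial distribution volume V0.  Needs >= 3 time points.
    """
    tissue = np.asarray(tissue_conc, dtype=float)
    blood = np.asarray(blood_conc, dtype=float)
    t = np.asarray(times, dtype=float)
    if not (tissue.shape == blood.shape == t.shape) or t.ndim != 1:
        raise InputError("tissue, blood and times must be equal-length 1-D")
    if t.size < 3:
        raise InsufficientDataError("Patlak regression needs >= 3 time points")
    if np.any(blood <= 0):
        raise ComputationError("blood concentration must be > 0 at every time")
    v = tissue / blood
    slope, intercept, r, p, se = sstats.linregress(t, v)
    return {
        "kin": float(slope),
        "v0": float(intercept),
        "se_kin": float(se),
        "r_squared": float(r**2),
        "n": int(t.size),
    }
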