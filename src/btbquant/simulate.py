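"""Seeded synthetic-data generators with known ground truth.

Three generators emulate the three experimental input families the
quantification pipeline consumes:

* :func:`simulate_chip_stack` — a microfluidic barrier-chip fluorescence
  time series.  The forward model is the linear uptake law
  ``ratio(t) = O_C + k_in * max(0, t - delay)`` where ``ratio`` is
  ``(C_CC + C_PF) / C_PF``, the central-plus-outer over outer compartment
  sum-intensity ratio.  The central-compartment pixel intensities are
  rendered so that the ROI sums reproduce that ratio exactly, then
  additive Gaussian detector noise is applied per pixel.

* :func:`simulate_section_set` — a co-registered brain-section triplet
  (tumor-marker channel, Texas Red channel, digitised autoradiograph)
  plus a strip of activity calibration standards.  Metastatic lesions are
  uniform-intensity disks whose tracer activity is ``normal_activity *
  fold``, with fold drawn from a four-group permeability mixture
  (low / intermediate / medium / high).  The autoradiograph records the
  configured intensity-response map (linear with offset, or saturating)
  applied to activity, so downstream calibration is exercised for real.

* :func:`simulate_biodistribution` — a gamma-counter organ table
  (organ, cpm, weight) built by inverting the %ID/g accounting chain.

Every generator takes a frozen config dataclass carrying an integer seed;
identical configs produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .exceptions import ConfigurationError, GenerationError
from .units import nci_to_cpm

OUTER_LABEL = 1
CENTRAL_LABEL = 2

PERM_CLASSES = ("low", "intermediate", "medium", "high")

#: per-group (mean, SD) of the fold-increase mixture: low, intermediate,
#: medium, high permeability.
DEFAULT_GROUP_FOLD_PARAMS: Dict[str, Tuple[float, float]] = {
    "low": (1.30, 0.34),
    "intermediate": (1.88, 0.07),
    "medium": (2.79, 0.61),
    "high": (7.40, 4.66),
}

#: per-organ (true %ID/g, sample weight g, count noise CV)
DEFAULT_ORGAN_PARAMS: Dict[str, Tuple[float, float, float]] = {
    "spleen": (5.04, 0.10, 0.05),
    "lungs": (4.45, 0.15, 0.05),
    "liver": (3.54, 1.30, 0.05),
    "kidney": (3.12, 0.40, 0.05),
    "heart": (3.08, 0.15, 0.05),
    "normal brain": (0.30, 0.40, 0.05),
    "tumor brain": (0.46, 0.05, 0.05),
}


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class ChipSimConfig:
    """Ground-truth parameters for one chip transport run.

    ``true_kin`` is the uptake-ratio slope in 1/min, ``intercept_oc`` the
    unitless ratio intercept at steady-state onset, ``steady_state_delay``
    the minutes of pre-steady-state dead time before linear uptake starts.
    Frames are acquired every ``frame_interval`` minutes from t=0 through
    ``total_duration`` inclusive.  ``outer_intensity`` is the mean per-pixel
    outer-compartment fluorescence (au); ``noise_sd`` is additive Gaussian
    per-pixel detector noise (au).
    """

    true_kin: float = 0.18
    intercept_oc: float = 1.2
    steady_state_delay: float = 22.0
    frame_interval: float = 2.0
    total_duration: float = 90.0
    noise_sd: float = 0.0
    outer_intensity: float = 100.0
    image_shape: Tuple[int, int] = (64, 64)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_kin < 0:
            raise ConfigurationError("true_kin must be >= 0")
        if self.frame_interval <= 0:
            raise ConfigurationError("frame_interval must be > 0")
        if self.total_duration <= self.steady_state_delay:
            raise ConfigurationError(
                "total_duration must exceed steady_state_delay"
            )
        if self.total_duration <= 0:
            raise ConfigurationError("total_duration must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.outer_intensity <= 0:
            raise ConfigurationError("outer_intensity must be > 0")
        if self.intercept_oc < 1.0:
            raise ConfigurationError(
                "intercept_oc must be >= 1 (ratio cannot fall below 1 "
                "for non-negative central signal)"
            )
        h, w = self.image_shape
        if h < 8 or w < 8:
            raise ConfigurationError("image_shape must be at least 8x8")


@dataclass(frozen=True)
class SectionSimConfig:
    """Ground truth for one brain-section image triplet.

    ``normal_mean``/``normal_sd`` are the mean and across-region SD of
    normal-brain tracer activity (nCi/g); the SD is a declared population
    parameter consumed by the permeability classification cutoff
    ``1 + 3*(normal_sd/normal_mean)``.  Lesion activity is
    ``normal_mean * fold`` with fold drawn from the four-group mixture,
    truncated to each class's fold interval so drawn group and rule-derived
    class always agree.  ``standard_activities`` are the co-exposed
    calibration standards; ``map_form`` selects how activity is converted
    to autoradiograph intensity ('linear': gain*a + offset;
    'saturating': offset + imax*(1 - exp(-a/scale))).
    """

    n_lesions: int = 25
    group_weights: Tuple[float, float, float, float] = (0.45, 0.15, 0.25, 0.15)
    group_fold_params: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_FOLD_PARAMS)
    )
    normal_mean: float = 1.0
    normal_sd: float = 0.1
    lesion_area_range: Tuple[float, float] = (0.01, 0.8)
    pixel_size: float = 0.02
    standard_activities: Tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
    map_form: str = "linear"
    map_params: Dict[str, float] = field(
        default_factory=lambda: {"gain": 50.0, "offset": 100.0}
    )
    marker_intensity: float = 1000.0
    tr_background: float = 200.0
    noise_sd: float = 0.0
    image_shape: Tuple[int, int] = (384, 384)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lesions < 0:
            raise ConfigurationError("n_lesions must be >= 0")
        w = np.asarray(self.group_weights, dtype=float)
        if w.shape != (4,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ConfigurationError("group_weights must be 4 proportions summing to 1")
        for name in PERM_CLASSES:
            if name not in self.group_fold_params:
                raise ConfigurationError(f"group_fold_params missing '{name}'")
            mean, sd = self.group_fold_params[name]
            if mean <= 0 or sd < 0:
                raise ConfigurationError("fold means must be > 0 and SDs >= 0")
        if self.normal_mean <= 0 or self.normal_sd < 0:
            raise ConfigurationError("normal_mean must be > 0 and normal_sd >= 0")
        lo, hi = self.lesion_area_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError("lesion_area_range must be positive and ordered")
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be > 0")
        acts = np.asarray(self.standard_activities, dtype=float)
        if acts.size < 2 or np.any(np.diff(acts) <= 0):
            raise ConfigurationError("standard activities must be strictly increasing")
        if self.map_form not in ("linear", "saturating"):
            raise ConfigurationError("map_form must be 'linear' or 'saturating'")

    @property
    def standards(self) -> List[Tuple[float, float]]:
        """(activity nCi/g, expected noise-free intensity au) pairs."""
        acts = np.asarray(self.standard_activities, dtype=float)
        return list(zip(acts.tolist(), activity_to_intensity(self, acts).tolist()))

    @property
    def fold_cutoff_low(self) -> float:
        """Fold value of 'mean brain + 3 SD' in fold units (1 + 3*CV)."""
        return 1.0 + 3.0 * self.normal_sd / self.normal_mean


@dataclass(frozen=True)
class BiodistSimConfig:
    """Ground truth for a gamma-counter biodistribution table.

    ``organ_params`` maps organ name to (true %ID/g, sample weight g,
    lognormal count-noise CV).  ``blood_activity`` is nCi/g of whole blood;
    ``counter_efficiency`` converts nCi to registered cpm.
    """

    injected_dose: float = 1.0e5
    organ_params: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ORGAN_PARAMS)
    )
    blood_activity: float = 1.5e4
    blood_weight_g: float = 0.5
    blood_cv: float = 0.05
    counter_efficiency: float = 1665.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.injected_dose <= 0:
            raise ConfigurationError("injected_dose must be > 0")
        if self.counter_efficiency <= 0:
            raise ConfigurationError("counter_efficiency must be > 0")
        if self.blood_activity < 0 or self.blood_weight_g <= 0:
            raise ConfigurationError("blood activity/weight invalid")
        for organ, (pct, weight, cv) in self.organ_params.items():
            if pct < 0 or weight <= 0 or cv < 0:
                raise ConfigurationError(f"invalid params for organ '{organ}'")


# ---------------------------------------------------------------------------
# chip generator


def chip_roi_mask(image_shape: Tuple[int, int]) -> np.ndarray:
    """Build the chip ROI label mask: outer-compartment channel on the left
    quarter (label 1), central compartment as a centered block (label 2)."""
    h, w = image_shape
    mask = np.zeros((h, w), dtype=np.uint8)
    mask[:, : w // 4] = OUTER_LABEL
    h0, h1 = h // 4, h - h // 4
    w0, w1 = w // 2, w // 2 + w // 4
    mask[h0:h1, w0:w1] = CENTRAL_LABEL
    return mask


def chip_frame_times(cfg: ChipSimConfig) -> np.ndarray:
    n = int(round(cfg.total_duration / cfg.frame_interval)) + 1
    return np.arange(n, dtype=float) * cfg.frame_interval


def true_ratio(cfg: ChipSimConfig, times: np.ndarray) -> np.ndarray:
    """Noise-free uptake ratio (C_CC + C_PF) / C_PF at each acquisition time."""
    t = np.asarray(times, dtype=float)
    return cfg.intercept_oc + cfg.true_kin * np.maximum(0.0, t - cfg.steady_state_delay)


@dataclass(frozen=True)
class ChipSimResult:
    """Image stack, ROI mask and ground truth for one simulated chip."""

    stack: np.ndarray          # (n_frames, h, w) float
    mask: np.ndarray           # (h, w) uint8 labels
    times: np.ndarray          # minutes from experiment start
    truth: pd.DataFrame        # per-frame noise-free ratio and ROI sums
    config: ChipSimConfig

    @property
    def true_kin(self) -> float:
        return self.config.true_kin


def simulate_chip_stack(cfg: ChipSimConfig) -> ChipSimResult:
    """Render a chip fluorescence time series realising the linear uptake law.

    The outer-compartment ROI holds constant per-pixel intensity
    ``outer_intensity``; central-ROI pixels are set so the compartment sum
    satisfies ``C_CC = C_PF * (ratio(t) - 1)``.  Per-pixel N(0, noise_sd)
    detector noise is added to every pixel of every frame.
    """
    rng = np.random.default_rng(cfg.seed)
    mask = chip_roi_mask(cfg.image_shape)
    times = chip_frame_times(cfg)
    n_outer = int((mask == OUTER_LABEL).sum())
    n_central = int((mask == CENTRAL_LABEL).sum())
    outer_sum = cfg.outer_intensity * n_outer

    ratios = true_ratio(cfg, times)
    central_px = outer_sum * (ratios - 1.0) / n_central  # per-pixel central value

    h, w = cfg.image_shape
    stack = np.zeros((times.size, h, w), dtype=float)
    stack[:, mask == OUTER_LABEL] = cfg.outer_intensity
    for i in range(times.size):
        stack[i, mask == CENTRAL_LABEL] = central_px[i]
    if cfg.noise_sd > 0:
        stack += rng.normal(0.0, cfg.noise_sd, size=stack.shape)

    truth = pd.DataFrame(
        {
            "time_min": times,
            "true_ratio": ratios,
            "c_pf_sum": outer_sum,
            "c_cc_sum": outer_sum * (ratios - 1.0),
        }
    )
    truth.attrs["true_kin"] = cfg.true_kin
    truth.attrs["intercept_oc"] = cfg.intercept_oc
    truth.attrs["steady_state_delay"] = cfg.steady_state_delay
    return ChipSimResult(stack=stack, mask=mask, times=times, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# section generator


def activity_to_intensity(cfg: SectionSimConfig, activity) -> np.ndarray:
    """The generator's intensity-response map (noise-free)."""
    a = np.asarray(activity, dtype=float)
    p = cfg.map_params
    if cfg.map_form == "linear":
        return p["gain"] * a + p["offset"]
    imax = p.get("imax", 8000.0)
    scale = p.get("scale", 20.0)
    offset = p.get("offset", 100.0)
    return offset + imax * (1.0 - np.exp(-a / scale))


def _draw_group_folds(cfg: SectionSimConfig, groups: np.ndarray, rng) -> np.ndarray:
    """Draw fold values from per-group normals truncated to the class interval."""
    cutoff = cfg.fold_cutoff_low
    bounds = {
        "low": (1e-9, cutoff),
        "intermediate": (cutoff, 2.0),
        "medium": (2.0, 4.0),
        "high": (4.0, np.inf),
    }
    folds = np.empty(groups.size, dtype=float)
    for name in PERM_CLASSES:
        idx = np.flatnonzero(groups == name)
        if idx.size == 0:
            continue
        mean, sd = cfg.group_fold_params[name]
        lo, hi = bounds[name]
        if lo >= hi:
            raise GenerationError(
                f"class interval for '{name}' is empty under cutoff {cutoff:.3g}"
            )
        if sd == 0:
            val = min(max(mean, lo), np.nextafter(hi, lo)) if np.isfinite(hi) else max(mean, lo)
            folds[idx] = val
            continue
        a, b = (lo - mean) / sd, (hi - mean) / sd
        folds[idx] = sstats.truncnorm.rvs(
            a, b, loc=mean, scale=sd, size=idx.size, random_state=rng
        )
    return folds


def _place_disks(radii: np.ndarray, shape: Tuple[int, int], rng,
                 max_tries_per_lesion: int = 200) -> np.ndarray:
    """Rejection-sample non-overlapping disk centers; (n, 2) row/col array."""
    h, w = shape
    centers: List[Tuple[float, float]] = []
    placed_r: List[float] = []
    for r in radii:
        ok = False
        for _ in range(max_tries_per_lesion):
            row = rng.uniform(r + 2, h - r - 2)
            col = rng.uniform(r + 2, w - r - 2)
            if all(
                (row - rr) ** 2 + (col - cc) ** 2 > (r + pr + 2.0) ** 2
                for (rr, cc), pr in zip(centers, placed_r)
            ):
                ok = True
                break
        if not ok:
            raise GenerationError(
                f"could not place lesion of radius {r:.1f}px without overlap"
            )
        centers.append((row, col))
        placed_r.append(float(r))
    return np.asarray(centers, dtype=float).reshape(-1, 2)


@dataclass(frozen=True)
class SectionSimResult:
    """One simulated brain section: image triplet, standards and truth table."""

    marker: np.ndarray          # tumor-marker channel (lesions bright)
    texas_red: np.ndarray       # Texas Red channel, linear in activity (zero offset)
    autoradiograph: np.ndarray  # digitised QAR image via the intensity map
    standards_strip: np.ndarray  # one square patch per calibration standard
    standards: pd.DataFrame     # activity_nCi_per_g, intensity_au (measured)
    truth: pd.DataFrame         # per-lesion ground truth
    lesion_mask: np.ndarray     # integer labels, 0 = background
    config: SectionSimConfig


def simulate_section_set(cfg: SectionSimConfig) -> SectionSimResult:
    """Render the co-registered section triplet plus calibration standards.

    Lesions are uniform disks: internal texture is irrelevant to ROI-sum
    statistics, so disks are the simplest shape that still exercises
    segmentation, area and fold recovery.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_shape

    groups = rng.choice(
        np.asarray(PERM_CLASSES, dtype=object),
        size=cfg.n_lesions,
        p=np.asarray(cfg.group_weights, dtype=float),
    ).astype(str)
    folds = _draw_group_folds(cfg, groups, rng)
    areas_mm2 = rng.uniform(*cfg.lesion_area_range, size=cfg.n_lesions)
    radii_px = np.sqrt(areas_mm2 / np.pi) / cfg.pixel_size
    # largest first eases packing
    order = np.argsort(radii_px)[::-1]
    centers = np.zeros((cfg.n_lesions, 2), dtype=float)
    if cfg.n_lesions:
        centers[order] = _place_disks(radii_px[order], (h, w), rng)

    lesion_mask = np.zeros((h, w), dtype=np.int32)
    activity = np.full((h, w), cfg.normal_mean, dtype=float)
    rows_idx, cols_idx = np.ogrid[:h, :w]
    records = []
    for i in range(cfg.n_lesions):
        r = radii_px[i]
        cy, cx = centers[i]
        disk = (rows_idx - cy) ** 2 + (cols_idx - cx) ** 2 <= r**2
        lesion_mask[disk] = i + 1
        activity[disk] = cfg.normal_mean * folds[i]
        records.append(
            {
                "lesion_id": i + 1,
                "row": cy,
                "col": cx,
                "radius_px": r,
                "area_px": int(disk.sum()),
                "area_mm2": float(disk.sum()) * cfg.pixel_size**2,
                "fold_increase": folds[i],
                "group": groups[i],
            }
        )

    truth = pd.DataFrame(
        records,
        columns=[
            "lesion_id", "row", "col", "radius_px", "area_px",
            "area_mm2", "fold_increase", "group",
        ],
    )
    truth.attrs["normal_mean"] = cfg.normal_mean
    truth.attrs["normal_sd"] = cfg.normal_sd
    truth.attrs["fold_cutoff_low"] = cfg.fold_cutoff_low

    marker = np.where(lesion_mask > 0, cfg.marker_intensity, 0.0)
    texas_red = cfg.tr_background * activity / cfg.normal_mean
    autorad = activity_to_intensity(cfg, activity)

    acts = np.asarray(cfg.standard_activities, dtype=float)
    patch = 16
    strip = np.repeat(
        activity_to_intensity(cfg, acts)[:, None], patch * patch, axis=1
    ).reshape(acts.size * patch, patch).astype(float)

    if cfg.noise_sd > 0:
        marker = marker + rng.normal(0.0, cfg.noise_sd, size=marker.shape)
        texas_red = texas_red + rng.normal(0.0, cfg.noise_sd, size=texas_red.shape)
        autorad = autorad + rng.normal(0.0, cfg.noise_sd, size=autorad.shape)
        strip = strip + rng.normal(0.0, cfg.noise_sd, size=strip.shape)

    measured_int = strip.reshape(acts.size, patch * patch).mean(axis=1)
    standards = pd.DataFrame(
        {"activity_nCi_per_g": acts, "intensity_au": measured_int}
    )

    return SectionSimResult(
        marker=marker,
        texas_red=texas_red,
        autoradiograph=autorad,
        standards_strip=strip,
        standards=standards,
        truth=truth,
        lesion_mask=lesion_mask,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# biodistribution generator


def simulate_biodistribution(cfg: BiodistSimConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Invert the %ID/g accounting chain into a raw gamma-counter table.

    Returns ``(counts_table, truth_table)``.  The counts table has columns
    (organ, cpm, weight_mg) as exported by a counter; the truth table holds
    the per-organ parameters the accounting stage should recover.
    ``cpm = (%ID/g / 100) * dose * weight * efficiency``, perturbed by
    multiplicative lognormal noise of the configured CV.
    """
    rng = np.random.default_rng(cfg.seed)
    rows, truth_rows = [], []

    def lognormal_factor(cv: float) -> float:
        if cv <= 0:
            return 1.0
        sigma = np.sqrt(np.log1p(cv**2))
        return float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))

    blood_nci_per_g = cfg.blood_activity
    for organ, (pct, weight_g, cv) in cfg.organ_params.items():
        activity_per_g = pct / 100.0 * cfg.injected_dose  # nCi/g
        cpm = nci_to_cpm(activity_per_g * weight_g, cfg.counter_efficiency)
        cpm = float(cpm) * lognormal_factor(cv)
        rows.append({"organ": organ, "cpm": cpm, "weight_mg": weight_g * 1000.0})
        truth_rows.append(
            {
                "organ": organ,
                "true_pct_id_per_g": pct,
                "weight_g": weight_g,
                "true_activity_nci_per_g": activity_per_g,
                "true_tissue_blood_ratio": activity_per_g / blood_nci_per_g
                if blood_nci_per_g > 0
                else np.nan,
            }
        )

    blood_cpm = float(
        nci_to_cpm(blood_nci_per_g * cfg.blood_weight_g, cfg.counter_efficiency)
    ) * lognormal_factor(cfg.blood_cv)
    rows.append({"organ": "blood", "cpm": blood_cpm, "weight_mg": cfg.blood_weight_g * 1000.0})
    truth_rows.append(
        {
            "organ": "blood",
            "true_pct_id_per_g": 100.0 * blood_nci_per_g / cfg.injected_dose,
            "weight_g": cfg.blood_weight_g,
            "true_activity_nci_per_g": blood_nci_per_g,
            "true_tissue_blood_ratio": 1.0,
        }
    )

    counts = pd.DataFrame(rows, columns=["organ", "cpm", "weight_mg"])
    truth = pd.DataFrame(truth_rows)
    truth.attrs["injected_dose"] = cfg.injected_dose
    truth.attrs["counter_efficiency"] = cfg.counter_efficiency
    return counts, truth
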