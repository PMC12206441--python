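"""Western-blot lane densitometry.

A lane image is collapsed to a 1-D migration profile, a rolling-minimum
(grey-opening) baseline is removed, and bands are detected as local maxima
near their expected apparent molecular weights — here the mature
(~45 kDa, complex-glycosylated) and immature (~43 kDa, core-glycosylated)
forms of the target channel plus an alpha-tubulin loading control.  Band
intensities are integrated over center +/- 3 sigma; lane expression is the
target total normalised to the loading band, and treatment/genotype effects
are expressed as fold changes against a reference condition so they are
invariant to exposure.

Quantification also accepts pre-integrated band tables (CSV), so the
normalisation and statistics stages can be exercised independently of peak
detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import find_peaks

__all__ = [
    "MWCalibration",
    "LaneProfile",
    "Band",
    "LaneQuant",
    "DegenerateDesignError",
    "extract_lane_profile",
    "subtract_background",
    "detect_and_integrate_bands",
    "band_ratio",
    "quantify_lane",
    "normalize_to_reference",
    "lane_table",
    "lanes_from_table",
]


class DegenerateDesignError(ValueError):
    """Band centers too close to resolve at the given band width."""


@dataclass(frozen=True)
class MWCalibration:
    """Monotone apparent-MW <-> migration-position map from a ladder.

    Piecewise-linear in log(MW), the standard behaviour of SDS-PAGE
    migration over the resolving range.  Positions must increase as MW
    decreases (smaller proteins run further).
    """

    ladder_kda: np.ndarray
    ladder_pos_px: np.ndarray

    def __post_init__(self):
        mw = np.asarray(self.ladder_kda, dtype=float)
        pos = np.asarray(self.ladder_pos_px, dtype=float)
        if mw.shape != pos.shape or mw.ndim != 1 or mw.size < 2:
            raise ValueError("ladder needs >= 2 (mw, position) points")
        order = np.argsort(mw)[::-1]  # descending MW = ascending position
        mw, pos = mw[order], pos[order]
        if np.any(np.diff(pos) <= 0):
            raise ValueError("ladder positions must increase monotonically as MW falls")
        object.__setattr__(self, "ladder_kda", mw)
        object.__setattr__(self, "ladder_pos_px", pos)

    def mw_to_pos(self, mw_kda: np.ndarray | float) -> np.ndarray | float:
        logmw = np.log(np.asarray(mw_kda, dtype=float))
        x = np.log(self.ladder_kda)[::-1]  # ascending log-MW
        y = self.ladder_pos_px[::-1]
        return np.interp(logmw, x, y)

    def pos_to_mw(self, pos_px: np.ndarray | float) -> np.ndarray | float:
        logmw = np.interp(
            np.asarray(pos_px, dtype=float), self.ladder_pos_px, np.log(self.ladder_kda)
        )
        return np.exp(logmw)


@dataclass(frozen=True)
class LaneProfile:
    """1-D lane intensity vs migration position (px)."""

    position: np.ndarray
    intensity: np.ndarray
    lane_id: str = ""
    calibration: MWCalibration | None = None

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if pos.shape != inten.shape or pos.ndim != 1:
            raise ValueError("position and intensity must be 1-D and equal length")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.all(np.isfinite(inten)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "intensity", inten)


@dataclass
class Band:
    """One detected (or flagged-absent) band."""

    label: str  # upper | lower | loading
    center_px: float
    apparent_mw_kda: float
    integrated_intensity: float
    absent: bool = False
    ambiguous: bool = False


@dataclass
class LaneQuant:
    """Per-lane quantification: band intensities and normalisations."""

    lane_id: str
    group: str = ""
    treatment: str = "none"
    upper: float = 0.0
    lower: float = 0.0
    loading: float = float("nan")
    flags: list = field(default_factory=list)

    @property
    def total_target(self) -> float:
        return self.upper + self.lower

    @property
    def norm_expression(self) -> float:
        return self.total_target / self.loading

    @property
    def ratio_upper_lower(self) -> float:
        return band_ratio(self)


def extract_lane_profile(
    image: np.ndarray,
    lane_bounds: tuple[int, int],
    lane_id: str = "",
    calibration: MWCalibration | None = None,
) -> LaneProfile:
    """Column-wise mean intensity across the lane width vs migration row."""
    img = np.asarray(image, dtype=float)
    x0, x1 = lane_bounds
    if not (0 <= x0 < x1 <= img.shape[1]):
        raise ValueError(f"lane bounds {lane_bounds} outside image width {img.shape[1]}")
    profile = img[:, x0:x1].mean(axis=1)
    return LaneProfile(
        position=np.arange(img.shape[0], dtype=float),
        intensity=profile,
        lane_id=lane_id,
        calibration=calibration,
    )


def subtract_background(
    profile: LaneProfile, band_sigma_px: float = 1.5, window_sigmas: float = 8.0
) -> LaneProfile:
    """Remove a rolling-minimum baseline and clip at zero.

    Grey opening (rolling minimum followed by rolling maximum over the same
    window) estimates the slowly varying baseline under peaks narrower than
    the window; under the bands themselves — where the opening is
    unreliable, e.g. biased by a tilted background — the baseline is
    linearly interpolated from the flanking band-free regions.  Adding a
    constant to the profile leaves the corrected profile unchanged.  The
    window must comfortably exceed the band width; the default is 8 band
    sigmas.
    """
    n = int(round(window_sigmas * band_sigma_px))
    if profile.intensity.size < 3 * max(n, 1):
        raise ValueError("profile too short relative to the background window")
    y = profile.intensity
    baseline = ndimage.grey_opening(y, size=max(n, 1))
    resid = y - baseline
    band = resid > max(3.0 * _robust_noise_sd(y), 1e-12 * max(y.max(), 1.0))
    if band.any():
        # opening hugs band tails (especially on a rising baseline), so keep
        # a guard margin of ~3 sigma around detected band regions out of the
        # anchor set before interpolating across them
        guard = int(np.ceil(3.0 * band_sigma_px))
        band = ndimage.binary_dilation(band, iterations=guard)
    nonband = ~band
    if nonband.any() and band.any():
        baseline = np.interp(
            profile.position, profile.position[nonband], baseline[nonband]
        )
    corrected = np.clip(y - baseline, 0.0, None)
    return LaneProfile(
        position=profile.position,
        intensity=corrected,
        lane_id=profile.lane_id,
        calibration=profile.calibration,
    )


def _robust_noise_sd(y: np.ndarray) -> float:
    # high-frequency MAD estimator; insensitive to the bands themselves
    d = np.diff(y)
    if d.size == 0:
        return 0.0
    return float(np.median(np.abs(d - np.median(d))) * 1.4826 / np.sqrt(2.0))


def detect_and_integrate_bands(
    profile: LaneProfile,
    expected_mws: dict[str, float],
    band_sigma_px: float = 1.5,
    mw_tol_kda: float = 2.0,
    floor_sigmas: float = 3.0,
) -> list[Band]:
    """Locate and integrate bands near their expected apparent MWs.

    Peaks are found on the (background-corrected) profile and each peak is
    attributed to the expected band whose calibrated position is nearest, so
    a neighbouring band sitting on the edge of another band's MW window is
    never double-counted.  A band takes its nearest attributed peak provided
    it lies within +/- ``mw_tol_kda`` and rises above the detection floor
    (``floor_sigmas`` x robust noise SD).  Intensities are sums over center
    +/- 3 band sigmas.  Missing bands report intensity 0 and are flagged
    absent; two candidate peaks inside one MW window break the tie toward
    the expected center and flag the band ambiguous.
    """
    if profile.calibration is None:
        raise ValueError("lane profile carries no ladder calibration")
    y = profile.intensity
    floor = floor_sigmas * _robust_noise_sd(y)
    peaks, _ = find_peaks(y, height=max(floor, 1e-12))
    half = int(np.ceil(3.0 * band_sigma_px))
    labels = list(expected_mws)
    centers = np.array([float(profile.calibration.mw_to_pos(expected_mws[l])) for l in labels])
    if peaks.size:
        nearest = np.argmin(
            np.abs(profile.position[peaks][:, None] - centers[None, :]), axis=1
        )
    else:
        nearest = np.empty(0, dtype=int)
    out: list[Band] = []
    for j, label in enumerate(labels):
        mw = expected_mws[label]
        center_expected = centers[j]
        lo = float(profile.calibration.mw_to_pos(mw + mw_tol_kda))
        hi = float(profile.calibration.mw_to_pos(mw - mw_tol_kda))
        mine = peaks[nearest == j]
        in_window = mine[(profile.position[mine] >= lo) & (profile.position[mine] <= hi)]
        ambiguous = in_window.size > 1
        if in_window.size == 0:
            out.append(
                Band(label=label, center_px=center_expected, apparent_mw_kda=mw,
                     integrated_intensity=0.0, absent=True)
            )
            continue
        k = in_window[np.argmin(np.abs(profile.position[in_window] - center_expected))]
        c = int(k)
        seg = y[max(c - half, 0): c + half + 1]
        out.append(
            Band(
                label=label,
                center_px=float(profile.position[c]),
                apparent_mw_kda=float(profile.calibration.pos_to_mw(profile.position[c])),
                integrated_intensity=float(seg.sum()),
                ambiguous=ambiguous,
            )
        )
    return out


def band_ratio(lane: LaneQuant, detection_floor: float = 0.0) -> float:
    """Mature/immature (upper/lower) band ratio; NaN + flag when the lower
    band sits at or below the detection floor (never infinity)."""
    if lane.lower <= detection_floor:
        if "ratio_undefined" not in lane.flags:
            lane.flags.append("ratio_undefined")
        return float("nan")
    return lane.upper / lane.lower


def quantify_lane(
    profile: LaneProfile,
    lane_id: str | None = None,
    group: str = "",
    treatment: str = "none",
    band_sigma_px: float = 1.5,
    upper_mw_kda: float = 45.0,
    lower_mw_kda: float = 43.0,
    loading_mw_kda: float = 50.0,
) -> LaneQuant:
    """Full single-lane pipeline: background, band detection, LaneQuant."""
    corrected = subtract_background(profile, band_sigma_px=band_sigma_px)
    bands = detect_and_integrate_bands(
        corrected,
        {"loading": loading_mw_kda, "upper": upper_mw_kda, "lower": lower_mw_kda},
        band_sigma_px=band_sigma_px,
    )
    by_label = {b.label: b for b in bands}
    lq = LaneQuant(
        lane_id=lane_id if lane_id is not None else profile.lane_id,
        group=group,
        treatment=treatment,
        upper=by_label["upper"].integrated_intensity,
        lower=by_label["lower"].integrated_intensity,
        loading=by_label["loading"].integrated_intensity,
    )
    for b in bands:
        if b.absent:
            lq.flags.append(f"{b.label}_absent")
        if b.ambiguous:
            lq.flags.append(f"{b.label}_ambiguous")
    return lq


def lane_table(lanes: Iterable[LaneQuant]) -> pd.DataFrame:
    """Tabulate LaneQuant objects (one row per lane)."""
    rows = []
    for lq in lanes:
        rows.append(
            {
                "lane_id": lq.lane_id,
                "group": lq.group,
                "treatment": lq.treatment,
                "upper": lq.upper,
                "lower": lq.lower,
                "total_target": lq.total_target,
                "loading": lq.loading,
                "norm_expression": lq.norm_expression,
                "ratio_upper_lower": band_ratio(lq),
                "flags": ";".join(lq.flags),
            }
        )
    return pd.DataFrame(rows)


def lanes_from_table(df: pd.DataFrame) -> list[LaneQuant]:
    """Build LaneQuant objects from a pre-integrated band table.

    Expected columns: lane_id, group, treatment, upper, lower, loading.
    """
    required = {"lane_id", "upper", "lower", "loading"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"band table is missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            LaneQuant(
                lane_id=str(row["lane_id"]),
                group=str(row.get("group", "")),
                treatment=str(row.get("treatment", "none")),
                upper=float(row["upper"]),
                lower=float(row["lower"]),
                loading=float(row["loading"]),
            )
        )
    return out


def normalize_to_reference(
    lanes: Sequence[LaneQuant] | pd.DataFrame,
    reference_selector: Callable[[pd.Series], bool] | tuple[str, str] | str = ("WT", "none"),
) -> pd.DataFrame:
    """Fold change of loading-normalised expression against a reference.

    Each lane's ``norm_expression`` (target total / loading) is divided by
    the mean ``norm_expression`` of the reference lanes, so the reference
    condition averages 1.0 and fold changes are invariant to global
    exposure.  The reference is a (group, treatment) pair, a group name, or
    a row predicate; non-transfected (NT) lanes never enter the reference.
    """
    df = lanes if isinstance(lanes, pd.DataFrame) else lane_table(lanes)
    if isinstance(reference_selector, str):
        reference_selector = (reference_selector, "none")
    if isinstance(reference_selector, tuple):
        grp, trt = reference_selector
        mask = (df["group"] == grp) & (df["treatment"] == trt)
    else:
        mask = df.apply(reference_selector, axis=1)
    mask &= df["group"] != "NT"
    if not mask.any():
        raise ValueError("no reference lanes matched the selector")
    ref_mean = df.loc[mask, "norm_expression"].mean()
    if not np.isfinite(ref_mean) or ref_mean == 0:
        raise ValueError("reference lanes have undefined or zero normalised expression")
    out = df.copy()
    out["fold_change"] = out["norm_expression"] / ref_mean
    return out
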