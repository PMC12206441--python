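"""Synthetic western-blot lanes with known band amounts.

Each lane is a small 2-D intensity patch carrying three Gaussian bands on a
tilted baseline: the mature (~45 kDa) and immature (~43 kDa) glycoforms of
the target channel, split by ``upper_frac``, plus an alpha-tubulin loading
control (~50 kDa).  Band positions come from the same monotone
log(MW) -> position calibration the densitometry stage fits to a ladder, so
generated lanes and the analysis agree on where bands run.

Default lane presets: the mutant lane carries 0.40x the wild-type target
abundance (both glycoforms scaled alike), and the enzymatic-deglycosylation
preset collapses the signal into the lower band (upper_frac <= 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ..densitometry import DegenerateDesignError, MWCalibration
from ..presets import load_presets

__all__ = [
    "BlotSimParams",
    "BlotGroundTruth",
    "default_ladder",
    "simulate_blot",
    "blot_preset",
    "BLOT_PRESET_NAMES",
]


@dataclass(frozen=True)
class BlotSimParams:
    """Parameters of one simulated lane."""

    abundance: float  # integrated target signal (upper + lower), a.u.
    upper_frac: float = 0.7  # fraction of target signal in the mature band
    tubulin_amount: float = 200.0
    background_level: float = 30.0
    background_tilt: float = 0.02  # a.u. per px along the migration axis
    band_sigma_px: float = 1.5
    noise_sd: float = 1.5
    seed: int = 0
    lane_id: str = ""
    group: str = ""
    treatment: str = "none"
    upper_mw_kda: float = 45.0
    lower_mw_kda: float = 43.0
    loading_mw_kda: float = 50.0
    lane_length_px: int = 900
    lane_width_px: int = 40

    def __post_init__(self):
        if not 0.0 <= self.upper_frac <= 1.0:
            raise ValueError("upper_frac must lie in [0, 1]")
        if self.abundance < 0:
            raise ValueError("abundance must be non-negative")
        if self.band_sigma_px <= 0:
            raise ValueError("band_sigma_px must be positive")
        if len({self.upper_mw_kda, self.lower_mw_kda, self.loading_mw_kda}) != 3:
            raise ValueError("band molecular weights must be distinct")


@dataclass(frozen=True)
class BlotGroundTruth:
    """Per-lane true integrated band amounts."""

    lanes: pd.DataFrame  # lane_id, group, treatment, true_upper, true_lower, true_loading


def default_ladder(
    ladder_kda: Sequence[float] | None = None,
    lane_length_px: int = 900,
    margin_px: int = 20,
) -> MWCalibration:
    """Ladder calibration linear in log(MW) across the resolving range."""
    if ladder_kda is None:
        ladder_kda = load_presets()["blot"]["shared"]["ladder_kda"]
    mw = np.sort(np.asarray(ladder_kda, dtype=float))[::-1]
    logmw = np.log(mw)
    span = lane_length_px - 2 * margin_px
    pos = margin_px + span * (logmw[0] - logmw) / (logmw[0] - logmw[-1])
    return MWCalibration(ladder_kda=mw, ladder_pos_px=pos)


def _render_lane(params: BlotSimParams, ladder: MWCalibration, rng) -> np.ndarray:
    sigma = params.band_sigma_px
    centers = {
        "upper": float(ladder.mw_to_pos(params.upper_mw_kda)),
        "lower": float(ladder.mw_to_pos(params.lower_mw_kda)),
        "loading": float(ladder.mw_to_pos(params.loading_mw_kda)),
    }
    cs = sorted(centers.values())
    gaps = np.diff(cs)
    if np.any(gaps < 3.0 * sigma):
        raise DegenerateDesignError(
            f"band centers {np.round(cs, 1).tolist()} px closer than "
            f"3 x band_sigma ({3 * sigma:.1f} px); bands unresolvable"
        )
    amounts = {
        "upper": params.abundance * params.upper_frac,
        "lower": params.abundance * (1.0 - params.upper_frac),
        "loading": params.tubulin_amount,
    }
    y = np.arange(params.lane_length_px, dtype=float)
    profile = params.background_level + params.background_tilt * y
    norm = sigma * np.sqrt(2.0 * np.pi)
    for name, c in centers.items():
        profile += amounts[name] / norm * np.exp(-0.5 * ((y - c) / sigma) ** 2)
    lane = np.tile(profile[:, None], (1, params.lane_width_px))
    if params.noise_sd > 0:
        lane = lane + rng.normal(0.0, params.noise_sd, size=lane.shape)
    return np.clip(lane, 0.0, None)


def simulate_blot(
    params_per_lane: Sequence[BlotSimParams],
    ladder: MWCalibration | None = None,
) -> tuple[np.ndarray, MWCalibration, BlotGroundTruth]:
    """Render a stack of lane images plus per-lane ground truth.

    Returns (stack, ladder, truth) where ``stack`` has shape
    (n_lanes, lane_length_px, lane_width_px).  A fixed per-lane seed makes
    the stack bit-reproducible.
    """
    if len(params_per_lane) < 1:
        raise ValueError("at least one lane is required")
    if ladder is None:
        ladder = default_ladder(lane_length_px=params_per_lane[0].lane_length_px)
    lanes = []
    rows = []
    for p in params_per_lane:
        rng = np.random.default_rng(p.seed)
        lanes.append(_render_lane(p, ladder, rng))
        rows.append(
            {
                "lane_id": p.lane_id,
                "group": p.group,
                "treatment": p.treatment,
                "true_upper": p.abundance * p.upper_frac,
                "true_lower": p.abundance * (1.0 - p.upper_frac),
                "true_loading": p.tubulin_amount,
                "true_total": p.abundance,
            }
        )
    return np.stack(lanes), ladder, BlotGroundTruth(lanes=pd.DataFrame(rows))


BLOT_PRESET_NAMES = ("NT", "WT", "MT", "WT_PNGaseF", "MT_PNGaseF", "WT_EndoH", "MT_EndoH")


def blot_preset(
    name: str,
    seed: int = 0,
    lane_id: str | None = None,
    jitter_abundance: bool = True,
    **overrides,
) -> BlotSimParams:
    """Default lane presets (genotype x treatment).

    ``jitter_abundance`` applies the preset's lane-to-lane coefficient of
    variation to the target abundance, emulating biological-replicate and
    loading variability; the loading control is jittered with the same CV.
    """
    cfg = load_presets()["blot"]
    try:
        lane = cfg["lanes"][name]
    except KeyError:
        raise KeyError(
            f"unknown blot preset {name!r}; available: {sorted(cfg['lanes'])}"
        ) from None
    sh = cfg["shared"]
    group = name.split("_")[0]
    treatment = name.split("_", 1)[1] if "_" in name else "none"
    abundance = float(lane["abundance"])
    tubulin = float(sh["tubulin_amount"])
    if jitter_abundance and abundance > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0B107]))
        cv = float(sh["abundance_cv"])
        abundance *= max(1.0 + cv * rng.standard_normal(), 0.1)
        tubulin *= max(1.0 + cv * rng.standard_normal(), 0.1)
    params = BlotSimParams(
        abundance=abundance,
        upper_frac=float(lane["upper_frac"]),
        tubulin_amount=tubulin,
        background_level=float(sh["background_level"]),
        background_tilt=float(sh["background_tilt"]),
        band_sigma_px=float(sh["band_sigma_px"]),
        noise_sd=float(sh["noise_sd"]),
        seed=seed,
        lane_id=lane_id if lane_id is not None else f"{name}-{seed}",
        group=group,
        treatment=treatment,
        upper_mw_kda=float(sh["upper_mw_kda"]),
        lower_mw_kda=float(sh["lower_mw_kda"]),
        loading_mw_kda=float(sh["loading_mw_kda"]),
        lane_length_px=int(sh["lane_length_px"]),
        lane_width_px=int(sh["lane_width_px"]),
    )
    if overrides:
        params = replace(params, **overrides)
    return params
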