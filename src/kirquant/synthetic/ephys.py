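"""Synthetic whole-cell ramp recordings with known Kir conductance.

The voltage protocol mirrors the recording convention for inward-rectifier
currents: a 400 ms ramp from +150 to -150 mV from a holding potential of
0 mV, sampled at 10 kHz.  The membrane current is modelled as a rectified
Kir conductance plus an ohmic leak,

    i(V) = [g_kir * r(V) * (V - E_rev) + g_leak * V] * C_m + noise,

with Boltzmann rectification r(V) = 1 / (1 + exp((V - Vh) / k)).  No
mechanistic gating model is implied — any smooth monotone inward-rectifying
shape exercises the analysis pipeline; the Boltzmann form gives
two-parameter control over midpoint and steepness.  Ba2+ scales g_kir by
(1 - ba_block_frac) and leaves the leak untouched, so the control-minus-Ba2+
difference isolates exactly the blocked Kir component.  Leak reverses at
0 mV, consistent with a near-symmetrical K+ bath.

Ground truth: the Ba2+-sensitive current density at -150 mV of each cell is

    CD = g_kir * ba_block_frac * r(-150) * (-150 - E_rev)   [pA/pF],

which the presets invert to place group-mean CD at the calibration targets
(between-cell SD enters through a normal spread on g_kir).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ..ephys import RampRecording
from ..presets import load_presets

__all__ = [
    "EphysSimParams",
    "EphysGroundTruth",
    "boltzmann_rectification",
    "build_ramp_command",
    "true_current_density",
    "simulate_ramp_pair",
    "ephys_preset",
    "EPHYS_PRESET_NAMES",
]


def boltzmann_rectification(
    v_mv: np.ndarray | float, vhalf_mv: float, slope_mv: float | None
) -> np.ndarray | float:
    """Rectification factor r(V) in (0, 1); ``slope_mv`` of None or 0 disables
    rectification (r identically 1)."""
    if slope_mv is None or slope_mv == 0:
        return np.ones_like(np.asarray(v_mv, dtype=float)) if np.ndim(v_mv) else 1.0
    return 1.0 / (1.0 + np.exp((np.asarray(v_mv, dtype=float) - vhalf_mv) / slope_mv))


@dataclass(frozen=True)
class EphysSimParams:
    """Parameters of one simulated recording group.

    ``g_kir`` and ``g_leak`` are conductance densities (nS/pF); the
    whole-cell current scales with each cell's capacitance.  ``g_kir_sd``
    is the between-cell SD of g_kir — the generator places all biological
    variability between cells, with sweep-level noise purely additive.
    """

    g_kir: float  # nS/pF, group mean
    e_rev: float = -5.0  # mV
    rect_vhalf: float = -10.0  # mV
    rect_slope: float | None = 25.0  # mV; None/0 disables rectification
    g_leak: float = 0.05  # nS/pF, reverses at 0 mV
    ba_block_frac: float = 0.95
    capacitance_pf: float = 12.0
    noise_sd_pa: float = 10.0
    n_cells: int = 5
    seed: int = 0
    g_kir_sd: float = 0.0  # nS/pF, between-cell
    capacitance_jitter_frac: float = 0.0
    group: str = "other"
    # protocol
    ramp_ms: float = 400.0
    hold_ms: float = 50.0
    v_start_mv: float = 150.0
    v_end_mv: float = -150.0
    v_hold_mv: float = 0.0
    sampling_hz: float = 10_000.0

    def __post_init__(self):
        for name in ("g_kir", "e_rev", "g_leak", "ba_block_frac", "capacitance_pf",
                     "noise_sd_pa", "g_kir_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0.0 <= self.ba_block_frac <= 1.0:
            raise ValueError("ba_block_frac must lie in [0, 1]")
        if self.capacitance_pf <= 0:
            raise ValueError("capacitance_pf must be positive")
        if self.g_kir < 0 or self.g_leak < 0:
            raise ValueError("conductance densities must be non-negative")
        if self.n_cells < 1:
            raise ValueError("n_cells must be at least 1")


@dataclass(frozen=True)
class EphysGroundTruth:
    """Per-cell generating values for a simulated group."""

    cells: pd.DataFrame  # cell_id, group, g_kir, capacitance_pf, true_cd_pa_per_pf
    params: EphysSimParams


def build_ramp_command(params: EphysSimParams) -> tuple[np.ndarray, np.ndarray]:
    """Time (s) and command voltage (mV): hold, descending ramp, hold."""
    dt = 1.0 / params.sampling_hz
    n_hold = int(round(params.hold_ms * 1e-3 * params.sampling_hz))
    n_ramp = int(round(params.ramp_ms * 1e-3 * params.sampling_hz))
    v = np.concatenate(
        [
            np.full(n_hold, params.v_hold_mv),
            np.linspace(params.v_start_mv, params.v_end_mv, n_ramp),
            np.full(n_hold, params.v_hold_mv),
        ]
    )
    t = np.arange(v.size) * dt
    return t, v


def true_current_density(params: EphysSimParams, g_kir: float | None = None) -> float:
    """Ground-truth Ba2+-sensitive current density at -150 mV (pA/pF)."""
    g = params.g_kir if g_kir is None else g_kir
    r = boltzmann_rectification(-150.0, params.rect_vhalf, params.rect_slope)
    return float(g * params.ba_block_frac * r * (-150.0 - params.e_rev))


def _membrane_current(
    v: np.ndarray, g_kir: float, params: EphysSimParams, cap_pf: float
) -> np.ndarray:
    r = boltzmann_rectification(v, params.rect_vhalf, params.rect_slope)
    dens = g_kir * r * (v - params.e_rev) + params.g_leak * (v - 0.0)
    return dens * cap_pf  # nS/pF * mV * pF = pA


def simulate_ramp_pair(
    params: EphysSimParams,
) -> tuple[list[tuple[RampRecording, RampRecording]], EphysGroundTruth]:
    """Simulate paired control / Ba2+ ramp sweeps for each cell of a group.

    Returns the list of (control, ba2+) pairs and the per-cell ground
    truth.  A fixed seed reproduces traces and truth bit for bit.
    """
    rng = np.random.default_rng(params.seed)
    t, v = build_ramp_command(params)
    pairs: list[tuple[RampRecording, RampRecording]] = []
    rows = []
    for c in range(params.n_cells):
        g_kir_c = max(float(rng.normal(params.g_kir, params.g_kir_sd)), 0.0)
        jit = params.capacitance_jitter_frac
        cap_c = params.capacitance_pf * (1.0 + (rng.uniform(-jit, jit) if jit else 0.0))
        cell_id = f"{params.group}-cell{c + 1:02d}"
        i_ctrl = _membrane_current(v, g_kir_c, params, cap_c)
        i_ba = _membrane_current(v, g_kir_c * (1.0 - params.ba_block_frac), params, cap_c)
        if params.noise_sd_pa > 0:
            i_ctrl = i_ctrl + rng.normal(0.0, params.noise_sd_pa, size=v.size)
            i_ba = i_ba + rng.normal(0.0, params.noise_sd_pa, size=v.size)
        common = dict(
            time=t, v_cmd=v, capacitance_pf=cap_c, cell_id=cell_id,
            sampling_hz=params.sampling_hz, group=params.group,
        )
        pairs.append(
            (
                RampRecording(i=i_ctrl, condition="control", **common),
                RampRecording(i=i_ba, condition="ba2+", **common),
            )
        )
        rows.append(
            {
                "cell_id": cell_id,
                "group": params.group,
                "g_kir_ns_per_pf": g_kir_c,
                "capacitance_pf": cap_c,
                "true_cd_pa_per_pf": true_current_density(params, g_kir_c),
            }
        )
    return pairs, EphysGroundTruth(cells=pd.DataFrame(rows), params=params)


EPHYS_PRESET_NAMES = ("WT", "MT", "WT+MT")


def ephys_preset(name: str, seed: int = 0, **overrides) -> EphysSimParams:
    """Default recording-group presets calibrated to the study group values.

    The preset's true group-mean current density at -150 mV equals the
    calibration target for that group (WT, MT or WT+MT), with matching
    between-cell SD; g_kir is solved from the target given the shared
    biophysical parameters.
    """
    cfg = load_presets()["ephys"]
    try:
        grp = cfg["groups"][name]
    except KeyError:
        raise KeyError(
            f"unknown ephys preset {name!r}; available: {sorted(cfg['groups'])}"
        ) from None
    shared = cfg["shared"]
    base = EphysSimParams(
        g_kir=1.0,
        e_rev=shared["e_rev_mv"],
        rect_vhalf=shared["rect_vhalf_mv"],
        rect_slope=shared["rect_slope_mv"],
        g_leak=shared["g_leak_ns_per_pf"],
        ba_block_frac=shared["ba_block_frac"],
        capacitance_pf=shared["capacitance_pf"],
        noise_sd_pa=shared["noise_sd_pa"],
        capacitance_jitter_frac=shared["capacitance_jitter_frac"],
        n_cells=grp["n_cells"],
        seed=seed,
        group=name,
    )
    # scale factor from g_kir to CD at -150 mV
    k = true_current_density(base, g_kir=1.0)
    params = replace(
        base,
        g_kir=grp["cd_mean_pa_per_pf"] / k,
        g_kir_sd=abs(grp["cd_sd_pa_per_pf"] / k),
    )
    if overrides:
        params = replace(params, **overrides)
    return params
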