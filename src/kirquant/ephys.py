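"""Ba2+-subtraction analysis of whole-cell voltage-ramp recordings.

Inward-rectifier (Kir) currents are isolated pharmacologically: the same
voltage ramp is applied to a cell under control conditions and in the
presence of extracellular Ba2+, which blocks Kir channels.  The
control-minus-Ba2+ difference trace is the Ba2+-sensitive current.  From it
we derive

* current density at -150 mV (pA/pF), normalising whole-cell current to
  membrane capacitance so cells of different size are comparable;
* the reversal potential V_rev, the zero-crossing of the difference
  current, expected near the K+ Nernst potential for the recording
  solutions;
* the chord conductance G(V) = I_Ba2+-sensitive / (V - V_rev), evaluated on
  the hyperpolarised limb between -140 and -20 mV.

Recordings enter as :class:`RampRecording` objects; pairs of recordings are
matched by ``cell_id`` and must share the command waveform sample for
sample.  The ramp segment is located from the slope of the command voltage
rather than fixed sample indices, so CSV exports from different acquisition
systems are handled uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

__all__ = [
    "RampRecording",
    "DifferenceTrace",
    "ChordConductanceCurve",
    "CellCurrentSummary",
    "nernst_potential",
    "ba_sensitive_current",
    "current_density",
    "reversal_potential",
    "chord_conductance",
    "summarize_groups",
    "analyze_pair",
]

#: Gas constant (J / mol / K)
_R = 8.314462618
#: Faraday constant (C / mol)
_F = 96485.33212

# Composition of the standard recording solutions (mM K+).
K_IN_MM = 140.0
K_OUT_MM = 115.0


@dataclass(frozen=True)
class RampRecording:
    """One voltage-ramp sweep from one cell under one condition."""

    time: np.ndarray  # s, strictly increasing
    v_cmd: np.ndarray  # mV
    i: np.ndarray  # pA
    capacitance_pf: float
    condition: Literal["control", "ba2+"]
    cell_id: str
    sampling_hz: float = 10_000.0
    group: str = "other"

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.v_cmd, dtype=float)
        i = np.asarray(self.i, dtype=float)
        if not (t.shape == v.shape == i.shape):
            raise ValueError("time, v_cmd and i must have identical shape")
        if t.ndim != 1 or t.size < 2:
            raise ValueError("a recording needs at least two samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.isfinite(self.capacitance_pf) or self.capacitance_pf <= 0:
            raise ValueError("capacitance_pf must be a positive finite number")
        if self.condition not in ("control", "ba2+"):
            raise ValueError(f"unknown condition {self.condition!r}")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "v_cmd", v)
        object.__setattr__(self, "i", i)

    def ramp_slice(self, min_span_mv: float = 100.0) -> slice:
        """Locate the descending ramp segment from the command slope.

        Returns the longest contiguous run of samples whose command voltage
        falls monotonically; the run must span at least ``min_span_mv``.
        """
        dv = np.diff(self.v_cmd)
        falling = dv < 0
        best = None
        start = None
        for k, f in enumerate(falling):
            if f and start is None:
                start = k
            elif not f and start is not None:
                if best is None or k - start > best[1] - best[0]:
                    best = (start, k)
                start = None
        if start is not None:
            if best is None or len(falling) - start > best[1] - best[0]:
                best = (start, len(falling))
        if best is None:
            raise ValueError("no descending ramp segment found in v_cmd")
        sl = slice(best[0], best[1] + 1)
        span = self.v_cmd[sl.start] - self.v_cmd[sl.stop - 1]
        if span < min_span_mv:
            raise ValueError(
                f"descending segment spans only {span:.1f} mV "
                f"(< {min_span_mv} mV); not a ramp"
            )
        return sl


@dataclass(frozen=True)
class DifferenceTrace:
    """Ba2+-sensitive current: control minus Ba2+ over the ramp segment."""

    v: np.ndarray  # mV
    i_diff: np.ndarray  # pA
    cell_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.v, dtype=float)
        i = np.asarray(self.i_diff, dtype=float)
        if v.shape != i.shape or v.ndim != 1:
            raise ValueError("v and i_diff must be 1-D arrays of equal length")
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "i_diff", i)


@dataclass(frozen=True)
class ChordConductanceCurve:
    """Chord conductance G(V) on a voltage grid within [-140, -20] mV."""

    v: np.ndarray  # mV
    g: np.ndarray  # nS
    v_rev: float  # mV
    cell_id: str = ""


@dataclass
class CellCurrentSummary:
    """Per-cell readouts handed to the group summary and statistics."""

    cell_id: str
    cd_pa_per_pf: float
    v_rev: float
    group: str = "other"


def nernst_potential(
    k_out_mm: float = K_OUT_MM, k_in_mm: float = K_IN_MM, temp_c: float = 22.0
) -> float:
    """K+ equilibrium potential (mV) for the given solutions.

    E_K = (RT/F) ln([K+]_out / [K+]_in).  For 115 mM out / 140 mM in at
    22 degC this is about -5 mV, which serves as the proximity prior when a
    noisy difference trace has several zero crossings.
    """
    if k_out_mm <= 0 or k_in_mm <= 0:
        raise ValueError("K+ concentrations must be positive")
    t_k = temp_c + 273.15
    return 1000.0 * _R * t_k / _F * np.log(k_out_mm / k_in_mm)


def ba_sensitive_current(control: RampRecording, ba: RampRecording) -> DifferenceTrace:
    """Subtract the Ba2+ sweep from the control sweep over the ramp.

    The two recordings must come from the same cell and share the command
    waveform sample for sample; the Ba2+-sensitive current is
    ``i_control(V) - i_ba(V)``.
    """
    if control.cell_id != ba.cell_id:
        raise ValueError(
            f"paired recordings must share cell_id "
            f"({control.cell_id!r} != {ba.cell_id!r})"
        )
    if control.v_cmd.shape != ba.v_cmd.shape:
        raise ValueError("paired recordings have different lengths")
    if not np.allclose(control.v_cmd, ba.v_cmd, atol=1e-6):
        raise ValueError("paired recordings have mismatched command voltages")
    sl = control.ramp_slice()
    return DifferenceTrace(
        v=control.v_cmd[sl],
        i_diff=control.i[sl] - ba.i[sl],
        cell_id=control.cell_id,
    )


def current_density(
    diff: DifferenceTrace,
    capacitance_pf: float,
    at_mv: float = -150.0,
    window_mv: float = 1.0,
) -> float:
    """Current density (pA/pF) at ``at_mv``.

    Takes the local median of the difference current over ``at_mv`` +/-
    ``window_mv`` — robust to single-sample noise without biasing the
    estimate — and divides by the cell capacitance.  Inward current is
    negative by convention.
    """
    if not np.isfinite(capacitance_pf) or capacitance_pf <= 0:
        raise ValueError("capacitance_pf must be positive")
    if at_mv < diff.v.min() - window_mv or at_mv > diff.v.max() + window_mv:
        raise ValueError(f"{at_mv} mV lies outside the ramp span")
    mask = np.abs(diff.v - at_mv) <= window_mv
    if not np.any(mask):
        mask = np.abs(diff.v - at_mv) == np.abs(diff.v - at_mv).min()
    return float(np.median(diff.i_diff[mask]) / capacitance_pf)


def reversal_potential(
    diff: DifferenceTrace,
    prior_mv: float | None = None,
    smooth_samples: int = 21,
) -> float:
    """Reversal potential (mV): the zero crossing of the difference current.

    The trace is boxcar-smoothed, sign changes are located, and each
    crossing is refined by local linear interpolation.  With several
    crossings (noise around zero current) the one nearest ``prior_mv``
    (default: the K+ Nernst potential for the standard solutions) is
    returned.
    """
    if prior_mv is None:
        prior_mv = nernst_potential()
    order = np.argsort(diff.v, kind="stable")
    v = diff.v[order]
    i = diff.i_diff[order]
    if smooth_samples > 1 and i.size > smooth_samples:
        i = uniform_filter1d(i, size=smooth_samples, mode="nearest")
    sign = np.sign(i)
    nz = sign != 0
    crossings = []
    idx = np.nonzero(np.diff(sign[nz]) != 0)[0]
    vi = v[nz]
    ii = i[nz]
    for k in idx:
        v0, v1 = vi[k], vi[k + 1]
        i0, i1 = ii[k], ii[k + 1]
        crossings.append(v0 - i0 * (v1 - v0) / (i1 - i0))
    # exact zeros count as crossings too
    crossings.extend(v[~nz].tolist())
    if not crossings:
        raise ValueError(
            "difference current does not change sign over the ramp: "
            f"i ranges [{i.min():.3g}, {i.max():.3g}] pA; no reversal potential"
        )
    crossings = np.asarray(crossings)
    return float(crossings[np.argmin(np.abs(crossings - prior_mv))])


def chord_conductance(
    diff: DifferenceTrace,
    v_rev: float,
    v_min: float = -140.0,
    v_max: float = -20.0,
    step_mv: float = 2.0,
    exclusion_mv: float = 5.0,
) -> ChordConductanceCurve:
    """Chord conductance G(V) = I_Ba2+-sensitive(V) / (V - V_rev), in nS.

    Evaluated on a regular grid restricted to [v_min, v_max]; grid points
    within ``exclusion_mv`` of the reversal potential are dropped to avoid
    0/0 amplification.
    """
    grid = np.arange(v_min, v_max + 0.5 * step_mv, step_mv)
    grid = grid[np.abs(grid - v_rev) >= exclusion_mv]
    lo, hi = diff.v.min(), diff.v.max()
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size == 0:
        raise ValueError("empty chord-conductance evaluation window")
    order = np.argsort(diff.v, kind="stable")
    i_at = np.interp(grid, diff.v[order], diff.i_diff[order])
    g = i_at / (grid - v_rev)  # pA / mV == nS
    return ChordConductanceCurve(v=grid, g=g, v_rev=float(v_rev), cell_id=diff.cell_id)


def analyze_pair(
    control: RampRecording,
    ba: RampRecording,
    group: str | None = None,
) -> CellCurrentSummary:
    """Run the full per-cell pipeline: subtraction, V_rev, current density."""
    diff = ba_sensitive_current(control, ba)
    v_rev = reversal_potential(diff)
    cd = current_density(diff, control.capacitance_pf)
    return CellCurrentSummary(
        cell_id=control.cell_id,
        cd_pa_per_pf=cd,
        v_rev=v_rev,
        group=group if group is not None else control.group,
    )


_GROUP_ORDER = {"WT": 0, "MT": 1, "WT+MT": 2}


def summarize_groups(summaries: Iterable[CellCurrentSummary]) -> pd.DataFrame:
    """Per-group mean +/- SD of current density over cells.

    Groups are ordered WT, MT, WT+MT, then any others alphabetically.
    Single-cell groups report SD 0 and are flagged via ``n``.
    """
    rows = list(summaries)
    if not rows:
        raise ValueError("no cell summaries to aggregate")
    df = pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in rows],
            "group": [r.group for r in rows],
            "cd_pa_per_pf": [r.cd_pa_per_pf for r in rows],
            "v_rev_mv": [r.v_rev for r in rows],
        }
    )
    out = (
        df.groupby("group")["cd_pa_per_pf"]
        .agg(n="size", mean_cd_pa_per_pf="mean", sd_cd_pa_per_pf=lambda s: s.std(ddof=1))
        .reset_index()
    )
    out["sd_cd_pa_per_pf"] = out["sd_cd_pa_per_pf"].fillna(0.0)
    out["order"] = out["group"].map(lambda g: _GROUP_ORDER.get(g, 99))
    out = (
        out.sort_values(["order", "group"], kind="stable")
        .drop(columns="order")
        .reset_index(drop=True)
    )
    return out
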