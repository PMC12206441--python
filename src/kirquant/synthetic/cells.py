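"""Synthetic three-channel fluorescence fields with known trafficking truth.

Each field emulates a confocal section of transfected cells stained with a
nuclear dye, a plasma-membrane marker (Na+/K+-ATPase-like ring), and the
tagged target channel:

* channel 1 (nuclei): filled ellipses with dark intra-nuclear nucleoli
  spots, exercising the hole-filling step of nucleus segmentation;
* channel 2 (marker): a bright ring of configurable width at each cell
  boundary;
* channel 3 (target): per cell, ``membrane_fraction`` of its total
  intensity spread uniformly over the membrane ring and the remainder
  uniformly over the interior.

Ground truth records label masks (nucleus, whole cell, membrane ring) and
the per-cell membrane fraction and total expression, so segmentation and
quantification can be scored exactly.  With the non-overlap flag cells are
placed by rejection sampling with a minimum centre distance; placement
failure after a bounded number of attempts raises :class:`PlacementError`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ..image_quant import MultiChannelImage
from ..presets import load_presets

__all__ = [
    "CellFieldSimParams",
    "CellFieldGroundTruth",
    "PlacementError",
    "simulate_cell_field",
    "cell_field_preset",
    "CELL_PRESET_NAMES",
]


class PlacementError(RuntimeError):
    """Could not place the requested number of non-overlapping cells."""


@dataclass(frozen=True)
class CellFieldSimParams:
    """Parameters of one simulated field."""

    n_cells: int = 10
    nucleus_radius_px: float = 12.0
    cell_radius_px: float = 28.0
    membrane_width_px: int = 3
    total_expression: float = 50_000.0  # summed target intensity per cell, a.u.
    membrane_fraction: float = 0.6
    marker_intensity: float = 120.0
    nucleus_intensity: float = 150.0
    nucleoli_count: int = 2
    nucleoli_radius_px: float = 2.5
    nucleoli_contrast: float = 0.6  # fractional dimming of nucleoli spots
    noise_gaussian_sd: float = 2.0
    noise_poisson_scale: float = 0.0  # photons per a.u.; 0 disables shot noise
    image_shape: tuple[int, int] = (512, 512)
    non_overlap: bool = True
    radius_jitter_frac: float = 0.10
    expression_cv: float = 0.15  # between-cell spread of total expression
    seed: int = 0
    group: str = ""
    max_placement_attempts: int = 20_000

    def __post_init__(self):
        if not 0.0 <= self.membrane_fraction <= 1.0:
            raise ValueError("membrane_fraction must lie in [0, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be at least 1")
        if self.nucleus_radius_px + self.membrane_width_px >= self.cell_radius_px:
            raise ValueError("nucleus must fit strictly inside the cell interior")
        if self.membrane_width_px < 1:
            raise ValueError("membrane_width_px must be >= 1")


@dataclass(frozen=True)
class CellFieldGroundTruth:
    """True masks and per-cell values for one simulated field."""

    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    membrane_labels: np.ndarray  # ring mask, labelled per cell
    cells: pd.DataFrame  # cell_id, group, membrane_fraction, total_expression, ...


def _place_centers(params: CellFieldSimParams, rng) -> np.ndarray:
    h, w = params.image_shape
    rmax = params.cell_radius_px * (1.0 + params.radius_jitter_frac)
    margin = rmax + 2.0
    if 2 * margin >= min(h, w):
        raise PlacementError("image too small for even one cell at this radius")
    min_d = 2.0 * rmax + 2.0 if params.non_overlap else 0.0
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < params.n_cells:
        if attempts >= params.max_placement_attempts:
            raise PlacementError(
                f"placed only {len(centers)}/{params.n_cells} cells after "
                f"{attempts} attempts; field too crowded"
            )
        attempts += 1
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        if min_d and any((cy - y) ** 2 + (cx - x) ** 2 < min_d**2 for y, x in centers):
            continue
        centers.append((cy, cx))
    return np.asarray(centers)


def simulate_cell_field(
    params: CellFieldSimParams,
) -> tuple[MultiChannelImage, CellFieldGroundTruth]:
    """Render one field and its ground truth.

    Deterministic for a fixed seed.  Compartment masks are disjoint within
    each cell (interior = cell minus ring; nucleus inside interior), and
    with noise off the summed target channel equals the summed per-cell
    total expression to float round-off.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_shape
    centers = _place_centers(params, rng)

    nuclei_ch = np.zeros((h, w), dtype=float)
    marker_ch = np.zeros((h, w), dtype=float)
    target_ch = np.zeros((h, w), dtype=float)
    nucleus_labels = np.zeros((h, w), dtype=np.int32)
    cell_labels = np.zeros((h, w), dtype=np.int32)
    membrane_labels = np.zeros((h, w), dtype=np.int32)

    yy, xx = np.mgrid[0:h, 0:w]
    rows = []
    for idx, (cy, cx) in enumerate(centers, start=1):
        jit = params.radius_jitter_frac
        r_cell = params.cell_radius_px * (1.0 + rng.uniform(-jit, jit))
        r_nuc = params.nucleus_radius_px * (1.0 + rng.uniform(-jit, jit))
        # nucleus strictly inside the interior (clear of the ring)
        max_off = max(r_cell - params.membrane_width_px - r_nuc - 2.0, 0.0)
        theta = rng.uniform(0, 2 * np.pi)
        off = rng.uniform(0, max_off)
        ny, nx = cy + off * np.sin(theta), cx + off * np.cos(theta)

        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        cell_mask = d2 <= r_cell**2
        interior_mask = d2 <= (r_cell - params.membrane_width_px) ** 2
        ring_mask = cell_mask & ~interior_mask

        # elliptical nucleus with mild anisotropy and rotation
        ecc = rng.uniform(0.85, 1.0)
        ang = rng.uniform(0, np.pi)
        ca, sa = np.cos(ang), np.sin(ang)
        u = (yy - ny) * ca + (xx - nx) * sa
        v = -(yy - ny) * sa + (xx - nx) * ca
        nuc_mask = (u / r_nuc) ** 2 + (v / (r_nuc * ecc)) ** 2 <= 1.0
        nuc_mask &= interior_mask  # guaranteed by construction; belt and braces

        nuc_img = np.where(nuc_mask, params.nucleus_intensity, 0.0)
        for _ in range(params.nucleoli_count):
            phi = rng.uniform(0, 2 * np.pi)
            rr = rng.uniform(0, max(r_nuc * ecc - params.nucleoli_radius_px - 1.0, 0.0))
            sy, sx = ny + rr * np.sin(phi), nx + rr * np.cos(phi)
            spot = (yy - sy) ** 2 + (xx - sx) ** 2 <= params.nucleoli_radius_px**2
            nuc_img[spot & nuc_mask] *= 1.0 - params.nucleoli_contrast
        nuclei_ch += nuc_img

        marker_ch[ring_mask] += params.marker_intensity

        total = params.total_expression * max(
            1.0 + params.expression_cv * rng.standard_normal(), 0.05
        )
        n_ring = int(ring_mask.sum())
        n_int = int(interior_mask.sum())
        if n_ring == 0 or n_int == 0:
            raise PlacementError("degenerate cell geometry (empty compartment)")
        target_ch[ring_mask] += params.membrane_fraction * total / n_ring
        target_ch[interior_mask] += (1.0 - params.membrane_fraction) * total / n_int

        nucleus_labels[nuc_mask] = idx
        cell_labels[cell_mask] = idx
        membrane_labels[ring_mask] = idx
        rows.append(
            {
                "cell_id": idx,
                "group": params.group,
                "center_y": cy,
                "center_x": cx,
                "cell_radius_px": r_cell,
                "nucleus_radius_px": r_nuc,
                "membrane_fraction": params.membrane_fraction,
                "total_expression": total,
            }
        )

    channels = {}
    for name, ch in (("nuclei", nuclei_ch), ("marker", marker_ch), ("target", target_ch)):
        out = ch
        if params.noise_poisson_scale > 0:
            out = rng.poisson(out * params.noise_poisson_scale) / params.noise_poisson_scale
        if params.noise_gaussian_sd > 0:
            out = out + rng.normal(0.0, params.noise_gaussian_sd, size=out.shape)
        channels[name] = np.clip(out, 0.0, None)

    image = MultiChannelImage(
        nuclei=channels["nuclei"],
        marker=channels["marker"],
        target=channels["target"],
        image_id=f"{params.group or 'field'}-seed{params.seed}",
    )
    truth = CellFieldGroundTruth(
        nucleus_labels=nucleus_labels,
        cell_labels=cell_labels,
        membrane_labels=membrane_labels,
        cells=pd.DataFrame(rows),
    )
    return image, truth


CELL_PRESET_NAMES = ("WT", "MT")


def cell_field_preset(name: str, seed: int = 0, **overrides) -> CellFieldSimParams:
    """Default field presets: the mutant-like group expresses 0.4x the
    wild-type total and routes a smaller fraction of it to the membrane."""
    cfg = load_presets()["cells"]
    try:
        grp = cfg["groups"][name]
    except KeyError:
        raise KeyError(
            f"unknown cell-field preset {name!r}; available: {sorted(cfg['groups'])}"
        ) from None
    sh = cfg["shared"]
    params = CellFieldSimParams(
        n_cells=int(grp["n_cells"]),
        nucleus_radius_px=float(sh["nucleus_radius_px"]),
        cell_radius_px=float(sh["cell_radius_px"]),
        membrane_width_px=int(sh["membrane_width_px"]),
        total_expression=float(grp["total_expression"]),
        membrane_fraction=float(grp["membrane_fraction"]),
        marker_intensity=float(sh["marker_intensity"]),
        nucleus_intensity=float(sh["nucleus_intensity"]),
        nucleoli_count=int(sh["nucleoli_count"]),
        nucleoli_radius_px=float(sh["nucleoli_radius_px"]),
        nucleoli_contrast=float(sh["nucleoli_contrast"]),
        noise_gaussian_sd=float(sh["noise_gaussian_sd"]),
        noise_poisson_scale=float(sh["noise_poisson_scale"]),
        image_shape=tuple(sh["image_shape"]),
        seed=seed,
        group=name,
    )
    if overrides:
        params = replace(params, **overrides)
    return params
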