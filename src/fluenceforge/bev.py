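"""Beam's-eye-view (BEV) projection of 3-D field doses and the PTV.

Each BEV pixel corresponds to a point on the isocenter plane of a beam; the
map value is obtained by marching the divergent ray from the source through
that point across the volume (trilinear sampling at a fixed step) and either
averaging the in-volume samples (default, keeping dose maps on the % Rx
scale and resolution-independent) or summing them (``mode='sum'``).  PTV
maps are binary: a pixel is 1 iff its ray intersects at least one PTV voxel.

BEV maps share the fluence-map grid (96x96 at 2.5 mm by default), so the
FM-CNN input and output are pixel-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .anatomy import Grid3D, PhantomCase, StructureMask
from .dose_engine import Beam, EngineConfig, beam_frame


@dataclass
class BEVMap:
    """2-D projection in the beam frame; ``kind`` is 'dose' or 'ptv_binary'."""

    values: np.ndarray
    pixel_mm: float
    beam: Beam
    kind: str = "dose"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.kind == "ptv_binary":
            bad = ~np.isin(self.values, (0.0, 1.0))
            if bad.any():
                raise ValueError("binary PTV map must contain only 0/1")


def _ray_samples(
    beam: Beam, grid: Grid3D, n: int, pixel_mm: float, step_mm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Index-space sample coordinates for all rays.

    Returns (coords shaped (3, n*n*nsteps), inside mask) where samples span
    the volume's full physical extent along each ray.
    """
    source, axis, u_ax, v_ax = beam_frame(beam)
    iso = np.asarray(beam.isocenter)
    half = (n - 1) / 2.0
    u = (np.arange(n) - half) * pixel_mm
    gu, gv = np.meshgrid(u, u, indexing="ij")
    plane_pts = (
        iso[None, :]
        + gu.ravel()[:, None] * u_ax[None, :]
        + gv.ravel()[:, None] * v_ax[None, :]
    )
    dirs = plane_pts - source[None, :]
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    # conservative parametric range covering the grid's bounding sphere
    lo = np.asarray(grid.origin)
    hi = grid.index_to_physical(np.array(grid.shape) - 1)
    center = 0.5 * (lo + hi)
    radius = 0.5 * float(np.linalg.norm(hi - lo)) + step_mm
    t_mid = float(np.linalg.norm(center - source))
    ts = np.arange(t_mid - radius, t_mid + radius + step_mm, step_mm)

    pts = source[None, None, :] + ts[None, :, None] * dirs[:, None, :]
    idx = (pts - lo[None, None, :]) / grid.spacing[None, None, :]
    inside = np.all((idx >= 0) & (idx <= np.array(grid.shape) - 1), axis=2)
    return idx.reshape(-1, 3).T, inside


def project_dose_bev(
    dose: np.ndarray,
    beam: Beam,
    grid: Grid3D,
    config: EngineConfig | None = None,
    mode: str = "mean",
    step_mm: float = 1.0,
    region: np.ndarray | None = None,
) -> BEVMap:
    """Project a 3-D dose volume along the BEV onto the isocenter-plane grid.

    ``mode='mean'`` averages the samples along each ray (keeping map values
    on the dose scale, resolution-independent); ``'sum'`` integrates them.
    An optional binary ``region`` restricts both the dose and the averaging
    support to a sub-volume (e.g. the ROI, where a dose prediction is
    defined) so map magnitudes stay comparable with whole-volume maps.
    """
    if mode not in ("mean", "sum"):
        raise ValueError(f"unknown projection mode {mode!r}")
    config = config or EngineConfig()
    n, pix = config.fluence_n, config.fluence_pixel_mm
    coords, inside = _ray_samples(beam, grid, n, pix, step_mm)
    vals = ndimage.map_coordinates(
        np.asarray(dose, dtype=np.float64), coords, order=1, mode="constant", cval=0.0
    ).reshape(inside.shape)
    if region is not None:
        in_region = ndimage.map_coordinates(
            np.asarray(region, dtype=np.float64), coords, order=0,
            mode="constant", cval=0.0,
        ).reshape(inside.shape)
        inside = inside & (in_region > 0.5)
    vals = vals * inside
    if mode == "mean":
        counts = inside.sum(axis=1)
        out = np.where(counts > 0, vals.sum(axis=1) / np.maximum(counts, 1), 0.0)
    else:
        out = vals.sum(axis=1) * step_mm
    return BEVMap(out.reshape(n, n), pix, beam, kind="dose")


def project_ptv_bev(
    ptv: StructureMask,
    beam: Beam,
    config: EngineConfig | None = None,
    step_mm: float = 1.0,
) -> BEVMap:
    """Binary BEV footprint of the PTV: 1 iff the ray hits >= 1 PTV voxel."""
    config = config or EngineConfig()
    n, pix = config.fluence_n, config.fluence_pixel_mm
    coords, inside = _ray_samples(beam, ptv.grid, n, pix, step_mm)
    vals = ndimage.map_coordinates(
        ptv.voxels.astype(np.float64), coords, order=0, mode="constant", cval=0.0
    ).reshape(inside.shape)
    hit = ((vals * inside) > 0.5).any(axis=1)
    return BEVMap(hit.reshape(n, n).astype(np.float64), pix, beam, kind="ptv_binary")


def project_case(
    case: PhantomCase,
    field_doses: np.ndarray,
    config: EngineConfig | None = None,
    mode: str = "mean",
    region: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """All nine BEV dose maps and PTV maps for one case.

    ``field_doses`` is (n_beams, nx, ny, nz); returns two arrays
    (n_beams, nf, nf).  ``region`` restricts the dose projection support.
    """
    from .dose_engine import make_beams

    config = config or EngineConfig()
    beams = make_beams(case.isocenter, config)
    dose_maps, ptv_maps = [], []
    for k, beam in enumerate(beams):
        dose_maps.append(
            project_dose_bev(field_doses[k], beam, case.grid, config, mode,
                             region=region).values
        )
        ptv_maps.append(project_ptv_bev(case.ptv, beam, config).values)
    return np.stack(dose_maps), np.stack(ptv_maps)
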