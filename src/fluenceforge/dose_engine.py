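"""Simplified forward dose engine for nine-beam coplanar IMRT.

Maps a per-beam fluence map (2.5 mm grid at the isocenter plane) to a 3-D
dose volume on the case grid.  The model is a deliberately simple,
non-clinical surrogate for a commercial dose algorithm:

* divergent projection of each voxel through the source onto the isocenter
  plane, bilinear sampling of the fluence there;
* exponential depth attenuation ``exp(-mu_att * (d - d_build))`` beyond a
  buildup depth, with ``d`` the radiological depth (density line integral
  along the beam direction, parallel-ray approximation) clamped at
  ``d_build``;
* inverse-square falloff ``(SAD / r)^2``;
* an isotropic Gaussian scatter blur.

The map is linear in the fluence, which the benchmark optimizer exploits via
the adjoint operator.  Engine output is in arbitrary dose units; a per-plan
scalar calibration (benchmark PTV mean = 100% Rx) converts to percent of
prescription.

Geometry: gantry rotates about the superior-inferior (z) axis; gantry 0
places the source anterior (-y); the beam axis at angle t (degrees) is
``(sin t, cos t, 0)``; the BEV u-axis ``(cos t, -sin t, 0)`` lies in the
axial plane and the v-axis is +z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .anatomy import Grid3D, PhantomCase


@dataclass(frozen=True)
class EngineConfig:
    """Dose-engine and beam-geometry parameters (non-clinical surrogate values)."""

    n_beams: int = 9
    gantry_start_deg: float = 0.0
    sad_mm: float = 1000.0
    fluence_n: int = 96
    fluence_pixel_mm: float = 2.5
    mu_att: float = 0.004        # mm^-1 effective attenuation
    d_build_mm: float = 20.0     # buildup depth
    scatter_sigma_mm: float = 3.0
    aperture_margin_mm: float = 5.0

    @staticmethod
    def coarse() -> "EngineConfig":
        """Desk-scale fluence grid: 32x32 at 7.5 mm (same 240 mm extent)."""
        return EngineConfig(fluence_n=32, fluence_pixel_mm=7.5)


@dataclass(frozen=True)
class Beam:
    gantry_deg: float
    isocenter: tuple[float, float, float]
    index: int = 0
    sad_mm: float = 1000.0


def make_beams(isocenter, config: EngineConfig) -> list[Beam]:
    """Nine (by default) equally spaced coplanar beams sharing the isocenter."""
    step = 360.0 / config.n_beams
    return [
        Beam(
            gantry_deg=config.gantry_start_deg + k * step,
            isocenter=tuple(np.asarray(isocenter, dtype=float)),
            index=k,
            sad_mm=config.sad_mm,
        )
        for k in range(config.n_beams)
    ]


def beam_frame(beam: Beam) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Return (source, beam_axis, u_axis, v_axis) for a beam."""
    t = np.deg2rad(beam.gantry_deg)
    axis = np.array([np.sin(t), np.cos(t), 0.0])
    u = np.array([np.cos(t), -np.sin(t), 0.0])
    v = np.array([0.0, 0.0, 1.0])
    source = np.asarray(beam.isocenter) - beam.sad_mm * axis
    return source, axis, u, v


@dataclass
class FluenceMap:
    """Nonnegative relative beam intensities on the isocenter-plane grid.

    ``values[iu, iv]`` with u along the axial in-plane axis and v along
    superior-inferior; pixel (n-1)/2 is on the beam axis.
    """

    values: np.ndarray
    pixel_mm: float
    beam: Beam

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("fluence values must be nonnegative")


@dataclass
class FieldDoseSet:
    """Per-beam 3-D dose volumes (stacked, shape (n_beams, nx, ny, nz))."""

    per_beam: np.ndarray
    grid: Grid3D

    def __post_init__(self):
        self.per_beam = np.asarray(self.per_beam)
        if self.per_beam.shape[1:] != self.grid.shape:
            raise ValueError("field-dose shape does not match grid")

    @property
    def total(self) -> np.ndarray:
        return total_dose(self)


def total_dose(fds: FieldDoseSet) -> np.ndarray:
    """Voxelwise sum of the per-beam dose volumes."""
    return fds.per_beam.sum(axis=0)


@dataclass
class BeamTemplateSet:
    """Open-field dose of the conformal aperture per beam, max-normalized to 1."""

    per_beam: np.ndarray            # (n_beams, nx, ny, nz)
    apertures: np.ndarray           # (n_beams, nf, nf) binary
    grid: Grid3D


# ---------------------------------------------------------------------------
# Geometry precomputation and the linear operator
# ---------------------------------------------------------------------------

def _rot2(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    return np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])


def _rotate_about_iso(vol: np.ndarray, grid: Grid3D, iso_idx_xy, deg: float) -> np.ndarray:
    """Rotate an (nx,ny,nz) volume in the axial plane about the isocenter by ``deg``.

    out[q] = vol[R(deg) @ (q - iso) + iso] in index space (requires dx == dy).
    """
    r = _rot2(deg)
    mat = np.eye(3)
    mat[:2, :2] = r
    iso = np.array([iso_idx_xy[0], iso_idx_xy[1], 0.0])
    offset = iso - mat @ iso
    return ndimage.affine_transform(
        vol, mat, offset=offset, order=1, mode="constant", cval=0.0
    )


class _BeamGeometry:
    """Cached per-beam projection indices, weights, and depth kernel."""

    def __init__(self, beam: Beam, case: PhantomCase, config: EngineConfig):
        grid = case.grid
        source, axis, u_ax, v_ax = beam_frame(beam)
        xs, ys, zs = grid.coords()
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        rel = np.stack([gx.ravel(), gy.ravel(), gz.ravel()]) - source[:, None]

        w = axis @ rel                       # distance along beam axis
        if np.any(w <= 1.0):
            raise ValueError("voxel at or behind the source")
        sad = beam.sad_mm
        u = sad * (u_ax @ rel) / w           # isocenter-plane ray coordinates, mm
        v = sad * (v_ax @ rel) / w

        nf, pix = config.fluence_n, config.fluence_pixel_mm
        fu = u / pix + (nf - 1) / 2.0
        fv = v / pix + (nf - 1) / 2.0
        i0 = np.floor(fu).astype(np.int64)
        j0 = np.floor(fv).astype(np.int64)
        tu = fu - i0
        tv = fv - j0
        idx_list, wgt_list = [], []
        for di, wu in ((0, 1.0 - tu), (1, tu)):
            for dj, wv in ((0, 1.0 - tv), (1, tv)):
                ii = i0 + di
                jj = j0 + dj
                valid = (ii >= 0) & (ii < nf) & (jj >= 0) & (jj < nf)
                wgt_list.append(np.where(valid, wu * wv, 0.0))
                idx_list.append(np.clip(ii, 0, nf - 1) * nf + np.clip(jj, 0, nf - 1))
        self.tap_idx = np.stack(idx_list)      # (4, nvox) flat fluence indices
        self.tap_wgt = np.stack(wgt_list)

        depth = _radiological_depth(case, beam)
        d = np.maximum(depth.ravel(), config.d_build_mm)
        invsq = (sad / np.sqrt((rel**2).sum(axis=0))) ** 2
        self.kernel = invsq * np.exp(-config.mu_att * (d - config.d_build_mm))
        self.shape = grid.shape
        self.nf = nf
        self.sigma_vox = (
            config.scatter_sigma_mm / grid.dx,
            config.scatter_sigma_mm / grid.dy,
            config.scatter_sigma_mm / grid.dz,
        )
        # projection of voxel centers, reused for aperture construction
        self.fu, self.fv = fu, fv

    def forward(self, fluence: np.ndarray) -> np.ndarray:
        flu = np.asarray(fluence, dtype=np.float64).ravel()
        vals = np.einsum("tn,tn->n", flu[self.tap_idx], self.tap_wgt)
        dose = (vals * self.kernel).reshape(self.shape)
        if max(self.sigma_vox) > 0:
            dose = ndimage.gaussian_filter(
                dose, self.sigma_vox, mode="constant", truncate=2.5
            )
        return dose

    def adjoint(self, grad_vol: np.ndarray) -> np.ndarray:
        g = np.asarray(grad_vol, dtype=np.float64)
        if max(self.sigma_vox) > 0:
            g = ndimage.gaussian_filter(
                g, self.sigma_vox, mode="constant", truncate=2.5
            )
        flat = g.ravel() * self.kernel
        out = np.zeros(self.nf * self.nf)
        for t in range(self.tap_idx.shape[0]):
            out += np.bincount(
                self.tap_idx[t], weights=flat * self.tap_wgt[t],
                minlength=self.nf * self.nf,
            )
        return out.reshape(self.nf, self.nf)


def _radiological_depth(case: PhantomCase, beam: Beam) -> np.ndarray:
    """Water-equivalent depth along the beam direction (parallel-ray cumsum)."""
    grid = case.grid
    iso_idx = grid.physical_to_index(np.asarray(beam.isocenter))[:2]
    # rotate so the beam axis maps onto +y (index axis 1), accumulate, rotate back
    rho = _rotate_about_iso(
        case.density.astype(np.float64), grid, iso_idx, -beam.gantry_deg
    )
    depth_rot = (np.cumsum(rho, axis=1) - 0.5 * rho) * grid.dy
    return _rotate_about_iso(depth_rot, grid, iso_idx, beam.gantry_deg)


class DoseEngine:
    """Linear fluence -> dose operator for all beams of one case (geometry cached)."""

    def __init__(self, case: PhantomCase, config: EngineConfig | None = None):
        self.case = case
        self.config = config or EngineConfig()
        self.beams = make_beams(case.isocenter, self.config)
        self._geom = [_BeamGeometry(b, case, self.config) for b in self.beams]

    def forward_beam(self, beam_index: int, fluence: np.ndarray) -> np.ndarray:
        return self._geom[beam_index].forward(fluence)

    def adjoint_beam(self, beam_index: int, grad_vol: np.ndarray) -> np.ndarray:
        return self._geom[beam_index].adjoint(grad_vol)

    def forward(self, fluences: np.ndarray) -> FieldDoseSet:
        """``fluences`` shaped (n_beams, nf, nf) -> per-beam dose volumes."""
        fluences = np.asarray(fluences)
        per_beam = np.stack(
            [self.forward_beam(k, fluences[k]) for k in range(len(self.beams))]
        )
        return FieldDoseSet(per_beam=per_beam, grid=self.case.grid)

    def apertures(self, margin_mm: float | None = None) -> np.ndarray:
        """Binary conformal apertures: BEV footprint of the PTV + margin, per beam."""
        if not self.case.ptv.voxels.any():
            raise ValueError("empty PTV has no aperture")
        margin = self.config.aperture_margin_mm if margin_mm is None else margin_mm
        ptv_flat = self.case.ptv.voxels.ravel() > 0
        nf = self.config.fluence_n
        rad = int(np.ceil(margin / self.config.fluence_pixel_mm))
        yy, xx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
        disk = (xx**2 + yy**2) <= rad**2
        out = np.zeros((len(self.beams), nf, nf), dtype=np.uint8)
        for k, geom in enumerate(self._geom):
            iu = np.clip(np.rint(geom.fu[ptv_flat]).astype(int), 0, nf - 1)
            iv = np.clip(np.rint(geom.fv[ptv_flat]).astype(int), 0, nf - 1)
            ap = np.zeros((nf, nf), dtype=bool)
            ap[iu, iv] = True
            out[k] = ndimage.binary_dilation(ap, structure=disk)
        return out


def compute_field_dose(fluence: FluenceMap, case: PhantomCase,
                       config: EngineConfig | None = None) -> np.ndarray:
    """Dose volume of a single beam's fluence map (convenience, uncached)."""
    config = config or EngineConfig()
    if abs(fluence.pixel_mm - config.fluence_pixel_mm) > 1e-9:
        raise ValueError("fluence pixel size inconsistent with engine config")
    geom = _BeamGeometry(fluence.beam, case, config)
    return geom.forward(fluence.values)


def compute_beam_templates(case: PhantomCase,
                           config: EngineConfig | None = None,
                           engine: "DoseEngine | None" = None) -> BeamTemplateSet:
    """Open-field dose of a uniform fluence over the conformal aperture
    (PTV + 5 mm margin in the BEV), normalized to per-beam maximum 1."""
    engine = engine or DoseEngine(case, config)
    aps = engine.apertures()
    vols = []
    for k in range(len(engine.beams)):
        dose = engine.forward_beam(k, aps[k].astype(np.float64))
        peak = dose.max()
        vols.append(dose / peak if peak > 0 else dose)
    return BeamTemplateSet(
        per_beam=np.stack(vols), apertures=aps, grid=case.grid
    )
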