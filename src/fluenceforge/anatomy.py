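"""Phantom anatomy: grids, structures, synthetic case generation, preprocessing.

Coordinate conventions (used throughout the package):

* volumes are numpy arrays indexed ``[ix, iy, iz]``;
* the axial plane is (x, y) and the slice axis is z, superior = increasing z;
* voxel *centers* sit at ``origin + index * spacing`` (0-based indices);
* model-facing grids use 1 mm axial spacing and 2 mm slice thickness, and
  axial slices are cropped to 192x192 pixels centered at the isocenter
  (the isocenter voxel maps to index (96, 96)); coarse-grid presets relax
  these sizes but keep the same conventions.

The synthetic generator emulates pancreas SBRT geometry: a planning target
volume (PTV) of 5-150 cc inside a water-density elliptical body, with a
tubular luminal organ at risk (OAR, the surrogate for stomach + duodenum +
bowel) placed at a sampled gap from the PTV surface, including overlap.
The inverted prescription (OAR max 25 Gy below the 33 Gy target dose) makes
these geometries the hard planning scenario the pipeline is built for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

RX_GY = 33.0  # prescription dose, Gy in 5 fractions; 100% in relative units


# ---------------------------------------------------------------------------
# Grids and structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid3D:
    """Regular 3-D voxel grid; ``origin`` is the physical center of voxel (0,0,0) in mm."""

    nx: int
    ny: int
    nz: int
    dx: float = 1.0
    dy: float = 1.0
    dz: float = 2.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def spacing(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz], dtype=float)

    @property
    def voxel_cc(self) -> float:
        """Voxel volume in cubic centimeters (mm^3 / 1000)."""
        return self.dx * self.dy * self.dz / 1000.0

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * self.spacing

    def physical_to_index(self, point: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel index of a physical point."""
        point = np.asarray(point, dtype=float)
        return (point - np.asarray(self.origin)) / self.spacing

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical center coordinates along each axis."""
        ox, oy, oz = self.origin
        return (
            ox + np.arange(self.nx) * self.dx,
            oy + np.arange(self.ny) * self.dy,
            oz + np.arange(self.nz) * self.dz,
        )


@dataclass
class StructureMask:
    """Binary occupancy mask on a grid."""

    grid: Grid3D
    voxels: np.ndarray

    def __post_init__(self):
        self.voxels = np.ascontiguousarray(self.voxels.astype(np.uint8))
        if self.voxels.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.voxels.shape} != grid shape {self.grid.shape}"
            )

    @property
    def volume_cc(self) -> float:
        return float(self.voxels.sum()) * self.grid.voxel_cc

    def centroid(self) -> np.ndarray:
        """Physical centroid of the mask (mm)."""
        idx = np.argwhere(self.voxels > 0)
        if idx.size == 0:
            raise ValueError("empty mask has no centroid")
        return self.grid.index_to_physical(idx.mean(axis=0))


@dataclass
class PhantomCase:
    """One synthetic case: density + PTV/OAR masks + isocenter on a shared grid."""

    grid: Grid3D
    density: np.ndarray
    ptv: StructureMask
    oar: StructureMask
    isocenter: np.ndarray
    case_id: str = ""
    seed: int = 0

    def __post_init__(self):
        self.density = np.asarray(self.density, dtype=np.float32)
        self.isocenter = np.asarray(self.isocenter, dtype=float)

    def roi(self, margin_mm: float = 10.0) -> StructureMask:
        """Prediction region of interest: the PTV expanded by ``margin_mm``."""
        return expand_structure(self.ptv, margin_mm)


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def resample_volume(
    volume: np.ndarray,
    source: Grid3D,
    target: Grid3D,
    mode: str = "linear",
) -> np.ndarray:
    """Resample a scalar field from ``source`` onto ``target`` voxel centers.

    ``mode='linear'`` (doses, density) or ``'nearest'`` (masks).  Target voxels
    outside the source extent are 0.
    """
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown mode {mode!r}")
    src_lo = np.asarray(source.origin)
    src_hi = source.index_to_physical(np.array(source.shape) - 1)
    tgt_lo = np.asarray(target.origin)
    tgt_hi = target.index_to_physical(np.array(target.shape) - 1)
    if np.any(tgt_lo > src_hi) or np.any(tgt_hi < src_lo):
        raise ValueError("source and target grids do not overlap")

    xs, ys, zs = target.coords()
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([gx, gy, gz]).reshape(3, -1)
    idx = (pts - src_lo[:, None]) / source.spacing[:, None]
    order = 1 if mode == "linear" else 0
    out = ndimage.map_coordinates(
        np.asarray(volume, dtype=float), idx, order=order, mode="constant", cval=0.0
    )
    return out.reshape(target.shape)


def crop_to_window(
    volume: np.ndarray, grid: Grid3D, isocenter: np.ndarray, window: int = 192
) -> tuple[np.ndarray, Grid3D]:
    """Crop each axial slice to ``window``x``window`` pixels centered at the isocenter.

    The isocenter voxel lands at in-window index (window//2, window//2).
    Regions outside the original extent are zero-padded.  Returns the cropped
    volume and its grid.
    """
    iso_idx = np.rint(grid.physical_to_index(isocenter)).astype(int)
    if not (0 <= iso_idx[0] < grid.nx and 0 <= iso_idx[1] < grid.ny):
        raise ValueError("isocenter lies outside the volume")
    half = window // 2
    out = np.zeros((window, window, volume.shape[2]), dtype=np.asarray(volume).dtype)
    x0, y0 = iso_idx[0] - half, iso_idx[1] - half
    sx0, sx1 = max(0, x0), min(grid.nx, x0 + window)
    sy0, sy1 = max(0, y0), min(grid.ny, y0 + window)
    out[sx0 - x0 : sx1 - x0, sy0 - y0 : sy1 - y0, :] = volume[sx0:sx1, sy0:sy1, :]
    new_origin = grid.index_to_physical(np.array([x0, y0, 0]))
    new_grid = Grid3D(
        window, window, volume.shape[2], grid.dx, grid.dy, grid.dz, tuple(new_origin)
    )
    return out, new_grid


def normalize_dose(dose_gy: np.ndarray, rx_gy: float = RX_GY) -> np.ndarray:
    """Convert absolute dose (Gy) to percent of prescription (33 Gy -> 100)."""
    dose_gy = np.asarray(dose_gy, dtype=float)
    if np.any(dose_gy < 0):
        raise ValueError("negative input dose")
    return dose_gy / rx_gy * 100.0


def expand_structure(mask: StructureMask, margin_mm: float = 10.0) -> StructureMask:
    """Spacing-aware Euclidean dilation: voxels whose center is within
    ``margin_mm`` of any mask voxel center.  With anisotropic spacing the
    expansion is asymmetric in voxel counts (e.g. 10 mm = 10 axial voxels but
    5 slices at 1x1x2 mm)."""
    if margin_mm < 0:
        raise ValueError("margin must be >= 0")
    if not mask.voxels.any():
        raise ValueError("cannot expand an empty mask")
    if margin_mm == 0:
        return StructureMask(mask.grid, mask.voxels.copy())
    dist = ndimage.distance_transform_edt(
        mask.voxels == 0, sampling=mask.grid.spacing
    )
    return StructureMask(mask.grid, (dist <= margin_mm + 1e-9).astype(np.uint8))


# ---------------------------------------------------------------------------
# Synthetic phantom generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomConfig:
    """Synthetic pancreas-SBRT phantom parameters.

    Defaults describe the clinical-scale grid (192x192 axial pixels at 1 mm,
    2 mm slices).  ``coarse()`` gives the desk-scale preset used for
    end-to-end experiments.  PTV volumes follow a lognormal distribution with
    median ~30 cc truncated to [5, 150] cc, typical of pancreas SBRT targets;
    the OAR sits at a gap sampled uniformly from ``oar_gap_mm`` relative to
    the PTV surface (negative = overlap), reproducing the abutting-luminal-
    organ scenario that motivates the inverted prescription.
    """

    window: int = 192
    nz: int = 64
    dx: float = 1.0
    dz: float = 2.0
    ptv_volume_cc: tuple[float, float] = (5.0, 150.0)
    ptv_logmean: float = 3.4012  # log(30 cc), the median PTV volume
    ptv_logsd: float = 0.5
    oar_gap_mm: tuple[float, float] = (-5.0, 15.0)
    oar_radius_mm: tuple[float, float] = (6.0, 12.0)
    body_halfaxis_x_mm: tuple[float, float] = (70.0, 90.0)
    body_halfaxis_y_mm: tuple[float, float] = (50.0, 65.0)
    max_attempts: int = 25

    @staticmethod
    def coarse() -> "PhantomConfig":
        """Desk-scale grid: 48x48x16 voxels at 4 mm isotropic (192 x 192 x 64 mm)."""
        return PhantomConfig(window=48, nz=16, dx=4.0, dz=4.0)

    @property
    def mean_ptv_cc(self) -> float:
        """Mean of the truncated lognormal PTV-volume distribution (Monte-Carlo)."""
        rng = np.random.default_rng(0)
        v = np.exp(rng.normal(self.ptv_logmean, self.ptv_logsd, 20000))
        lo, hi = self.ptv_volume_cc
        return float(np.mean(np.clip(v, lo, hi)))


def _smooth_noise(rng: np.random.Generator, shape, sigma_vox) -> np.ndarray:
    n = rng.normal(size=shape)
    n = ndimage.gaussian_filter(n, sigma=sigma_vox)
    s = n.std()
    return n / s if s > 0 else n


def generate_phantom(
    seed: int, config: PhantomConfig | None = None, case_id: str | None = None
) -> PhantomCase:
    """Generate one synthetic case; deterministic for a fixed seed.

    Draws the body ellipse, a smoothed random-blob PTV with an exactly
    volume-matched threshold, and a tubular OAR translated so its surface gap
    to the PTV matches a sampled target.  Rejection-resamples internal draws
    up to ``max_attempts`` times before raising.
    """
    config = config or PhantomConfig()
    last_err = "unknown"
    for attempt in range(config.max_attempts):
        rng = np.random.default_rng(np.random.SeedSequence((seed, attempt)))
        case = _try_generate(rng, config, seed, case_id)
        if isinstance(case, PhantomCase):
            return case
        last_err = case
    raise RuntimeError(
        f"phantom generation failed after {config.max_attempts} attempts: {last_err}"
    )


def _try_generate(rng, config: PhantomConfig, seed, case_id) -> PhantomCase | str:
    n, nz = config.window, config.nz
    dx, dz = config.dx, config.dz
    # center the grid on (0,0,0): origin chosen so voxel (n//2, n//2, nz//2) is at 0
    origin = (-(n // 2) * dx, -(n // 2) * dx, -(nz // 2) * dz)
    grid = Grid3D(n, n, nz, dx, dx, dz, origin)
    xs, ys, zs = grid.coords()
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")

    # --- body: water-density elliptical cylinder, air outside
    ax = rng.uniform(*config.body_halfaxis_x_mm)
    ay = rng.uniform(*config.body_halfaxis_y_mm)
    body = ((gx / ax) ** 2 + (gy / ay) ** 2) <= 1.0
    density = body.astype(np.float32)

    # --- PTV: perturbed ellipsoid thresholded at the exact target volume
    lo, hi = config.ptv_volume_cc
    target_cc = float(np.clip(
        np.exp(rng.normal(config.ptv_logmean, config.ptv_logsd)), lo, hi
    ))
    center = np.array([rng.uniform(-10, 10), rng.uniform(-8, 8), rng.uniform(-4, 4)])
    r_eq = (3.0 * target_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    ratios = rng.uniform(0.7, 1.4, size=3)
    ratios /= ratios.prod() ** (1.0 / 3.0)
    axes = r_eq * ratios
    q = (
        ((gx - center[0]) / axes[0]) ** 2
        + ((gy - center[1]) / axes[1]) ** 2
        + ((gz - center[2]) / axes[2]) ** 2
    )
    q = q * (1.0 + 0.25 * _smooth_noise(rng, grid.shape, sigma_vox=(8 / dx, 8 / dx, 8 / dz)))
    k = int(round(target_cc / grid.voxel_cc))
    if k < 8 or k >= q.size:
        return "PTV volume unreachable on this grid"
    thresh = np.partition(q.ravel(), k)[k]
    ptv_vox = (q <= thresh) & body
    ptv_vox = ndimage.binary_fill_holes(ptv_vox)
    lab, nlab = ndimage.label(ptv_vox)
    if nlab == 0:
        return "empty PTV"
    if nlab > 1:
        sizes = ndimage.sum(ptv_vox, lab, range(1, nlab + 1))
        ptv_vox = lab == (1 + int(np.argmax(sizes)))
    ptv = StructureMask(grid, ptv_vox)
    if not (lo * 0.8 <= ptv.volume_cc <= hi * 1.05):
        return f"PTV volume {ptv.volume_cc:.1f} cc out of range"

    # --- OAR: vertical tube with wandering centerline, shifted to target gap
    gap_target = rng.uniform(*config.oar_gap_mm)
    r_lo, r_hi = config.oar_radius_mm
    radius = rng.uniform(r_lo, r_hi)
    wander = ndimage.gaussian_filter1d(rng.normal(0, 8, size=(2, nz)), 3, axis=1)
    theta = rng.uniform(0, 2 * np.pi)
    direction = np.array([np.cos(theta), np.sin(theta) * ay / ax])
    ptv_c = ptv.centroid()[:2]

    dist_out = ndimage.distance_transform_edt(ptv.voxels == 0, sampling=grid.spacing)
    dist_in = ndimage.distance_transform_edt(ptv.voxels == 1, sampling=grid.spacing)
    signed = dist_out - dist_in  # negative inside the PTV

    def tube_mask(shift_mm: float) -> np.ndarray:
        cx = ptv_c[0] + direction[0] * shift_mm + wander[0]
        cy = ptv_c[1] + direction[1] * shift_mm + wander[1]
        d2 = (gx - cx[None, None, :]) ** 2 + (gy - cy[None, None, :]) ** 2
        return (d2 <= radius**2) & body

    def gap_of(mask: np.ndarray) -> float:
        if not mask.any():
            return np.inf
        return float(signed[mask].min())

    s_lo, s_hi = 0.0, float(max(ax, ay) + 60.0)
    if gap_of(tube_mask(s_lo)) > gap_target:
        return "OAR cannot reach target gap (PTV off-center)"
    for _ in range(40):
        mid = 0.5 * (s_lo + s_hi)
        if gap_of(tube_mask(mid)) < gap_target:
            s_lo = mid
        else:
            s_hi = mid
    oar_vox = tube_mask(s_lo)
    achieved = gap_of(oar_vox)
    if not oar_vox.any() or abs(achieved - gap_target) > 3.0:
        return f"OAR gap {achieved:.1f} mm missed target {gap_target:.1f} mm"
    # the OAR must approach within the PTV expansion region (max sampled gap)
    if achieved > config.oar_gap_mm[1] + 1e-6:
        return "OAR outside the PTV expansion region"
    oar = StructureMask(grid, oar_vox)

    iso_idx = np.rint(grid.physical_to_index(ptv.centroid())).astype(int)
    isocenter = grid.index_to_physical(iso_idx)
    return PhantomCase(
        grid=grid,
        density=density,
        ptv=ptv,
        oar=oar,
        isocenter=isocenter,
        case_id=case_id or f"case{seed:05d}",
        seed=seed,
    )


# ---------------------------------------------------------------------------
# FD-CNN sample assembly
# ---------------------------------------------------------------------------

@dataclass
class FDSample:
    """One slice-wise training sample for the field-dose network.

    ``ptv_stack`` holds the query slice and its six neighbors (query +- 3),
    ordered inferior to superior, zero-filled outside the volume.
    ``target_fd`` holds the nine per-beam ground-truth dose slices in % Rx.
    """

    case_id: str
    query_index: int
    ptv_stack: np.ndarray      # (7, n, n)
    oar_slice: np.ndarray      # (n, n)
    templates: np.ndarray      # (9, n, n)
    target_fd: np.ndarray      # (9, n, n)
    roi_slice: np.ndarray      # (n, n)


def _padded_slice(vol: np.ndarray, z: int) -> np.ndarray:
    if 0 <= z < vol.shape[2]:
        return vol[:, :, z]
    return np.zeros(vol.shape[:2], dtype=vol.dtype)


def build_fd_samples(
    case: PhantomCase,
    field_doses: np.ndarray,
    templates: np.ndarray,
    roi_margin_mm: float = 10.0,
    n_adjacent: int = 3,
) -> list[FDSample]:
    """One sample per axial slice intersecting the ROI (PTV + 10 mm)."""
    field_doses = np.asarray(field_doses)
    if field_doses.shape[1:] != case.grid.shape:
        raise ValueError("field-dose grid mismatch with case grid")
    if templates.shape[1:] != case.grid.shape:
        raise ValueError("template grid mismatch with case grid")
    roi = case.roi(roi_margin_mm).voxels
    samples = []
    for z in range(case.grid.nz):
        roi_slice = roi[:, :, z]
        if not roi_slice.any():
            continue
        stack = np.stack(
            [_padded_slice(case.ptv.voxels, z + off)
             for off in range(-n_adjacent, n_adjacent + 1)]
        )
        samples.append(
            FDSample(
                case_id=case.case_id,
                query_index=z,
                ptv_stack=stack.astype(np.float32),
                oar_slice=case.oar.voxels[:, :, z].astype(np.float32),
                templates=templates[:, :, :, z].astype(np.float32),
                target_fd=field_doses[:, :, :, z].astype(np.float32),
                roi_slice=roi_slice.astype(np.float32),
            )
        )
    return samples


def roi_slice_count(case: PhantomCase, roi_margin_mm: float = 10.0) -> int:
    roi = case.roi(roi_margin_mm).voxels
    return int(roi.any(axis=(0, 1)).sum())
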