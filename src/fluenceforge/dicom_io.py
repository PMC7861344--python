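"""Optional DICOM-RT adapter: CT series + RT Structure Set -> PhantomCase.

Reads a directory of axial CT slices and an RT Structure Set, rasterizes
the PTV and the luminal organs (stomach / duodenum / bowel, unioned into
one OAR) onto the model grid, and converts CT numbers to relative density
with the simple linear rule ``density = 1 + HU/1000`` (clipped at 0).

Assumptions: axial slices with identity in-plane orientation, uniform
slice spacing, planar contours.  Anything else raises.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pydicom
from skimage.draw import polygon as _sk_polygon

from .anatomy import Grid3D, PhantomCase, StructureMask, resample_volume

OAR_NAME_PARTS = ("stomach", "duodenum", "c-loop", "cloop", "bowel")


def _load_ct_series(files):
    slices = [pydicom.dcmread(str(f)) for f in files]
    slices = [s for s in slices if getattr(s, "Modality", "") == "CT"]
    if not slices:
        raise ValueError("no CT slices found")
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    iop = np.asarray(slices[0].ImageOrientationPatient, dtype=float)
    if not np.allclose(iop, [1, 0, 0, 0, 1, 0], atol=1e-3):
        raise ValueError("only identity in-plane orientation is supported")
    dy_row, dx_col = map(float, slices[0].PixelSpacing)
    x0, y0, z0 = map(float, slices[0].ImagePositionPatient)
    dz = (
        float(slices[1].ImagePositionPatient[2]) - z0 if len(slices) > 1 else 1.0
    )
    if dz <= 0:
        raise ValueError("non-increasing slice positions")
    rows = slices[0].Rows
    cols = slices[0].Columns
    vol = np.zeros((cols, rows, len(slices)), dtype=np.float32)
    for k, s in enumerate(slices):
        hu = s.pixel_array.astype(np.float32)
        hu = hu * float(getattr(s, "RescaleSlope", 1.0)) + float(
            getattr(s, "RescaleIntercept", 0.0)
        )
        vol[:, :, k] = hu.T  # DICOM rows run along y; our first axis is x
    grid = Grid3D(cols, rows, len(slices), dx_col, dy_row, dz, (x0, y0, z0))
    return vol, grid


def _rasterize_structure(rtss, roi_number, grid: Grid3D) -> np.ndarray:
    mask = np.zeros(grid.shape, dtype=np.uint8)
    for item in rtss.ROIContourSequence:
        if int(item.ReferencedROINumber) != roi_number:
            continue
        for contour in getattr(item, "ContourSequence", []):
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            idx = (pts - np.asarray(grid.origin)) / grid.spacing
            z = int(round(idx[:, 2].mean()))
            if not (0 <= z < grid.nz):
                continue
            rr, cc = _sk_polygon(idx[:, 0], idx[:, 1], shape=(grid.nx, grid.ny))
            mask[rr, cc, z] = 1
    return mask


def read_dicom_case(
    path: str | Path,
    target_grid: Grid3D | None = None,
    ptv_name: str = "PTV",
    case_id: str | None = None,
) -> PhantomCase:
    """Build a PhantomCase from a directory of DICOM files (CT + RTSTRUCT).

    The PTV structure is matched by name (case-insensitive substring); the
    OAR is the union of all structures whose names contain a luminal-organ
    keyword.  Raises with the available ROI names when the PTV is missing.
    """
    path = Path(path)
    files = sorted(path.glob("*.dcm")) or sorted(path.iterdir())
    rtss = None
    ct_files = []
    for f in files:
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(f), stop_before_pixels=True)
        except Exception:
            continue
        if getattr(ds, "Modality", "") == "RTSTRUCT":
            rtss = pydicom.dcmread(str(f))
        elif getattr(ds, "Modality", "") == "CT":
            ct_files.append(f)
    if rtss is None:
        raise ValueError("no RT Structure Set found")
    hu, ct_grid = _load_ct_series(ct_files)

    names = {
        int(r.ROINumber): str(r.ROIName) for r in rtss.StructureSetROISequence
    }
    ptv_numbers = [n for n, name in names.items()
                   if ptv_name.lower() in name.lower()]
    if not ptv_numbers:
        raise ValueError(
            f"no structure matching {ptv_name!r}; available: {sorted(names.values())}"
        )
    oar_numbers = [n for n, name in names.items()
                   if any(p in name.lower() for p in OAR_NAME_PARTS)]

    ptv_ct = _rasterize_structure(rtss, ptv_numbers[0], ct_grid)
    oar_ct = np.zeros(ct_grid.shape, dtype=np.uint8)
    for n in oar_numbers:
        oar_ct |= _rasterize_structure(rtss, n, ct_grid)

    density_ct = np.clip(1.0 + hu / 1000.0, 0.0, None)

    if target_grid is None:
        # model grid centered on the PTV centroid at 1 x 1 x 2 mm, 192 window
        centroid = StructureMask(ct_grid, ptv_ct).centroid()
        nz = ct_grid.nz
        origin = (centroid[0] - 96.0, centroid[1] - 96.0, float(ct_grid.origin[2]))
        target_grid = Grid3D(192, 192, nz, 1.0, 1.0, max(ct_grid.dz, 2.0), origin)

    density = resample_volume(density_ct, ct_grid, target_grid, "linear")
    ptv = StructureMask(
        target_grid, resample_volume(ptv_ct, ct_grid, target_grid, "nearest")
    )
    oar_vox = resample_volume(oar_ct, ct_grid, target_grid, "nearest")
    if not oar_vox.any():
        oar_vox = np.zeros(target_grid.shape, dtype=np.uint8)
    oar = StructureMask(target_grid, oar_vox)

    iso_idx = np.rint(target_grid.physical_to_index(ptv.centroid())).astype(int)
    return PhantomCase(
        grid=target_grid,
        density=density.astype(np.float32),
        ptv=ptv,
        oar=oar,
        isocenter=target_grid.index_to_physical(iso_idx),
        case_id=case_id or "dicom_case",
    )
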