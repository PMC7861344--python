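"""Shared geometry checks: dose-engine rotational consistency, BEV
round-trip, and opposed-beam mirror symmetry.  Used by both the module
tests and the acceptance geometry suite (which runs them on the larger
96x96x24 phantom)."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from fluenceforge.anatomy import PhantomCase
from fluenceforge.bev import project_dose_bev, project_ptv_bev
from fluenceforge.dose_engine import DoseEngine, EngineConfig, make_beams


def _rot_about(vol: np.ndarray, deg: float, center_xy) -> np.ndarray:
    """Active in-plane rotation of an (x, y, z) volume about a point."""
    t = np.deg2rad(deg)
    m = np.eye(3)
    m[0, 0] = np.cos(t)
    m[0, 1] = -np.sin(t)
    m[1, 0] = np.sin(t)
    m[1, 1] = np.cos(t)
    c = np.array([center_xy[0], center_xy[1], 0.0])
    return ndimage.affine_transform(vol, m, offset=c - m @ c, order=1,
                                    mode="constant")


def rotational_consistency_error(case: PhantomCase,
                                 config: EngineConfig | None = None) -> float:
    """Max in-body deviation (fraction of max dose) between beam k=1 on the
    original phantom and beam k=0 on the 40 deg-rotated phantom, rotated back.

    Requires the isocenter on the grid's central voxel.
    """
    config = config or EngineConfig.coarse()
    iso_idx = np.rint(case.grid.physical_to_index(case.isocenter)).astype(int)[:2]
    rng = np.random.default_rng(4)
    flu = ndimage.gaussian_filter(rng.random((config.fluence_n,) * 2), 2.0)

    d1 = DoseEngine(case, config).forward_beam(1, flu)
    case_rot = PhantomCase(
        grid=case.grid,
        density=_rot_about(case.density.astype(np.float64), -40.0, iso_idx),
        ptv=case.ptv,
        oar=case.oar,
        isocenter=case.isocenter,
    )
    d0_rot = DoseEngine(case_rot, config).forward_beam(0, flu)
    back = _rot_about(d0_rot, 40.0, iso_idx)
    body = case.density > 0.5
    return float(np.abs(back - d1)[body].max() / d1[body].max())


def bev_roundtrip_peak_offset(case: PhantomCase,
                              config: EngineConfig | None = None,
                              pixel=(0, 0)) -> float:
    """Project the dose of a single-pixel fluence back along the BEV; return
    the distance (in pixels) between the map's peak and the source pixel."""
    config = config or EngineConfig.coarse()
    beam = make_beams(case.isocenter, config)[2]
    nf = config.fluence_n
    c = (nf - 1) // 2
    pix = (c + pixel[0], c + pixel[1])
    flu = np.zeros((nf, nf))
    flu[pix] = 1.0
    engine = DoseEngine(case, config)
    engine.beams[2] = beam
    dose = engine.forward_beam(2, flu)
    bev = project_dose_bev(dose, beam, case.grid, config)
    peak = np.unravel_index(np.argmax(bev.values), bev.values.shape)
    return float(np.hypot(peak[0] - pix[0], peak[1] - pix[1]))


def opposed_beam_mirror_error(case: PhantomCase,
                              config: EngineConfig | None = None) -> float:
    """On a mirror-symmetric phantom, PTV maps of gantry t and t+180 must be
    mirror images in u; returns the fraction of disagreeing pixels."""
    config = config or EngineConfig.coarse()
    b0 = make_beams(case.isocenter, config)[0]
    from fluenceforge.dose_engine import Beam

    b180 = Beam(b0.gantry_deg + 180.0, b0.isocenter, 0, b0.sad_mm)
    m0 = project_ptv_bev(case.ptv, b0, config).values
    m180 = project_ptv_bev(case.ptv, b180, config).values
    mirrored = m0[::-1, :]
    return float(np.mean(mirrored != m180))
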