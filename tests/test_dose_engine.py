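"""Beam geometry and the forward dose operator."""

import numpy as np
import pytest

from fluenceforge.anatomy import Grid3D, PhantomCase, StructureMask
from fluenceforge.dose_engine import (
    Beam,
    DoseEngine,
    EngineConfig,
    FieldDoseSet,
    beam_frame,
    compute_beam_templates,
    compute_field_dose,
    make_beams,
    total_dose,
)

from conftest import make_centered_case
from geometry_checks import rotational_consistency_error


class TestBeamFrame:
    def test_gantry_zero_is_anterior(self):
        src, axis, u, v = beam_frame(Beam(0.0, (0, 0, 0), sad_mm=1000.0))
        assert np.allclose(axis, [0, 1, 0])
        assert np.allclose(src, [0, -1000, 0])
        assert np.allclose(v, [0, 0, 1])

    def test_opposed_beam_mirrors(self):
        s0, a0, u0, v0 = beam_frame(Beam(30.0, (0, 0, 0)))
        s1, a1, u1, v1 = beam_frame(Beam(210.0, (0, 0, 0)))
        assert np.allclose(a1, -a0)
        assert np.allclose(u1, -u0)
        assert np.allclose(v1, v0)

    def test_frames_are_rotations_of_each_other(self):
        # frames at k*40 deg are images of the k=0 frame under explicit
        # rotation matrices about the superior-inferior axis
        iso = np.array([5.0, -3.0, 10.0])
        beams = make_beams(iso, EngineConfig())
        assert len(beams) == 9
        s0, a0, u0, v0 = beam_frame(beams[0])
        for k, beam in enumerate(beams):
            t = np.deg2rad(40.0 * k)
            # rotation by -t about z maps the k=0 frame onto frame k
            rot = np.array(
                [[np.cos(t), np.sin(t), 0],
                 [-np.sin(t), np.cos(t), 0],
                 [0, 0, 1]]
            )
            sk, ak, uk, vk = beam_frame(beam)
            assert np.allclose(ak, rot @ a0, atol=1e-12)
            assert np.allclose(uk, rot @ u0, atol=1e-12)
            assert np.allclose(sk - iso, rot @ (s0 - iso), atol=1e-9)


class TestForwardOperator:
    def test_zero_fluence_zero_dose(self, coarse_engine):
        nf = coarse_engine.config.fluence_n
        dose = coarse_engine.forward_beam(0, np.zeros((nf, nf)))
        assert np.all(dose == 0)

    def test_linearity(self, coarse_engine):
        rng = np.random.default_rng(0)
        nf = coarse_engine.config.fluence_n
        f1, f2 = rng.random((nf, nf)), rng.random((nf, nf))
        d12 = coarse_engine.forward_beam(2, 2.5 * f1 + f2)
        d1 = coarse_engine.forward_beam(2, f1)
        d2 = coarse_engine.forward_beam(2, f2)
        assert np.allclose(d12, 2.5 * d1 + d2, rtol=1e-10, atol=1e-12)

    def test_nonnegativity(self, coarse_engine):
        rng = np.random.default_rng(1)
        nf = coarse_engine.config.fluence_n
        dose = coarse_engine.forward(rng.random((9, nf, nf)))
        assert np.all(dose.per_beam >= 0)

    def test_adjoint_identity(self, coarse_engine):
        rng = np.random.default_rng(2)
        nf = coarse_engine.config.fluence_n
        f = rng.random((nf, nf))
        g = rng.random(coarse_engine.case.grid.shape)
        lhs = float(np.sum(coarse_engine.forward_beam(4, f) * g))
        rhs = float(np.sum(f * coarse_engine.adjoint_beam(4, g)))
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_central_axis_decay_closed_form(self):
        # water-filled grid, no scatter blur: along the central axis the dose
        # equals fluence * exp(-mu (d - d_build)) * (SAD/r)^2 with d the
        # water depth from the anterior face -- evaluated independently here
        n, nz, dx = 32, 8, 4.0
        origin = (-(n // 2) * dx, -(n // 2) * dx, -(nz // 2) * dx)
        grid = Grid3D(n, n, nz, dx, dx, dx, origin)
        case = PhantomCase(
            grid=grid,
            density=np.ones(grid.shape, dtype=np.float32),
            ptv=StructureMask(grid, np.ones(grid.shape, dtype=np.uint8)),
            oar=StructureMask(grid, np.zeros(grid.shape, dtype=np.uint8)),
            isocenter=np.zeros(3),
        )
        config = EngineConfig.coarse()
        config = EngineConfig(
            fluence_n=32, fluence_pixel_mm=7.5, scatter_sigma_mm=0.0
        )
        engine = DoseEngine(case, config)
        dose = engine.forward_beam(0, np.ones((32, 32)))
        ix, iz = n // 2, nz // 2
        ys = grid.coords()[1]
        mu, build, sad = config.mu_att, config.d_build_mm, config.sad_mm
        for iy in range(n):
            depth = ys[iy] - ys[0] + 0.5 * dx   # water depth from entry
            r = sad + ys[iy]                     # source at y = -SAD
            expected = np.exp(-mu * max(0.0, depth - build)) * (sad / r) ** 2
            assert dose[ix, iy, iz] == pytest.approx(expected, rel=1e-6)

    def test_single_pixel_fluence_matches_bruteforce_influence(self):
        # the operator column of a 1-pixel fluence equals an independent
        # scalar-math ray computation on a coarse grid (gantry 0 and 90,
        # where the parallel-ray depth is exact)
        case = make_centered_case(n=24, nz=8, dx=8.0, dz=8.0, ptv_r_mm=30.0,
                                  body_ax=90.0, body_ay=90.0)
        config = EngineConfig(fluence_n=16, fluence_pixel_mm=15.0,
                              scatter_sigma_mm=0.0)
        for gantry in (0.0, 90.0):
            beam = Beam(gantry, tuple(case.isocenter), 0, config.sad_mm)
            engine = DoseEngine(case, config)
            engine.beams = [beam]
            from fluenceforge.dose_engine import _BeamGeometry

            geom = _BeamGeometry(beam, case, config)
            pix = (9, 8)
            flu = np.zeros((16, 16))
            flu[pix] = 1.0
            dose = geom.forward(flu)

            # independent computation with its own trigonometry
            t = np.deg2rad(gantry)
            axis = np.array([np.sin(t), np.cos(t), 0.0])
            uax = np.array([np.cos(t), -np.sin(t), 0.0])
            src = case.isocenter - config.sad_mm * axis
            xs, ys, zs = case.grid.coords()
            rng = np.random.default_rng(3)
            for _ in range(60):
                i, j, k = (rng.integers(0, s) for s in case.grid.shape)
                p = np.array([xs[i], ys[j], zs[k]])
                rel = p - src
                w = rel @ axis
                u = config.sad_mm * (rel @ uax) / w
                v = config.sad_mm * rel[2] / w
                fu = u / 15.0 + 7.5
                fv = v / 15.0 + 7.5
                # bilinear weight of the single nonzero pixel
                wu = max(0.0, 1.0 - abs(fu - pix[0]))
                wv = max(0.0, 1.0 - abs(fv - pix[1]))
                # water-equivalent depth along the (parallel) beam direction
                s_along = p @ axis
                # body is a centered circle r=90 in-plane: entry coordinate
                perp = p - (p @ axis) * axis
                perp2 = perp[0] ** 2 + perp[1] ** 2
                if perp2 < 90.0**2:
                    entry = -np.sqrt(90.0**2 - perp2)
                    depth = max(0.0, s_along - entry)
                else:
                    depth = 0.0
                kernel = (config.sad_mm / np.linalg.norm(rel)) ** 2 * np.exp(
                    -config.mu_att * max(0.0, depth - config.d_build_mm)
                )
                expected = wu * wv * kernel
                assert dose[i, j, k] == pytest.approx(expected, abs=2e-2 * max(expected, 0.05))

    def test_rotational_consistency(self, centered_case):
        # rotating the phantom by 40 deg about the SI axis and shifting the
        # beam index by one yields the same in-body dose within
        # interpolation error (< 2% of max)
        assert rotational_consistency_error(centered_case) <= 0.02


class TestTemplates:
    def test_normalized_and_nonnegative(self, coarse_phantom, coarse_engine):
        tpl = compute_beam_templates(coarse_phantom, engine=coarse_engine)
        assert tpl.per_beam.shape[0] == 9
        assert np.all(tpl.per_beam >= 0)
        assert np.allclose(tpl.per_beam.max(axis=(1, 2, 3)), 1.0)

    def test_monotone_in_aperture_margin(self, coarse_phantom, coarse_engine):
        a_small = coarse_engine.apertures(margin_mm=2.0)
        a_big = coarse_engine.apertures(margin_mm=8.0)
        assert np.all(a_small <= a_big)

    def test_empty_ptv_error(self, coarse_phantom):
        bad = PhantomCase(
            grid=coarse_phantom.grid,
            density=coarse_phantom.density,
            ptv=StructureMask(coarse_phantom.grid,
                              np.zeros(coarse_phantom.grid.shape)),
            oar=coarse_phantom.oar,
            isocenter=coarse_phantom.isocenter,
        )
        engine = DoseEngine(bad, EngineConfig.coarse())
        with pytest.raises(ValueError, match="empty PTV"):
            engine.apertures()


class TestTotalDose:
    def _fds(self, arrays, grid):
        return FieldDoseSet(per_beam=np.stack(arrays), grid=grid)

    def test_zero_and_single_beam(self, coarse_phantom):
        grid = coarse_phantom.grid
        z = np.zeros(grid.shape)
        rng = np.random.default_rng(5)
        d = rng.random(grid.shape)
        assert np.all(total_dose(self._fds([z, z, z], grid)) == 0)
        assert np.allclose(total_dose(self._fds([z, d, z], grid)), d)

    def test_permutation_invariant(self, coarse_phantom):
        rng = np.random.default_rng(6)
        arrays = [rng.random(coarse_phantom.grid.shape) for _ in range(4)]
        t1 = total_dose(self._fds(arrays, coarse_phantom.grid))
        t2 = total_dose(self._fds(arrays[::-1], coarse_phantom.grid))
        assert np.allclose(t1, t2)


def test_compute_field_dose_wrapper(coarse_phantom):
    from fluenceforge.dose_engine import FluenceMap

    config = EngineConfig.coarse()
    beam = make_beams(coarse_phantom.isocenter, config)[0]
    nf = config.fluence_n
    flu = FluenceMap(np.ones((nf, nf)), config.fluence_pixel_mm, beam)
    dose = compute_field_dose(flu, coarse_phantom, config)
    assert dose.shape == coarse_phantom.grid.shape
    assert dose.max() > 0
    with pytest.raises(ValueError, match="pixel"):
        compute_field_dose(
            FluenceMap(np.ones((nf, nf)), 1.0, beam), coarse_phantom, config
        )
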