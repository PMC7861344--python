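"""Shared fixtures.

The session-scoped ``e2e`` fixture runs the full desk-scale experiment
(40-case cohort, 30 train / 10 test, both networks trained) exactly once;
the end-to-end and learning-curve tests all reuse its artifacts.
"""

from __future__ import annotations

import numpy as np
import pytest

from fluenceforge import (
    EngineConfig,
    ExperimentConfig,
    PhantomConfig,
    generate_phantom,
    run_experiment,
)
from fluenceforge.anatomy import Grid3D, PhantomCase, StructureMask
from fluenceforge.dose_engine import DoseEngine

E2E_SEED = 7  # fixed study seed for the shared experiment


@pytest.fixture(scope="session")
def coarse_phantom() -> PhantomCase:
    return generate_phantom(1, PhantomConfig.coarse())


@pytest.fixture(scope="session")
def coarse_engine(coarse_phantom) -> DoseEngine:
    return DoseEngine(coarse_phantom, EngineConfig.coarse())


def make_centered_case(n=48, nz=16, dx=4.0, dz=4.0, ptv_r_mm=20.0,
                       body_ax=85.0, body_ay=60.0) -> PhantomCase:
    """Analytic case with the isocenter exactly at the central voxel:
    centered ellipse body, centered spherical PTV, lateral tubular OAR."""
    origin = (-(n // 2) * dx, -(n // 2) * dx, -(nz // 2) * dz)
    grid = Grid3D(n, n, nz, dx, dx, dz, origin)
    xs, ys, zs = grid.coords()
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    body = (gx / body_ax) ** 2 + (gy / body_ay) ** 2 <= 1.0
    ptv = gx**2 + gy**2 + gz**2 <= ptv_r_mm**2
    oar = (gx - 45.0) ** 2 + gy**2 <= 10.0**2
    return PhantomCase(
        grid=grid,
        density=body.astype(np.float32),
        ptv=StructureMask(grid, ptv & body),
        oar=StructureMask(grid, oar & body),
        isocenter=np.zeros(3),
        case_id="centered",
    )


@pytest.fixture(scope="session")
def centered_case() -> PhantomCase:
    return make_centered_case()


@pytest.fixture(scope="session")
def geometry_case() -> PhantomCase:
    """The 96x96x24 phantom used by the geometry suite."""
    return make_centered_case(n=96, nz=24, dx=2.0, dz=3.0)


@pytest.fixture(scope="session")
def e2e():
    """The shared desk-scale end-to-end experiment (trains both networks)."""
    return run_experiment(seed=E2E_SEED, config=ExperimentConfig())
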