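"""Benchmark-plan generation by fluence-map optimization.

The training ground truth is a standardized nine-beam plan per phantom:
33 Gy / 5 fx to the PTV with the OAR maximum (0.1 cc) limited to 25 Gy —
an inverted prescription (OAR limit below the target dose).  A transparent
quadratic-penalty objective stands in for expert inverse planning:

* PTV term: mean squared deviation from 100% Rx;
* OAR term: one-sided quadratic above 75.76% Rx (= 25/33), an OAR-dominant
  weight making the maximum-dose limit outweigh target coverage;
* body term: one-sided quadratic above 80% Rx outside the ROI;
* smoothness: mean squared first differences of each fluence map.

Optimization is projected gradient descent (nonnegativity projection after
every step) with a backtracking line search, so the objective trace is
non-increasing.  The exact OAR D_max(0.1 cc) metric is enforced only at
accept/reject time; plans exceeding 80% Rx there are rejected and the
phantom is redrawn upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import PhantomCase, PhantomConfig, generate_phantom
from .dose_engine import (
    BeamTemplateSet,
    DoseEngine,
    EngineConfig,
    FieldDoseSet,
    compute_beam_templates,
)
from .evaluation import dvh_metrics

OAR_LIMIT_PCT = 25.0 / 33.0 * 100.0  # 75.7575...% Rx


@dataclass(frozen=True)
class ProtocolConfig:
    """Prescription protocol; the OAR limit sits below the target dose."""

    rx_gy: float = 33.0
    n_fractions: int = 5
    oar_limit_gy: float = 25.0
    oar_limit_cc: float = 0.1
    n_beams: int = 9
    reject_oar_dmax_pct: float = 80.0   # accept/reject bound on D_max(0.1cc), % Rx

    def __post_init__(self):
        if self.oar_limit_gy >= self.rx_gy:
            raise ValueError("protocol requires OAR limit < prescription")

    @property
    def oar_limit_pct(self) -> float:
        return self.oar_limit_gy / self.rx_gy * 100.0


@dataclass(frozen=True)
class ObjectiveWeights:
    w_ptv: float = 1.0
    w_oar: float = 50.0
    w_body: float = 1.0
    w_smooth: float = 0.1


@dataclass(frozen=True)
class OptimizerConfig:
    max_iter: int = 100
    rel_tol: float = 1e-5
    max_backtracks: int = 25
    step_growth: float = 1.25
    cleanup_fraction: float = 1e-3   # zero fluence pixels below this fraction of max
    weights: ObjectiveWeights = field(default_factory=ObjectiveWeights)


class PlanRejected(RuntimeError):
    """Raised when an optimized plan violates the protocol's OAR bound."""


@dataclass
class BenchmarkPlan:
    """Optimized ground-truth plan for one phantom.

    ``fluences`` are in raw engine units; ``field_doses`` are calibrated to
    % Rx via ``calibration`` (benchmark PTV mean = 100%), and the same scalar
    must be reused when converting predicted fluences of this case to % Rx.
    """

    case_id: str
    fluences: np.ndarray                 # (n_beams, nf, nf), >= 0
    field_doses: FieldDoseSet            # % Rx
    calibration: float
    protocol: ProtocolConfig
    converged: bool
    objective_trace: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.field_doses.total


def _masks(case: PhantomCase, roi_margin_mm: float = 10.0):
    ptv = case.ptv.voxels > 0
    oar = case.oar.voxels > 0
    roi = case.roi(roi_margin_mm).voxels > 0
    body = (case.density > 0.5) & ~roi
    return ptv, oar, body


def _smooth_penalty(fluences: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared first differences over all maps, with gradient."""
    du = np.diff(fluences, axis=1)
    dv = np.diff(fluences, axis=2)
    n = du.size + dv.size
    val = (np.sum(du**2) + np.sum(dv**2)) / n
    grad = np.zeros_like(fluences)
    grad[:, 1:, :] += 2 * du / n
    grad[:, :-1, :] -= 2 * du / n
    grad[:, :, 1:] += 2 * dv / n
    grad[:, :, :-1] -= 2 * dv / n
    return float(val), grad


def plan_objective(
    fluences: np.ndarray,
    case: PhantomCase,
    weights: ObjectiveWeights | None = None,
    engine: DoseEngine | None = None,
    total: np.ndarray | None = None,
) -> float:
    """Quadratic-penalty planning objective (doses on the ~% Rx scale)."""
    weights = weights or ObjectiveWeights()
    if total is None:
        engine = engine or DoseEngine(case)
        total = engine.forward(np.asarray(fluences)).total
    ptv, oar, body = _masks(case)
    obj = weights.w_ptv * float(np.mean((total[ptv] - 100.0) ** 2))
    if oar.any():
        obj += weights.w_oar * float(
            np.mean(np.maximum(0.0, total[oar] - OAR_LIMIT_PCT) ** 2)
        )
    if body.any():
        obj += weights.w_body * float(np.mean(np.maximum(0.0, total[body] - 80.0) ** 2))
    sval, _ = _smooth_penalty(np.asarray(fluences, dtype=np.float64))
    return obj + weights.w_smooth * sval


def _dose_gradient(total, ptv, oar, body, weights) -> np.ndarray:
    g = np.zeros_like(total)
    g[ptv] += weights.w_ptv * 2.0 * (total[ptv] - 100.0) / ptv.sum()
    if oar.any():
        g[oar] += weights.w_oar * 2.0 * np.maximum(0.0, total[oar] - OAR_LIMIT_PCT) / oar.sum()
    if body.any():
        g[body] += weights.w_body * 2.0 * np.maximum(0.0, total[body] - 80.0) / body.sum()
    return g


def optimize_fluence(
    case: PhantomCase,
    protocol: ProtocolConfig | None = None,
    opt_config: OptimizerConfig | None = None,
    engine: DoseEngine | None = None,
) -> BenchmarkPlan:
    """Projected-gradient benchmark optimization for one phantom.

    Deterministic: initialization is a uniform fluence over each conformal
    aperture, scaled so the initial PTV mean dose is 100.  Returns
    ``converged=False`` (rather than failing) when the iteration cap is hit;
    raises :class:`PlanRejected` when the final OAR D_max(0.1 cc) exceeds
    the protocol's rejection bound.
    """
    protocol = protocol or ProtocolConfig()
    cfg = opt_config or OptimizerConfig()
    engine = engine or DoseEngine(case)
    w = cfg.weights
    ptv, oar, body = _masks(case)

    f = engine.apertures().astype(np.float64)
    per_beam = engine.forward(f).per_beam
    total = per_beam.sum(axis=0)
    mean_ptv = total[ptv].mean()
    if mean_ptv <= 0:
        raise PlanRejected("initial aperture dose misses the PTV")
    f *= 100.0 / mean_ptv
    per_beam *= 100.0 / mean_ptv
    total = per_beam.sum(axis=0)

    def objective(fl, tot):
        obj = w.w_ptv * float(np.mean((tot[ptv] - 100.0) ** 2))
        if oar.any():
            obj += w.w_oar * float(np.mean(np.maximum(0.0, tot[oar] - OAR_LIMIT_PCT) ** 2))
        if body.any():
            obj += w.w_body * float(np.mean(np.maximum(0.0, tot[body] - 80.0) ** 2))
        return obj + w.w_smooth * _smooth_penalty(fl)[0]

    obj = objective(f, total)
    trace = [obj]
    n_beams = f.shape[0]
    step = None
    converged = False
    for _ in range(cfg.max_iter):
        gd = _dose_gradient(total, ptv, oar, body, w)
        grad = np.stack([engine.adjoint_beam(k, gd) for k in range(n_beams)])
        grad += w.w_smooth * _smooth_penalty(f)[1]
        gmax = np.abs(grad).max()
        if gmax == 0:
            converged = True
            break
        if step is None:
            step = 0.05 * max(f.max(), 1.0) / gmax
        accepted = False
        for _bt in range(cfg.max_backtracks):
            f_new = np.maximum(0.0, f - step * grad)
            pb_new = np.stack(
                [engine.forward_beam(k, f_new[k]) for k in range(n_beams)]
            )
            tot_new = pb_new.sum(axis=0)
            obj_new = objective(f_new, tot_new)
            if obj_new < obj:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True
            break
        rel = (obj - obj_new) / max(obj, 1e-30)
        f, per_beam, total, obj = f_new, pb_new, tot_new, obj_new
        trace.append(obj)
        step *= cfg.step_growth
        if rel < cfg.rel_tol:
            converged = True
            break

    # deliverable-fluence cleanup: drop sub-threshold transmission pixels so
    # the positive support of each map is the real aperture
    if cfg.cleanup_fraction > 0 and f.max() > 0:
        f[f < cfg.cleanup_fraction * f.max()] = 0.0
        per_beam = np.stack(
            [engine.forward_beam(k, f[k]) for k in range(n_beams)]
        )
        total = per_beam.sum(axis=0)

    cal = 100.0 / total[ptv].mean()
    total_pct = total * cal
    if oar.any():
        oar_dmax = dvh_metrics(total_pct, oar, case.grid.voxel_cc).d_max_01cc
        if oar_dmax > protocol.reject_oar_dmax_pct:
            raise PlanRejected(
                f"OAR D_max(0.1cc) = {oar_dmax:.1f}% Rx exceeds "
                f"{protocol.reject_oar_dmax_pct}% Rx"
            )
    return BenchmarkPlan(
        case_id=case.case_id,
        fluences=f,
        field_doses=FieldDoseSet(per_beam=(per_beam * cal).astype(np.float32),
                                 grid=case.grid),
        calibration=float(cal),
        protocol=protocol,
        converged=converged,
        objective_trace=np.asarray(trace),
    )


# ---------------------------------------------------------------------------
# Cohort construction
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Phantoms + benchmark plans + templates with a train/test split."""

    cases: dict[str, PhantomCase]
    plans: dict[str, BenchmarkPlan]
    templates: dict[str, BeamTemplateSet]
    train_ids: list[str]
    test_ids: list[str]
    seed: int

    @property
    def case_ids(self) -> list[str]:
        return self.train_ids + self.test_ids


def split_ids(case_ids: list[str], seed: int, train_fraction: float = 0.85):
    """Deterministic random split; the test count is floored (100 -> 85/15)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(case_ids))
    n_test = int(np.floor(len(case_ids) * (1.0 - train_fraction)))
    test = sorted(perm[:n_test].tolist())
    test_ids = [case_ids[i] for i in test]
    train_ids = [cid for cid in case_ids if cid not in set(test_ids)]
    return train_ids, test_ids


def _derived_seed(*parts) -> int:
    return int(np.random.SeedSequence(parts).generate_state(1)[0] % (2**31))


def build_cohort(
    n_cases: int,
    seed: int,
    phantom_config: PhantomConfig | None = None,
    engine_config: EngineConfig | None = None,
    protocol: ProtocolConfig | None = None,
    opt_config: OptimizerConfig | None = None,
    train_fraction: float = 0.85,
    with_plans: bool = True,
    max_redraws: int = 8,
    progress: bool = False,
) -> Cohort:
    """Generate ``n_cases`` phantoms with benchmark plans and split them.

    Phantoms whose optimized plan is rejected (OAR bound violated) are
    redrawn with a fresh derived seed.  Fully deterministic in ``seed``.
    """
    phantom_config = phantom_config or PhantomConfig()
    engine_config = engine_config or EngineConfig()
    protocol = protocol or ProtocolConfig()
    cases: dict[str, PhantomCase] = {}
    plans: dict[str, BenchmarkPlan] = {}
    templates: dict[str, BeamTemplateSet] = {}
    for i in range(n_cases):
        plan = None
        case = None
        tpl = None
        for redraw in range(max_redraws):
            case_seed = _derived_seed(seed, i, redraw)
            case = generate_phantom(case_seed, phantom_config, case_id=f"case{i:04d}")
            if not with_plans:
                break
            engine = DoseEngine(case, engine_config)
            tpl = compute_beam_templates(case, engine=engine)
            try:
                plan = optimize_fluence(case, protocol, opt_config, engine)
                break
            except PlanRejected:
                plan = None
                continue
        if with_plans and plan is None:
            raise RuntimeError(
                f"no acceptable benchmark plan for cohort slot {i} "
                f"after {max_redraws} redraws"
            )
        cases[case.case_id] = case
        if with_plans:
            plans[case.case_id] = plan
            templates[case.case_id] = tpl
        if progress:
            print(f"  cohort case {i + 1}/{n_cases} done", flush=True)
    train_ids, test_ids = split_ids(list(cases.keys()), seed, train_fraction)
    return Cohort(
        cases=cases, plans=plans, templates=templates,
        train_ids=train_ids, test_ids=test_ids, seed=seed,
    )
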