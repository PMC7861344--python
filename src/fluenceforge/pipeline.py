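"""End-to-end experiment orchestration.

Ties the pieces together in pipeline order: synthetic cohort with benchmark
plans -> FD-CNN training -> BEV projection -> FM-CNN training -> plan
prediction on held-out cases -> evaluation.  Three plan variants are
produced per test case:

* ``fd_cnn_dose`` — the FD-CNN field dose itself (dose quality of CNN #1);
* ``fm_cnn_plan`` — FM-CNN fed with the *benchmark* field dose, isolating
  CNN #2 from upstream error;
* ``model_predicted_plan`` — the full chain FD-CNN -> BEV -> FM-CNN ->
  forward dose.

Predicted fluences are converted to % Rx with the benchmark plan's
calibration scalar, keeping all comparisons on one scale.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .anatomy import PhantomCase, PhantomConfig, build_fd_samples
from .bev import project_case
from .dose_engine import DoseEngine, EngineConfig, FluenceMap, make_beams
from .evaluation import (
    PredictedPlan,
    aggregate_reports,
    evaluate_case,
    fluence_mae,
)
from .fd_net import FDNet, FDNetConfig, predict_field_dose, train_fd, evaluate_fd_loss
from .fm_net import (
    FMModel,
    FMNetConfig,
    FMSample,
    predict_fluences,
    train_fm,
)
from .planner import Cohort, OptimizerConfig, ProtocolConfig, build_cohort


@dataclass(frozen=True)
class ExperimentConfig:
    """Study conditions for one end-to-end experiment.

    The desk-scale defaults: a 40-case cohort (30 train / 10 test) on the
    coarse 48x48x16 grid with reduced-width networks.
    """

    n_cases: int = 40
    train_fraction: float = 0.75
    phantom: PhantomConfig = field(default_factory=PhantomConfig.coarse)
    engine: EngineConfig = field(default_factory=EngineConfig.coarse)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    fd: FDNetConfig = field(default_factory=FDNetConfig.coarse)
    fm: FMNetConfig = field(default_factory=FMNetConfig.coarse)
    roi_margin_mm: float = 10.0

    @staticmethod
    def full() -> "ExperimentConfig":
        """Clinical-scale geometry (192x192 at 1 mm, 96x96 fluence at 2.5 mm)."""
        return ExperimentConfig(
            n_cases=100,
            train_fraction=0.85,
            phantom=PhantomConfig(),
            engine=EngineConfig(),
            fd=FDNetConfig(),
            fm=FMNetConfig(),
        )


# ---------------------------------------------------------------------------
# Sample assembly
# ---------------------------------------------------------------------------

def cohort_fd_samples(cohort: Cohort, ids: list[str], config: ExperimentConfig):
    samples = []
    for cid in ids:
        samples.extend(
            build_fd_samples(
                cohort.cases[cid],
                cohort.plans[cid].field_doses.per_beam,
                cohort.templates[cid].per_beam,
                roi_margin_mm=config.roi_margin_mm,
            )
        )
    return samples


def case_bev_maps(case: PhantomCase, field_doses: np.ndarray, config: ExperimentConfig):
    """BEV dose + PTV maps (n_beams, nf, nf) for one case's field doses.

    The projection averages dose over the ROI-intersecting portion of each
    ray: the dose prediction is only defined inside the ROI, so using the
    same ROI-restricted projection for benchmark doses keeps the FM input
    distribution identical between the benchmark pathway (training) and the
    predicted pathway (inference), and keeps map values on the % Rx scale.
    """
    roi = case.roi(config.roi_margin_mm).voxels
    return project_case(case, field_doses, config.engine, region=roi)


def cohort_fm_samples(cohort: Cohort, ids: list[str], config: ExperimentConfig):
    """FM training samples from benchmark field doses and fluences."""
    samples = []
    for cid in ids:
        case = cohort.cases[cid]
        plan = cohort.plans[cid]
        dose_maps, ptv_maps = case_bev_maps(case, plan.field_doses.per_beam, config)
        beams = make_beams(case.isocenter, config.engine)
        from .bev import BEVMap

        for k, beam in enumerate(beams):
            samples.append(
                FMSample(
                    bev_dose=BEVMap(dose_maps[k], config.engine.fluence_pixel_mm,
                                    beam, "dose"),
                    bev_ptv=BEVMap(ptv_maps[k], config.engine.fluence_pixel_mm,
                                   beam, "ptv_binary"),
                    target_fluence=FluenceMap(plan.fluences[k],
                                              config.engine.fluence_pixel_mm, beam),
                )
            )
    return samples


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_plans(
    case: PhantomCase,
    cohort: Cohort,
    fd_model: FDNet,
    fm_model: FMModel,
    config: ExperimentConfig,
    engine: DoseEngine | None = None,
) -> dict[str, PredictedPlan]:
    """All three predicted plan variants for one (test) case."""
    plan = cohort.plans[case.case_id]
    templates = cohort.templates[case.case_id].per_beam
    engine = engine or DoseEngine(case, config.engine)
    cal = plan.calibration

    # CNN #1: field dose prediction
    fd_pred = predict_field_dose(case, fd_model, templates, config.roi_margin_mm)

    # CNN #2 alone: benchmark field dose -> BEV -> fluence -> dose
    bench_dose_maps, ptv_maps = case_bev_maps(case, plan.field_doses.per_beam, config)
    fm_flu = predict_fluences(bench_dose_maps, ptv_maps, fm_model)
    fm_doses = engine.forward(fm_flu).per_beam * cal

    # full chain: FD-CNN dose -> BEV -> fluence -> dose
    pred_dose_maps, _ = case_bev_maps(case, fd_pred.per_beam, config)
    model_flu = predict_fluences(pred_dose_maps, ptv_maps, fm_model)
    model_doses = engine.forward(model_flu).per_beam * cal

    return {
        "fd_cnn_dose": PredictedPlan(total=fd_pred.total, per_beam=fd_pred.per_beam),
        "fm_cnn_plan": PredictedPlan(
            total=fm_doses.sum(axis=0), per_beam=fm_doses, fluences=fm_flu
        ),
        "model_predicted_plan": PredictedPlan(
            total=model_doses.sum(axis=0), per_beam=model_doses, fluences=model_flu
        ),
    }


# ---------------------------------------------------------------------------
# The experiment
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    cohort: Cohort
    fd_model: FDNet
    fm_model: FMModel
    fd_history: object
    fm_history: object
    reports: list[pd.DataFrame]
    summary: pd.DataFrame
    metrics: dict[str, float]


def _mean_metric(reports, plan, region, metric) -> float:
    df = pd.concat(reports, ignore_index=True)
    sel = df[(df.plan == plan) & (df.region == region) & (df.metric == metric)]
    return float(sel.value.mean())


def run_experiment(
    seed: int,
    config: ExperimentConfig | None = None,
    cohort: Cohort | None = None,
    progress: bool = False,
) -> ExperimentResult:
    """Build (or reuse) a cohort, train both networks, evaluate test cases."""
    config = config or ExperimentConfig()
    t0 = time.time()
    if cohort is None:
        cohort = build_cohort(
            config.n_cases,
            seed,
            phantom_config=config.phantom,
            engine_config=config.engine,
            protocol=config.protocol,
            opt_config=config.optimizer,
            train_fraction=config.train_fraction,
            progress=progress,
        )
    if progress:
        print(f"cohort ready ({time.time() - t0:.0f}s); training FD-CNN", flush=True)

    fd_cfg = replace(config.fd, seed=_net_seed(seed, 1))
    fd_samples = cohort_fd_samples(cohort, cohort.train_ids, config)
    fd_model, fd_history = train_fd(fd_samples, fd_cfg)
    if progress:
        print(f"FD-CNN trained ({time.time() - t0:.0f}s); training FM-CNN", flush=True)

    fm_cfg = replace(config.fm, seed=_net_seed(seed, 2))
    fm_samples = cohort_fm_samples(cohort, cohort.train_ids, config)
    fm_model, fm_history = train_fm(fm_samples, fm_cfg)
    if progress:
        print(f"FM-CNN trained ({time.time() - t0:.0f}s); evaluating", flush=True)

    reports = []
    fm_maes = []
    for cid in cohort.test_ids:
        case = cohort.cases[cid]
        plan = cohort.plans[cid]
        predicted = predict_plans(case, cohort, fd_model, fm_model, config)
        reports.append(
            evaluate_case(
                case,
                plan,
                predicted,
                roi_margin_mm=config.roi_margin_mm,
                gamma_pixel_mm=config.engine.fluence_pixel_mm,
            )
        )
        flu = predicted["fm_cnn_plan"].fluences
        fm_maes.append(
            np.mean([
                fluence_mae(plan.fluences[k] / fm_model.fluence_norm,
                            flu[k] / fm_model.fluence_norm)
                for k in range(flu.shape[0])
            ])
        )
    summary = aggregate_reports(reports)
    metrics = {
        "fd_roi_voxel_dd_pct": _mean_metric(reports, "fd_cnn_dose", "ROI",
                                            "voxel_dd_pct"),
        "fd_ptv_voxel_dd_pct": _mean_metric(reports, "fd_cnn_dose", "PTV",
                                            "voxel_dd_pct"),
        "fm_plan_ptv_dmean_diff_pct": _mean_metric(reports, "fm_cnn_plan", "PTV",
                                                   "abs_dmean_diff_pct"),
        "model_plan_ptv_dmean_diff_pct": _mean_metric(
            reports, "model_predicted_plan", "PTV", "abs_dmean_diff_pct"),
        "model_plan_ptv_voxel_dd_pct": _mean_metric(
            reports, "model_predicted_plan", "PTV", "voxel_dd_pct"),
        "fm_fluence_mae_norm": float(np.mean(fm_maes)),
        "model_gamma_pass_pct": _mean_metric(reports, "model_predicted_plan",
                                             "fluence", "gamma_pass_pct"),
        "n_train_cases": float(len(cohort.train_ids)),
        "n_test_cases": float(len(cohort.test_ids)),
        "n_fd_train_slices": float(len(fd_samples)),
        "n_fm_train_maps": float(len(fm_samples)),
    }
    return ExperimentResult(
        cohort=cohort,
        fd_model=fd_model,
        fm_model=fm_model,
        fd_history=fd_history,
        fm_history=fm_history,
        reports=reports,
        summary=summary,
        metrics=metrics,
    )


def _net_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence((seed, salt)).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Learning-curve and ablation studies
# ---------------------------------------------------------------------------

def fd_learning_curve(
    cohort: Cohort,
    config: ExperimentConfig,
    sizes: list[int],
    seed: int,
    trained_full: FDNet | None = None,
) -> dict[int, float]:
    """FD test loss vs number of training cases (network units).

    If ``trained_full`` is given it is reused for the largest size.
    """
    test_samples = cohort_fd_samples(cohort, cohort.test_ids, config)
    out = {}
    for size in sizes:
        if size > len(cohort.train_ids):
            raise ValueError("size exceeds available training cases")
        if trained_full is not None and size == len(cohort.train_ids):
            model = trained_full
        else:
            sub = cohort.train_ids[:size]
            samples = cohort_fd_samples(cohort, sub, config)
            model, _ = train_fd(samples, replace(config.fd, seed=_net_seed(seed, 1)))
        out[size] = evaluate_fd_loss(model, test_samples)
    return out


def fd_template_ablation(
    cohort: Cohort,
    config: ExperimentConfig,
    seed: int,
    trained_full: FDNet | None = None,
) -> dict[str, float]:
    """FD test loss with and without the beam-template input."""
    test_samples = cohort_fd_samples(cohort, cohort.test_ids, config)
    train_samples = cohort_fd_samples(cohort, cohort.train_ids, config)
    if trained_full is None:
        trained_full, _ = train_fd(train_samples,
                                   replace(config.fd, seed=_net_seed(seed, 1)))
    ablated_cfg = replace(config.fd, use_templates=False, seed=_net_seed(seed, 1))
    ablated, _ = train_fd(train_samples, ablated_cfg)
    return {
        "with_templates": evaluate_fd_loss(trained_full, test_samples),
        "without_templates": evaluate_fd_loss(ablated, test_samples),
    }
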