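"""Plan evaluation: voxel-wise dose differences, DVH endpoints, gamma analysis.

All doses are handled in percent of the prescription (33 Gy = 100%), so the
voxel-wise percentage dose difference uses a normalization of 100.  The
gamma comparator is a general two-map implementation (global normalization
to the reference maximum, 3%/3 mm by default, 10% low-dose cutoff) applied
here to predicted-vs-benchmark fluence maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage


# ---------------------------------------------------------------------------
# Voxel-wise dose difference and DVH endpoints
# ---------------------------------------------------------------------------

@dataclass
class EvalRegion:
    """Named voxel set over which dose differences are averaged."""

    name: str
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask) > 0
        if not self.mask.any():
            raise ValueError(f"evaluation region {self.name!r} is empty")


def voxel_dose_difference(
    d_bench: np.ndarray,
    d_pred: np.ndarray,
    region: EvalRegion | np.ndarray,
    d_rx: float = 100.0,
) -> float:
    """Mean absolute voxel dose difference in the region, as % of prescription.

    With doses already in % Rx the normalization ``d_rx`` is 100.
    """
    mask = region.mask if isinstance(region, EvalRegion) else np.asarray(region) > 0
    if not mask.any():
        raise ValueError("empty evaluation region")
    diff = np.abs(np.asarray(d_bench, float)[mask] - np.asarray(d_pred, float)[mask])
    return float(diff.mean() / d_rx * 100.0)


@dataclass(frozen=True)
class DVHMetrics:
    d_mean: float
    d_max_01cc: float      # dose fully covering the hottest 0.1 cc
    d_95: float            # dose received by >= 95% of the volume


def dvh_metrics(dose: np.ndarray, mask: np.ndarray, voxel_cc: float = 0.002) -> DVHMetrics:
    """DVH endpoints over a structure.

    ``d_max_01cc`` is the minimum dose among the hottest ceil(0.1/voxel_cc)
    voxels; ``d_95`` is the nearest-rank 5th percentile of in-structure dose.
    Structures smaller than 0.1 cc fall back to the plain maximum (warning).
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("empty structure mask")
    vals = np.sort(np.asarray(dose, float)[mask])
    n = vals.size
    n_hot = int(np.ceil(0.1 / voxel_cc))
    if n < n_hot:
        warnings.warn("structure smaller than 0.1 cc; D_max(0.1cc) = plain max")
        d_max = float(vals[-1])
    else:
        d_max = float(vals[n - n_hot])
    rank = max(1, int(np.ceil(0.05 * n)))
    return DVHMetrics(
        d_mean=float(vals.mean()), d_max_01cc=d_max, d_95=float(vals[rank - 1])
    )


def dvh_curve(dose: np.ndarray, mask: np.ndarray, edges: np.ndarray | None = None):
    """Cumulative DVH: fraction of structure volume receiving >= each dose level."""
    mask = np.asarray(mask) > 0
    vals = np.asarray(dose, float)[mask]
    if edges is None:
        edges = np.linspace(0.0, max(float(vals.max()), 1.0) * 1.05, 200)
    frac = (vals[None, :] >= edges[:, None]).mean(axis=1)
    return edges, frac


# ---------------------------------------------------------------------------
# 2-D gamma analysis
# ---------------------------------------------------------------------------

@dataclass
class GammaResult:
    pass_rate: float               # percent of evaluated pixels with gamma <= 1
    gamma_map: np.ndarray          # NaN where below the low-dose cutoff
    dose_crit: float               # absolute dose criterion (3% of reference max)
    dist_crit: float               # mm
    low_dose_cutoff: float


def _sample(evaluated: np.ndarray, coords_i, coords_j) -> np.ndarray:
    """Bilinear sample; positions outside the map return NaN (invalid candidate)."""
    return ndimage.map_coordinates(
        evaluated, [coords_i, coords_j], order=1, mode="constant", cval=np.nan
    )


def gamma_2d(
    reference: np.ndarray,
    evaluated: np.ndarray,
    dose_pct: float = 3.0,
    dist_mm: float = 3.0,
    pixel_mm: float = 2.5,
    cutoff_fraction: float = 0.10,
    search_factor: float = 3.0,
    subsample: int = 10,
) -> GammaResult:
    """Global-normalization gamma index between two pixel-aligned 2-D maps.

    For each reference pixel above the low-dose cutoff the minimum of
    ``sqrt((dD/crit_d)^2 + (dr/crit_r)^2)`` is searched over evaluated-map
    positions within ``search_factor * dist_mm`` at 1/``subsample`` pixel
    steps (bilinear), then refined locally to sub-milli-pixel resolution.
    The truncated search radius cannot change pass/fail: any position beyond
    ``dist_mm`` already has a distance term above 1.
    """
    reference = np.asarray(reference, dtype=np.float64)
    evaluated = np.asarray(evaluated, dtype=np.float64)
    if reference.shape != evaluated.shape:
        raise ValueError("maps must share shape")
    ref_max = reference.max()
    if ref_max <= 0:
        raise ValueError("all-zero reference map")
    crit_d = dose_pct / 100.0 * ref_max
    crit_r = dist_mm
    sel = reference >= cutoff_fraction * ref_max
    ii, jj = np.nonzero(sel)
    ref_vals = reference[sel]

    # stage 1: coarse grid over the truncated search disk, nearest offsets first
    step = pixel_mm / subsample
    radius = search_factor * dist_mm
    m = int(np.floor(radius / step))
    offs = np.arange(-m, m + 1) * step
    ou, ov = np.meshgrid(offs, offs, indexing="ij")
    keep = ou**2 + ov**2 <= radius**2
    offsets = np.stack([ou[keep], ov[keep]], axis=1)
    order = np.argsort((offsets**2).sum(axis=1))
    offsets = offsets[order]

    best = np.full(ref_vals.shape, np.inf)
    best_off = np.zeros((ref_vals.size, 2))
    for du, dv in offsets:
        dist_term = (du * du + dv * dv) / (crit_r * crit_r)
        if best.size and dist_term >= best.max():
            break
        ev = _sample(evaluated, ii + du / pixel_mm, jj + dv / pixel_mm)
        cand = (ev - ref_vals) ** 2 / (crit_d * crit_d) + dist_term
        cand = np.where(np.isnan(cand), np.inf, cand)
        better = cand < best
        best = np.where(better, cand, best)
        best_off[better] = (du, dv)

    # stages 2-3: refine around each pixel's best offset
    for span, fine in ((step, step / 10.0), (step / 10.0, step / 100.0)):
        k = int(round(span / fine))
        f = np.arange(-k, k + 1) * fine
        for du in f:
            for dv in f:
                odu = best_off[:, 0] + du
                odv = best_off[:, 1] + dv
                ev = _sample(evaluated, ii + odu / pixel_mm, jj + odv / pixel_mm)
                cand = (ev - ref_vals) ** 2 / (crit_d * crit_d) + (
                    odu**2 + odv**2
                ) / (crit_r * crit_r)
                cand = np.where(np.isnan(cand), np.inf, cand)
                better = cand < best
                if better.any():
                    newu = np.where(better, odu, best_off[:, 0])
                    newv = np.where(better, odv, best_off[:, 1])
                    best = np.where(better, cand, best)
                    best_off = np.stack([newu, newv], axis=1)

    gamma_vals = np.sqrt(best)
    gamma_map = np.full(reference.shape, np.nan)
    gamma_map[sel] = gamma_vals
    pass_rate = float((gamma_vals <= 1.0).mean() * 100.0) if gamma_vals.size else 100.0
    return GammaResult(
        pass_rate=pass_rate,
        gamma_map=gamma_map,
        dose_crit=crit_d,
        dist_crit=dist_mm,
        low_dose_cutoff=cutoff_fraction,
    )


# ---------------------------------------------------------------------------
# Fluence MAE and per-case reports
# ---------------------------------------------------------------------------

def fluence_mae(y_bench: np.ndarray, y_pred: np.ndarray) -> float:
    """Sum of absolute errors over all pixels, normalized by the count of
    positive benchmark pixels (the lambda = 0 reduction of the FM loss)."""
    y_bench = np.asarray(y_bench, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    n_pos = int((y_bench > 0).sum())
    if n_pos == 0:
        raise ValueError("benchmark fluence has no positive pixels")
    return float(np.abs(y_bench - y_pred).sum() / n_pos)


@dataclass
class PredictedPlan:
    """Doses (and optionally fluences) of one predicted plan variant, % Rx."""

    total: np.ndarray
    per_beam: np.ndarray | None = None
    fluences: np.ndarray | None = None


def evaluate_case(
    case,
    benchmark,
    predicted: dict[str, PredictedPlan | None],
    roi_margin_mm: float = 10.0,
    gamma_pixel_mm: float = 2.5,
) -> pd.DataFrame:
    """Per-case evaluation report in tidy form.

    ``predicted`` maps plan-type names (``fd_cnn_dose``, ``fm_cnn_plan``,
    ``model_predicted_plan``) to :class:`PredictedPlan`; a missing / None
    entry yields an explicit ``absent`` marker row.  ``benchmark`` needs
    ``field_doses`` (a :class:`~fluenceforge.dose_engine.FieldDoseSet`) and
    ``fluences``.
    """
    grid = case.grid
    roi = case.roi(roi_margin_mm).voxels > 0
    ptv = case.ptv.voxels > 0
    oar = case.oar.voxels > 0
    regions = {"PTV": ptv, "OAR": oar, "ROI": roi}
    rim = roi & ~ptv
    if rim.any():
        regions["ROI-PTV"] = rim
    bench_total = benchmark.field_doses.total
    voxel_cc = grid.voxel_cc

    rows = []

    def add(plan, region, metric, value):
        rows.append(
            {"case_id": case.case_id, "plan": plan, "region": region,
             "metric": metric, "value": value}
        )

    for plan_name, plan in predicted.items():
        if plan is None:
            add(plan_name, "-", "absent", np.nan)
            continue
        for reg_name, mask in regions.items():
            if not mask.any():
                continue
            add(plan_name, reg_name, "voxel_dd_pct",
                voxel_dose_difference(bench_total, plan.total, mask))
            mb = dvh_metrics(bench_total, mask, voxel_cc)
            mp = dvh_metrics(plan.total, mask, voxel_cc)
            add(plan_name, reg_name, "abs_dmean_diff_pct", abs(mb.d_mean - mp.d_mean))
            add(plan_name, reg_name, "abs_dmax01cc_diff_pct",
                abs(mb.d_max_01cc - mp.d_max_01cc))
            if reg_name == "PTV":
                add(plan_name, reg_name, "abs_d95_diff_pct", abs(mb.d_95 - mp.d_95))
        if plan.fluences is not None:
            maes, passes = [], []
            for k in range(plan.fluences.shape[0]):
                yb = benchmark.fluences[k]
                maes.append(fluence_mae(yb, plan.fluences[k]))
                if yb.max() > 0:
                    passes.append(
                        gamma_2d(yb, plan.fluences[k], pixel_mm=gamma_pixel_mm).pass_rate
                    )
            add(plan_name, "fluence", "mae", float(np.mean(maes)))
            if passes:
                add(plan_name, "fluence", "gamma_pass_pct", float(np.mean(passes)))
    return pd.DataFrame(rows)


def aggregate_reports(reports: list[pd.DataFrame]) -> pd.DataFrame:
    """Cohort summary: mean and SD per plan x region x metric across cases."""
    df = pd.concat(reports, ignore_index=True)
    df = df[df.metric != "absent"]
    out = (
        df.groupby(["plan", "region", "metric"])["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    return out
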