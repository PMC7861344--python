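"""Persistence: case bundles (HDF5), cohort manifests, model checkpoints,
report CSVs, and the run log.

One array container (chunked, gzip-compressed HDF5) holds everything for a
case: density, masks, isocenter, grid metadata, beam templates, and the
benchmark plan.  The manifest is a plain-text file with one ``case_id
split`` pair per line.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .anatomy import Grid3D, PhantomCase, StructureMask
from .dose_engine import BeamTemplateSet, FieldDoseSet
from .fd_net import FDNet, FDNetConfig
from .fm_net import FMModel, FMNetConfig, build_fm_cnn
from .fd_net import build_fd_cnn
from .planner import BenchmarkPlan, Cohort, ProtocolConfig
from . import nn


# ---------------------------------------------------------------------------
# Case bundles
# ---------------------------------------------------------------------------

def _write_grid(grp, grid: Grid3D):
    grp.attrs["grid"] = json.dumps(dataclasses.asdict(grid))


def _read_grid(grp) -> Grid3D:
    d = json.loads(grp.attrs["grid"])
    d["origin"] = tuple(d["origin"])
    return Grid3D(**d)


def save_case_bundle(
    path: str | Path,
    case: PhantomCase,
    plan: BenchmarkPlan | None = None,
    templates: BeamTemplateSet | None = None,
) -> Path:
    """Write one case (and optionally its plan and templates) to an HDF5 bundle."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    opts = dict(compression="gzip", compression_opts=4, shuffle=True)
    with h5py.File(path, "w") as f:
        f.attrs["case_id"] = case.case_id
        f.attrs["seed"] = case.seed
        _write_grid(f, case.grid)
        f.create_dataset("density", data=case.density.astype(np.float32), **opts)
        f.create_dataset("ptv", data=case.ptv.voxels, **opts)
        f.create_dataset("oar", data=case.oar.voxels, **opts)
        f.create_dataset("isocenter", data=np.asarray(case.isocenter))
        if templates is not None:
            f.create_dataset("templates", data=templates.per_beam.astype(np.float32),
                             **opts)
            f.create_dataset("apertures", data=templates.apertures, **opts)
        if plan is not None:
            g = f.create_group("benchmark")
            g.create_dataset("fluences", data=plan.fluences.astype(np.float32), **opts)
            g.create_dataset("field_doses",
                             data=plan.field_doses.per_beam.astype(np.float32), **opts)
            g.create_dataset("objective_trace", data=plan.objective_trace)
            g.attrs["calibration"] = plan.calibration
            g.attrs["converged"] = bool(plan.converged)
            g.attrs["protocol"] = json.dumps(dataclasses.asdict(plan.protocol))
    return path


def load_case_bundle(path: str | Path):
    """Read a case bundle; returns (case, plan | None, templates | None)."""
    with h5py.File(path, "r") as f:
        grid = _read_grid(f)
        case = PhantomCase(
            grid=grid,
            density=f["density"][...],
            ptv=StructureMask(grid, f["ptv"][...]),
            oar=StructureMask(grid, f["oar"][...]),
            isocenter=f["isocenter"][...],
            case_id=str(f.attrs["case_id"]),
            seed=int(f.attrs["seed"]),
        )
        templates = None
        if "templates" in f:
            templates = BeamTemplateSet(
                per_beam=f["templates"][...],
                apertures=f["apertures"][...],
                grid=grid,
            )
        plan = None
        if "benchmark" in f:
            g = f["benchmark"]
            plan = BenchmarkPlan(
                case_id=case.case_id,
                fluences=g["fluences"][...].astype(np.float64),
                field_doses=FieldDoseSet(per_beam=g["field_doses"][...], grid=grid),
                calibration=float(g.attrs["calibration"]),
                protocol=ProtocolConfig(**json.loads(g.attrs["protocol"])),
                converged=bool(g.attrs["converged"]),
                objective_trace=g["objective_trace"][...],
            )
    return case, plan, templates


def save_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write all case bundles plus the split manifest to a directory."""
    out_dir = Path(out_dir)
    cases_dir = out_dir / "cases"
    cases_dir.mkdir(parents=True, exist_ok=True)
    for cid, case in cohort.cases.items():
        save_case_bundle(
            cases_dir / f"{cid}.h5",
            case,
            plan=cohort.plans.get(cid),
            templates=cohort.templates.get(cid),
        )
    write_manifest(out_dir / "manifest.txt", cohort.train_ids, cohort.test_ids,
                   cohort.seed)
    return out_dir


def load_cohort(out_dir: str | Path) -> Cohort:
    out_dir = Path(out_dir)
    train_ids, test_ids, seed = read_manifest(out_dir / "manifest.txt")
    cases, plans, templates = {}, {}, {}
    for cid in train_ids + test_ids:
        case, plan, tpl = load_case_bundle(out_dir / "cases" / f"{cid}.h5")
        cases[cid] = case
        if plan is not None:
            plans[cid] = plan
        if tpl is not None:
            templates[cid] = tpl
    return Cohort(cases=cases, plans=plans, templates=templates,
                  train_ids=train_ids, test_ids=test_ids, seed=seed)


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def write_manifest(path: str | Path, train_ids, test_ids, seed: int) -> Path:
    path = Path(path)
    lines = [f"# cohort manifest (seed {seed})"]
    lines += [f"{cid}\ttrain" for cid in train_ids]
    lines += [f"{cid}\ttest" for cid in test_ids]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_manifest(path: str | Path):
    train_ids, test_ids, seed = [], [], 0
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line.startswith("#"):
            if "seed" in line:
                seed = int(line.rstrip(")").split("seed")[-1])
            continue
        if not line:
            continue
        cid, split = line.split("\t")
        (train_ids if split == "train" else test_ids).append(cid)
    return train_ids, test_ids, seed


# ---------------------------------------------------------------------------
# Model checkpoints
# ---------------------------------------------------------------------------

def save_fd_model(path: str | Path, model: FDNet) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    weights = {f"w{i}": p.value for i, p in enumerate(model.params())}
    np.savez_compressed(
        path, __config__=json.dumps(dataclasses.asdict(model.config)), **weights
    )
    return path


def load_fd_model(path: str | Path) -> FDNet:
    data = np.load(path, allow_pickle=False)
    config = FDNetConfig(**_detuple(json.loads(str(data["__config__"]))))
    model = build_fd_cnn(config)
    nn.set_weights(model, [data[f"w{i}"] for i in range(len(model.params()))])
    return model


def save_fm_model(path: str | Path, model: FMModel) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    weights = {f"w{i}": p.value for i, p in enumerate(model.net.params())}
    meta = dict(
        config=dataclasses.asdict(model.config),
        dose_norm=model.dose_norm,
        fluence_norm=model.fluence_norm,
    )
    np.savez_compressed(path, __meta__=json.dumps(meta), **weights)
    return path


def load_fm_model(path: str | Path) -> FMModel:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    net = build_fm_cnn(FMNetConfig(**_detuple(meta["config"])))
    nn.set_weights(net, [data[f"w{i}"] for i in range(len(net.params()))])
    return FMModel(net=net, dose_norm=meta["dose_norm"],
                   fluence_norm=meta["fluence_norm"])


def _detuple(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


# ---------------------------------------------------------------------------
# Reports and run log
# ---------------------------------------------------------------------------

def write_report_csv(path: str | Path, reports: list[pd.DataFrame]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.concat(reports, ignore_index=True).to_csv(path, index=False)
    return path


def append_run_log(workdir: str | Path, stage: str, config_text: str,
                   extra: dict | None = None) -> Path:
    """Append a structured run header (timestamp, stage, config hash, version)."""
    from . import __version__

    path = Path(workdir) / "run.log"
    path.parent.mkdir(parents=True, exist_ok=True)
    record = {
        "time": datetime.datetime.now().isoformat(timespec="seconds"),
        "stage": stage,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest()[:16],
        "version": __version__,
    }
    if extra:
        record.update(extra)
    with path.open("a") as f:
        f.write(json.dumps(record) + "\n")
    return path
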