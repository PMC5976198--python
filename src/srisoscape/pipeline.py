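"""Config-driven end-to-end pipeline.

Five stages, each writing declared on-disk artifacts so a run can restart
from any completed stage: (1) resample/assemble the covariate stack,
(2) extract covariates at sites and build the regression matrix,
(3) train and cross-validate (optionally with variable selection),
(4) predict the isoscape (quantile forest for uncertainty),
(5) spatial diagnostics.  All randomness flows from the master seed; the
run report lists every artifact with its content hash, so two runs with
the same config and seed produce identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diagnostics import correlogram, residuals_geojson
from .grids import CovariateStack, Grid, reproject_resample
from .isoscape import predict_isoscape
from .projection import CRS, transform
from .qrf import fit_qrf
from .regression import CVScheme, cross_validate, partial_dependence, \
    permutation_importance, select_variables, train
from .samples import SampleTable, extract_at_sites

log = logging.getLogger("srisoscape")

_SCHEMA = {
    "stack_dir": str,
    "samples_csv": str,
    "out_dir": str,
    "learner": (str, dict),
    "seed": int,
}
_OPTIONAL = {
    "cv": dict,             # k, repeats, train_fraction
    "selection": bool,
    "qrf": bool,
    "qrf_params": dict,
    "target_grid": dict,    # crs_id, origin_x, origin_y, cell_size, nrows, ncols
    "log_level": str,
}


@dataclass
class RunConfig:
    stack_dir: str
    samples_csv: str
    out_dir: str
    learner: str | dict = "rf"
    seed: int = 0
    cv: dict = field(default_factory=dict)
    selection: bool = False
    qrf: bool = True
    qrf_params: dict = field(default_factory=dict)
    target_grid: dict | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        validate_config(raw, base=Path(path).parent)
        return cls(**raw)


def validate_config(raw: dict, base: Path | None = None) -> None:
    """Schema validation before any computation."""
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    for key, typ in _SCHEMA.items():
        if key not in raw:
            raise ValueError(f"config missing required key {key!r}")
        if not isinstance(raw[key], typ):
            raise ValueError(f"config key {key!r} has wrong type")
    unknown = set(raw) - set(_SCHEMA) - set(_OPTIONAL)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    base = base or Path(".")
    for key in ("stack_dir", "samples_csv"):
        p = Path(raw[key])
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise ValueError(f"config path {key}={raw[key]!r} does not exist")


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow; returns the run report (also written)."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO),
                        format="%(levelname)s [%(name)s] %(message)s")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def record(path: Path) -> None:
        artifacts[str(path.relative_to(out))] = _sha(path)

    try:
        stage = "stack"
        log.info("[stack] reading covariate stack from %s", cfg.stack_dir)
        stack = CovariateStack.read(cfg.stack_dir)
        if cfg.target_grid:
            from .grids import GridSpec
            target = GridSpec(**cfg.target_grid)
            stack = CovariateStack(
                [reproject_resample(g, target) for g in stack.layers],
                stack.transform_tags,
            )
        stack_dir = out / "stack"
        stack.write(stack_dir)
        for p in sorted(stack_dir.glob("*")):
            record(p)

        stage = "extract"
        samples = SampleTable.read_csv(cfg.samples_csv)
        matrix = extract_at_sites(stack, samples)
        log.info("[extract] %d sites retained, %d dropped",
                 len(matrix.data), matrix.n_dropped)
        matrix.data.to_csv(out / "regression_matrix.csv")
        record(out / "regression_matrix.csv")

        stage = "train"
        scheme = CVScheme(seed=cfg.seed, **cfg.cv)
        work = matrix
        selected = list(matrix.covariate_names)
        if cfg.selection:
            selected = select_variables(matrix, cfg.learner, scheme, seed=cfg.seed)
            log.info("[train] selected covariates: %s", selected)
            work = matrix.subset_covariates(selected)
        model = train(work, cfg.learner, scheme, seed=cfg.seed)
        model.cv.table.to_csv(out / "cv_metrics.csv", index=False)
        record(out / "cv_metrics.csv")
        summary = {"learner": cfg.learner if isinstance(cfg.learner, str)
                   else cfg.learner.get("name"),
                   "selected_covariates": selected,
                   **model.cv.summary()}
        (out / "cv_summary.json").write_text(json.dumps(summary, indent=1,
                                                        sort_keys=True))
        record(out / "cv_summary.json")
        imp = permutation_importance(model, seed=cfg.seed)
        imp.to_csv(out / "importance.csv", index=False)
        record(out / "importance.csv")
        pd_dir = out / "partial_dependence"
        pd_dir.mkdir(exist_ok=True)
        for cov in selected:
            if cov in work.categorical:
                continue
            curve = partial_dependence(model, cov)
            curve.to_csv(pd_dir / f"{cov}.csv", index=False)
            record(pd_dir / f"{cov}.csv")

        stage = "predict"
        if cfg.qrf:
            qf = fit_qrf(work, seed=cfg.seed, **cfg.qrf_params)
            iso = predict_isoscape(qf, stack, covariates=selected,
                                   provenance={"seed": cfg.seed})
        else:
            iso = predict_isoscape(model, stack, provenance={"seed": cfg.seed})
        iso_dir = out / "isoscape"
        iso.write(iso_dir)
        for p in sorted(iso_dir.glob("*")):
            record(p)

        stage = "diagnose"
        resid = model.residuals
        corr = correlogram(work.coords, resid, seed=cfg.seed)
        corr.write_csv(out / "correlogram.csv")
        record(out / "correlogram.csv")
        lon, lat = transform(stack.spec.crs, CRS("wgs84"),
                             work.coords[:, 0], work.coords[:, 1])
        residuals_geojson(np.column_stack([lon, lat]), resid,
                          out / "residuals.geojson")
        record(out / "residuals.geojson")
    except Exception as exc:
        report = {"status": "failed", "stage": stage, "error": str(exc),
                  "artifacts": artifacts}
        (out / "report.json").write_text(json.dumps(report, indent=1,
                                                    sort_keys=True))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report = {"status": "ok", "seed": cfg.seed, "artifacts": artifacts}
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    log.info("run complete: %d artifacts", len(artifacts))
    return report
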