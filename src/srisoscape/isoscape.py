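"""Isoscape prediction and continuous-probability geographic assignment.

Applying a trained model across the covariate stack yields the isoscape:
mean and median ⁸⁷Sr/⁸⁶Sr grids plus the 2.5th/97.5th percentile grids
from the quantile forest, whose difference (interval width) is the
spatially explicit uncertainty surface.

Assignment inverts the isoscape: for a measured sample ratio r with
analytical SD σₘ, each cell gets the normal likelihood
N(r; mean_cell, √(σ_cell² + σₘ²)) with σ_cell = width/3.92 (the 95%
interval of a normal spans 3.92 SDs), normalized over land cells into a
posterior probability-of-origin surface under a uniform spatial prior.
Computation runs in log space to avoid underflow on large grids.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grids import CovariateStack, Grid, GridSpec
from .qrf import QuantileForest, predict_mean, predict_quantiles

INTERVAL_TO_SD = 3.92  # width of a central 95% normal interval in SD units


@dataclass
class Isoscape:
    """Prediction grids plus provenance."""

    mean: Grid
    median: Grid | None = None
    q025: Grid | None = None
    q975: Grid | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.q025 is not None and self.q975 is not None:
            lo, hi = self.q025.values, self.q975.values
            m = self.median.values if self.median is not None else None
            ok = np.isfinite(lo) & np.isfinite(hi)
            if not np.all(lo[ok] <= hi[ok] + 1e-12):
                raise ValueError("q2.5 must not exceed q97.5")
            if m is not None and not (
                np.all(lo[ok] <= m[ok] + 1e-12) and np.all(m[ok] <= hi[ok] + 1e-12)
            ):
                raise ValueError("median must lie inside [q2.5, q97.5]")

    @property
    def width(self) -> Grid | None:
        """Width of the 95% prediction interval (the uncertainty surface)."""
        if self.q025 is None or self.q975 is None:
            return None
        return Grid(self.mean.spec, self.q975.values - self.q025.values,
                    name="width95")

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        layers = {"mean": self.mean, "median": self.median,
                  "q025": self.q025, "q975": self.q975, "width95": self.width}
        for key, g in layers.items():
            if g is not None:
                g.copy_with(name=key).write_ascii(directory / f"{key}.asc")
        (directory / "provenance.json").write_text(
            json.dumps(self.provenance, indent=1, sort_keys=True))

    @classmethod
    def read(cls, directory) -> "Isoscape":
        directory = Path(directory)
        def opt(key):
            p = directory / f"{key}.asc"
            return Grid.read_ascii(p) if p.exists() else None
        prov_path = directory / "provenance.json"
        prov = json.loads(prov_path.read_text()) if prov_path.exists() else {}
        return cls(Grid.read_ascii(directory / "mean.asc"),
                   opt("median"), opt("q025"), opt("q975"), prov)


def stack_hash(stack: CovariateStack) -> str:
    """Deterministic content hash of a covariate stack, for provenance."""
    h = hashlib.sha256()
    for g in stack.layers:
        h.update(g.name.encode())
        h.update(np.ascontiguousarray(g.values).tobytes())
    return h.hexdigest()[:16]


def predict_isoscape(
    model,
    stack: CovariateStack,
    covariates: list[str] | None = None,
    tile: int = 4096,
    provenance: dict | None = None,
) -> Isoscape:
    """Apply a fitted model (point learner or quantile forest) over the stack.

    ``covariates`` names the stack layers feeding the model, in model
    column order (defaults to a TrainedModel's selected covariates).
    Cells missing any required layer stay missing.  Predictions are
    computed tile-wise; the result is independent of the tile size.
    """
    from .regression import TrainedModel  # local import to avoid a cycle

    if covariates is None:
        if isinstance(model, TrainedModel):
            covariates = model.covariates
        else:
            raise ValueError("covariates must be given for a bare learner")
    missing = set(covariates) - set(stack.names)
    if missing:
        raise ValueError(f"stack is missing required layer(s): {sorted(missing)}")

    sub = stack.subset(covariates).transformed()
    arr = np.stack([g.values for g in sub.layers])  # (p, nr, nc)
    spec = stack.spec
    flat = arr.reshape(len(covariates), -1).T       # (ncells, p)
    valid = np.all(np.isfinite(flat), axis=1)
    idx = np.flatnonzero(valid)

    ncells = flat.shape[0]
    mean = np.full(ncells, np.nan)
    med = lo = hi = None
    is_qf = isinstance(model, QuantileForest)
    if is_qf:
        med = np.full(ncells, np.nan)
        lo = np.full(ncells, np.nan)
        hi = np.full(ncells, np.nan)

    predictor = model.learner if isinstance(model, TrainedModel) else model
    for s in range(0, idx.size, tile):
        block = idx[s:s + tile]
        Xb = flat[block]
        if is_qf:
            mean[block] = predict_mean(model, Xb)
            q = predict_quantiles(model, Xb, [0.025, 0.5, 0.975])
            lo[block], med[block], hi[block] = q[:, 0], q[:, 1], q[:, 2]
        else:
            mean[block] = predictor.predict(Xb)

    prov = dict(provenance or {})
    prov.setdefault("stack_hash", stack_hash(stack))
    prov.setdefault("covariates", list(covariates))
    shape = (spec.nrows, spec.ncols)
    return Isoscape(
        mean=Grid(spec, mean.reshape(shape), name="mean"),
        median=Grid(spec, med.reshape(shape), name="median") if is_qf else None,
        q025=Grid(spec, lo.reshape(shape), name="q025") if is_qf else None,
        q975=Grid(spec, hi.reshape(shape), name="q975") if is_qf else None,
        provenance=prov,
    )


@dataclass
class AssignmentSurface:
    """Posterior probability-of-origin surface for one measured sample."""

    posterior: Grid
    measured_ratio: float
    measurement_sd: float

    def __post_init__(self) -> None:
        v = self.posterior.values
        total = np.nansum(v)
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError("posterior must sum to 1 over non-missing cells")
        if np.any(v[np.isfinite(v)] < 0):
            raise ValueError("posterior must be non-negative")


def assign(
    isoscape: Isoscape,
    measured_ratio: float,
    measurement_sd: float = 0.0,
) -> AssignmentSurface:
    """Continuous-probability assignment of a sample to the isoscape.

    Cell SD comes from the prediction-interval width (width/3.92), combined
    in quadrature with the measurement SD; likelihoods are normal, evaluated
    and normalized in log space, under a uniform prior over non-missing
    cells.
    """
    if measurement_sd < 0:
        raise ValueError("measurement SD must be >= 0")
    width = isoscape.width
    if width is None:
        raise ValueError("assignment requires an isoscape with interval grids")
    mu = isoscape.mean.values
    sd = np.sqrt((width.values / INTERVAL_TO_SD) ** 2 + measurement_sd**2)
    valid = np.isfinite(mu) & np.isfinite(sd)
    sd_floor = 1e-8  # keeps degenerate (zero-width, exact-match) cells finite
    sd = np.maximum(sd, sd_floor)

    loglik = np.full(mu.shape, -np.inf)
    loglik[valid] = (
        -0.5 * ((measured_ratio - mu[valid]) / sd[valid]) ** 2 - np.log(sd[valid])
    )
    m = loglik[valid].max()
    post = np.full(mu.shape, np.nan)
    unnorm = np.exp(loglik[valid] - m)
    post[valid] = unnorm / unnorm.sum()
    return AssignmentSurface(
        Grid(isoscape.mean.spec, post, name="posterior"),
        float(measured_ratio), float(measurement_sd),
    )


def credible_region(surface: AssignmentSurface, mass: float = 0.95) -> Grid:
    """Smallest set of cells holding at least ``mass`` posterior probability.

    Cells are accumulated in descending posterior order; ties break by flat
    cell index (stable sort).  Returns a binary grid (1 inside, 0 outside,
    missing preserved).
    """
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must be in (0, 1)")
    p = surface.posterior.values.ravel()
    valid = np.isfinite(p)
    order = np.argsort(-p[valid], kind="stable")
    csum = np.cumsum(p[valid][order])
    k = int(np.searchsorted(csum, mass - 1e-12) + 1)
    member = np.zeros(valid.sum())
    member[order[:k]] = 1.0
    out = np.full(p.shape, np.nan)
    out[valid] = member
    return Grid(surface.posterior.spec,
                out.reshape(surface.posterior.values.shape),
                kind="categorical", name="credible_region", codes=(0, 1))
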