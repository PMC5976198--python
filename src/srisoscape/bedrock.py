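"""Process-based bedrock ⁸⁷Sr/⁸⁶Sr model.

The ⁸⁷Sr/⁸⁶Sr ratio of a rock grows over geological time by β-decay of
⁸⁷Rb (half-life 48.8 Gyr):

    (⁸⁷Sr/⁸⁶Sr)(t) = (⁸⁷Sr/⁸⁶Sr)₀ + (⁸⁷Rb/⁸⁶Sr) · (e^{λt} − 1)

so a rock unit's present-day ratio is controlled by its initial ratio, its
Rb/Sr ratio and its age.  Geological maps supply per-unit lithology and
age; per-lithology distributions of Rb/Sr and initial ratio (configuration,
editable) are propagated through the ingrowth equation by Monte Carlo to
give median / Q1 / Q3 prediction layers per unit, which the regression
engine consumes as covariates (layer names ``r.m1``, ``r.srsrq1``,
``r.srsrq3``).

The elemental Rb/Sr weight ratio is converted to the atomic ⁸⁷Rb/⁸⁶Sr
ratio with the standard composition-dependent geochemical relation

    ⁸⁷Rb/⁸⁶Sr = (Rb/Sr)_wt · (2.6939 + 0.2832 · ⁸⁷Sr/⁸⁶Sr)

(abundance and atomic-weight constants from isotope-geochemistry practice);
a fixed conversion factor is available as a fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .grids import Grid, GridSpec

HALF_LIFE_87RB_YR = 48.8e9  # years
#: composition-dependent Rb/Sr(weight) -> 87Rb/86Sr conversion coefficients
RBSR_CONV_A = 2.6939
RBSR_CONV_B = 0.2832
#: fixed-factor fallback, valid for typical crustal Sr isotope compositions
RBSR_CONV_FIXED = 2.8936

#: GLiM first-level lithology codes used throughout the package
GLIM_CODES = ("mt", "pa", "va", "pb", "vb", "sm", "sc", "ss", "su")


def decay_constant(half_life_years: float = HALF_LIFE_87RB_YR) -> float:
    """Decay constant λ = ln(2)/t½ in yr⁻¹."""
    if half_life_years <= 0:
        raise ValueError("half-life must be positive")
    return float(np.log(2.0) / half_life_years)


def present_day_ratio(initial, rb87_sr86, age_ma, lam: float | None = None):
    """Present-day ⁸⁷Sr/⁸⁶Sr after radiogenic ingrowth.

    Parameters
    ----------
    initial : array_like
        ⁸⁷Sr/⁸⁶Sr at rock formation.
    rb87_sr86 : array_like
        Atomic ⁸⁷Rb/⁸⁶Sr ratio (≥ 0).
    age_ma : array_like
        Rock age in Ma (≥ 0).
    lam : float, optional
        Decay constant in yr⁻¹; defaults to ln(2)/48.8 Gyr.
    """
    if lam is None:
        lam = decay_constant()
    initial = np.asarray(initial, dtype=float)
    rb = np.asarray(rb87_sr86, dtype=float)
    age = np.asarray(age_ma, dtype=float)
    if np.any(rb < 0):
        raise ValueError("87Rb/86Sr must be non-negative")
    if np.any(age < 0):
        raise ValueError("age must be non-negative")
    if lam <= 0:
        raise ValueError("decay constant must be positive")
    out = initial + rb * np.expm1(lam * age * 1e6)
    return out if out.ndim else float(out)


def rbsr_weight_to_87rb86sr(rbsr_weight, sr_ratio, mode: str = "composition"):
    """Convert elemental Rb/Sr weight ratio to atomic ⁸⁷Rb/⁸⁶Sr."""
    rbsr = np.asarray(rbsr_weight, dtype=float)
    if np.any(rbsr < 0):
        raise ValueError("Rb/Sr must be non-negative")
    if mode == "composition":
        return rbsr * (RBSR_CONV_A + RBSR_CONV_B * np.asarray(sr_ratio, dtype=float))
    if mode == "fixed":
        return rbsr * RBSR_CONV_FIXED
    raise ValueError(f"unknown conversion mode {mode!r}")


@dataclass(frozen=True)
class LithoParams:
    """Per-lithology distributions feeding the Monte-Carlo propagation.

    Rb/Sr weight ratios are lognormal (median ``rbsr_median``, log-scale SD
    ``rbsr_sigma``); initial ratios are normal (``init_mean``, ``init_sd``)
    truncated to [0.699, 0.720].
    """

    rbsr_median: float
    rbsr_sigma: float
    init_mean: float
    init_sd: float

    def __post_init__(self):
        if self.rbsr_median < 0 or self.rbsr_sigma < 0 or self.init_sd < 0:
            raise ValueError("distribution parameters must be non-negative")
        if not (0.699 <= self.init_mean <= 0.720):
            raise ValueError("initial ratio mean outside [0.699, 0.720]")

    def draw(self, rng: np.random.Generator, n: int):
        """Draw (initial, Rb/Sr weight) pairs."""
        if self.rbsr_sigma == 0 or self.rbsr_median == 0:
            rbsr = np.full(n, self.rbsr_median)
        else:
            rbsr = self.rbsr_median * np.exp(rng.normal(0.0, self.rbsr_sigma, n))
        if self.init_sd == 0:
            init = np.full(n, self.init_mean)
        else:
            init = np.clip(rng.normal(self.init_mean, self.init_sd, n), 0.699, 0.720)
        return init, rbsr


def default_litho_params() -> dict[str, LithoParams]:
    """Editable defaults per GLiM class.

    Values reflect broad geochemical expectations — carbonates are Sr-rich
    and Rb-poor with near-seawater initial ratios; felsic igneous and
    metamorphic rocks have high and highly variable Rb/Sr; mafic rocks have
    low Rb/Sr and mantle-like initial ratios — and are configuration, not
    ground truth.
    """
    return {
        "mt": LithoParams(0.9, 0.8, 0.7050, 0.0015),   # metamorphic
        "pa": LithoParams(1.5, 0.8, 0.7040, 0.0010),   # felsic plutonic
        "va": LithoParams(1.1, 0.7, 0.7040, 0.0010),   # felsic volcanic
        "pb": LithoParams(0.06, 0.6, 0.7035, 0.0005),  # mafic plutonic
        "vb": LithoParams(0.05, 0.6, 0.7035, 0.0005),  # mafic volcanic
        "sm": LithoParams(0.40, 0.5, 0.7080, 0.0010),  # mixed sediments
        "sc": LithoParams(0.12, 0.5, 0.7086, 0.0005),  # carbonate sediments
        "ss": LithoParams(0.70, 0.6, 0.7090, 0.0012),  # siliciclastic sediments
        "su": LithoParams(0.45, 0.5, 0.7070, 0.0010),  # unconsolidated sediments
    }


def load_litho_params(path) -> dict[str, LithoParams]:
    """Read a per-lithology parameter file (YAML mapping of 4-field dicts)."""
    raw = yaml.safe_load(Path(path).read_text())
    return {code: LithoParams(**vals) for code, vals in raw.items()}


def write_litho_params(params: Mapping[str, LithoParams], path) -> None:
    raw = {c: vars(p) for c, p in params.items()}
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))


@dataclass(frozen=True)
class BedrockConfig:
    """Configuration of the ingrowth Monte Carlo."""

    half_life_years: float = HALF_LIFE_87RB_YR
    conversion_mode: str = "composition"  # or "fixed"
    n_draws: int = 1000
    age_attribute: str = "mean_age"  # min_age | mean_age | max_age
    seed: int = 0

    def __post_init__(self):
        if self.n_draws < 100:
            raise ValueError("n_draws must be >= 100")
        if self.age_attribute not in ("min_age", "mean_age", "max_age"):
            raise ValueError(f"unknown age attribute {self.age_attribute!r}")

    @property
    def lam(self) -> float:
        return decay_constant(self.half_life_years)


@dataclass
class GeolUnitTable:
    """Geological units: id, GLiM lithology code, min/mean/max age (Ma)."""

    units: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"unit_id", "lithology", "min_age", "mean_age", "max_age"}
        missing = req - set(self.units.columns)
        if missing:
            raise ValueError(f"unit table missing columns: {sorted(missing)}")
        u = self.units
        if (u[["min_age", "mean_age", "max_age"]] < 0).any().any():
            raise ValueError("ages must be >= 0 Ma")
        ok = (u["min_age"] <= u["mean_age"]) & (u["mean_age"] <= u["max_age"])
        if not ok.all():
            raise ValueError("require min_age <= mean_age <= max_age per unit")

    @classmethod
    def read_csv(cls, path) -> "GeolUnitTable":
        return cls(pd.read_csv(path))

    def write_csv(self, path) -> None:
        self.units.to_csv(path, index=False)


def unit_quantiles(
    unit: Mapping,
    params: Mapping[str, LithoParams],
    cfg: BedrockConfig = BedrockConfig(),
) -> tuple[float, float, float]:
    """Monte-Carlo (median, Q1, Q3) present-day ratio for one rock unit.

    Draws (initial ratio, Rb/Sr) pairs for the unit's lithology, converts to
    ⁸⁷Rb/⁸⁶Sr and applies the ingrowth equation at the configured age
    attribute.  Seeded per unit so grids are reproducible regardless of
    evaluation order.
    """
    code = unit["lithology"]
    if code not in params:
        raise KeyError(f"no lithology parameters for code {code!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, int(unit["unit_id"]) & 0x7FFFFFFF])
    )
    init, rbsr = params[code].draw(rng, cfg.n_draws)
    rb87 = rbsr_weight_to_87rb86sr(rbsr, init, mode=cfg.conversion_mode)
    ratios = present_day_ratio(init, rb87, float(unit[cfg.age_attribute]), cfg.lam)
    q1, med, q3 = np.percentile(ratios, [25, 50, 75])
    return float(med), float(q1), float(q3)


@dataclass
class BedrockPrediction:
    """Median/Q1/Q3 bedrock ratio grids (layers r.m1, r.srsrq1, r.srsrq3)."""

    median: Grid
    q1: Grid
    q3: Grid

    def __post_init__(self) -> None:
        m, lo, hi = self.median.values, self.q1.values, self.q3.values
        finite = np.isfinite(m)
        if not (np.all(lo[finite] <= m[finite] + 1e-12)
                and np.all(m[finite] <= hi[finite] + 1e-12)):
            raise ValueError("require q1 <= median <= q3 cell-wise")

    @property
    def layers(self) -> list[Grid]:
        return [self.median, self.q1, self.q3]


def rasterize_bedrock(
    units: GeolUnitTable,
    unit_grid: Grid,
    params: Mapping[str, LithoParams],
    cfg: BedrockConfig = BedrockConfig(),
) -> BedrockPrediction:
    """Paint per-unit quantiles onto the unit-id raster.

    ``unit_grid`` is a categorical raster of unit ids on the target grid;
    pixels with no unit stay missing.
    """
    per_unit = {
        int(row["unit_id"]): unit_quantiles(row, params, cfg)
        for _, row in units.units.iterrows()
    }
    shape = unit_grid.values.shape
    med = np.full(shape, np.nan)
    q1 = np.full(shape, np.nan)
    q3 = np.full(shape, np.nan)
    ids = unit_grid.values
    for uid, (m, lo, hi) in per_unit.items():
        mask = ids == uid
        med[mask], q1[mask], q3[mask] = m, lo, hi
    spec = unit_grid.spec
    return BedrockPrediction(
        Grid(spec, med, name="r.m1"),
        Grid(spec, q1, name="r.srsrq1"),
        Grid(spec, q3, name="r.srsrq3"),
    )
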