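"""Synthetic study regions for end-to-end testing without external geodata.

The generator builds a self-contained landscape with the statistical
structure the isoscape method assumes:

* discrete geology — a seeded Voronoi tessellation of rock units, each
  with a GLiM lithology class and an age drawn from its class range;
* a "true" bedrock ⁸⁷Sr/⁸⁶Sr surface from one radiogenic-ingrowth draw
  per unit (so the bedrock-model covariates are informative but imperfect,
  as for a real map);
* smooth atmospheric fields — sea-salt deposition decaying exponentially
  from the western "coast" and a dust gradient strongest in the south;
* a true bioavailable surface from three-endmember linear mixing of
  bedrock, sea-salt and dust Sr, weighted by lithology-dependent bedrock
  contribution and the local fluxes;
* noisy multi-substrate samples: 1–3 records per site, a site-level
  source/measurement offset shared by a site's records, and per-record
  substrate scatter calibrated so the median within-site SD statistic
  reproduces the configured value (0.0003 by default).

One master seed derives all stage seeds, so the full landscape is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from scipy.stats import chi

from .bedrock import (
    BedrockConfig,
    BedrockPrediction,
    GeolUnitTable,
    LithoParams,
    default_litho_params,
    present_day_ratio,
    rasterize_bedrock,
    rbsr_weight_to_87rb86sr,
)
from .grids import CovariateStack, Grid, GridSpec
from .samples import SampleTable, extract_at_sites

#: default per-lithology age ranges, Ma
DEFAULT_AGE_RANGES: dict[str, tuple[float, float]] = {
    "mt": (300.0, 2000.0),
    "pa": (250.0, 1800.0),
    "va": (100.0, 1200.0),
    "pb": (200.0, 1500.0),
    "vb": (50.0, 800.0),
    "sm": (5.0, 350.0),
    "sc": (5.0, 400.0),
    "ss": (5.0, 450.0),
    "su": (0.0, 30.0),
}

#: default lithology frequencies (sum to 1)
DEFAULT_LITHO_FREQ: dict[str, float] = {
    "sc": 0.20, "ss": 0.15, "sm": 0.10, "su": 0.15,
    "pa": 0.10, "va": 0.05, "pb": 0.05, "vb": 0.05, "mt": 0.15,
}

#: relative bedrock Sr contribution to the bioavailable pool, by lithology
#: (carbonates weather fast and are Sr-rich; felsic rocks contribute little)
DEFAULT_BED_WEIGHT: dict[str, float] = {
    "sc": 10.0, "sm": 5.0, "ss": 4.0, "su": 6.0,
    "pb": 3.0, "vb": 3.0, "mt": 2.0, "pa": 1.5, "va": 1.5,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-region generator settings (defaults are the benchmark)."""

    nrows: int = 200
    ncols: int = 200
    cell_size: float = 1000.0            # metres (1 km cells)
    crs_id: str = "cea:3.0:46.0"
    origin_x: float = -100_000.0
    origin_y: float = 100_000.0
    n_units: int = 25
    litho_freq: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LITHO_FREQ))
    age_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AGE_RANGES))
    litho_params: Mapping[str, LithoParams] = field(
        default_factory=default_litho_params)
    salt_ratio: float = 0.7092           # ~ modern seawater
    dust_ratio: float = 0.7120           # Saharan-type dust, more radiogenic
    salt_efold_m: float = 50_000.0       # e-folding of coastal deposition
    salt_scale: float = 1.0
    dust_scale: float = 0.5
    bed_weight: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BED_WEIGHT))
    substrate_sd: float = 0.0003         # target median within-site SD
    measurement_sd: float = 0.0005       # site-level source offset SD
    n_sites: int = 1500
    records_per_site_probs: tuple[float, ...] = (0.5, 0.3, 0.2)  # P(1), P(2), P(3)
    seed: int = 42

    def __post_init__(self):
        if abs(sum(self.litho_freq.values()) - 1.0) > 1e-9:
            raise ValueError("lithology frequencies must sum to 1")
        if self.substrate_sd < 0 or self.measurement_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not (0.703 <= self.salt_ratio <= 0.725 and 0.703 <= self.dust_ratio <= 0.725):
            raise ValueError("endmember ratios outside [0.703, 0.725]")
        if self.n_units < 1:
            raise ValueError("need at least one unit")

    @property
    def spec(self) -> GridSpec:
        return GridSpec(self.crs_id, self.origin_x, self.origin_y,
                        self.cell_size, self.nrows, self.ncols)

    @property
    def litho_codes(self) -> list[str]:
        return list(self.litho_freq)


def _stage_rng(master_seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master_seed, stage]))


@dataclass
class SyntheticTruth:
    """All generated grids plus unit table and sample table."""

    unit_grid: Grid
    litho_grid: Grid      # categorical, codes = index into cfg.litho_codes
    age_grid: Grid        # unit true age, Ma
    bedrock_grid: Grid    # true bedrock ratio per unit
    salt_grid: Grid
    dust_grid: Grid
    bio_grid: Grid        # true bioavailable ratio
    units: GeolUnitTable
    samples: SampleTable | None = None


def generate_geology(cfg: SyntheticConfig, seed: int | None = None):
    """Seeded Voronoi tessellation with per-unit lithology and age.

    Returns (unit grid, lithology grid, age grid, unit table).  Grids are
    piecewise constant by unit.
    """
    seed = cfg.seed if seed is None else seed
    rng = _stage_rng(seed, 1)
    spec = cfg.spec
    X, Y = spec.cell_centers()
    pts = np.column_stack([
        rng.uniform(spec.origin_x, spec.origin_x + spec.ncols * spec.cell_size,
                    cfg.n_units),
        rng.uniform(spec.origin_y - spec.nrows * spec.cell_size, spec.origin_y,
                    cfg.n_units),
    ])
    _, unit_of_cell = cKDTree(pts).query(
        np.column_stack([X.ravel(), Y.ravel()]))
    unit_ids = unit_of_cell.reshape(spec.nrows, spec.ncols).astype(float)

    codes = cfg.litho_codes
    freqs = np.array([cfg.litho_freq[c] for c in codes])
    lith_idx = rng.choice(len(codes), size=cfg.n_units, p=freqs)
    ages = np.array([
        rng.uniform(*cfg.age_ranges[codes[i]]) for i in lith_idx
    ])
    units = GeolUnitTable(pd.DataFrame({
        "unit_id": np.arange(cfg.n_units),
        "lithology": [codes[i] for i in lith_idx],
        "min_age": ages * 0.9,
        "mean_age": ages,
        "max_age": ages * 1.1,
    }))

    litho_vals = lith_idx[unit_of_cell].reshape(spec.nrows, spec.ncols).astype(float)
    age_vals = ages[unit_of_cell].reshape(spec.nrows, spec.ncols)
    return (
        Grid(spec, unit_ids, kind="categorical", name="r.unit",
             codes=range(cfg.n_units)),
        Grid(spec, litho_vals, kind="categorical", name="r.litho",
             codes=range(len(codes))),
        Grid(spec, age_vals, name="r.meanage"),
        units,
    )


def true_bedrock(cfg: SyntheticConfig, units: GeolUnitTable, unit_grid: Grid,
                 seed: int | None = None) -> Grid:
    """One ingrowth draw per unit: the landscape's actual bedrock ratio.

    Distinct from the bedrock *model* covariates (Monte-Carlo quantiles),
    which see the same lithology/age attributes but not these draws.
    """
    seed = cfg.seed if seed is None else seed
    rng = _stage_rng(seed, 2)
    vals = np.full(unit_grid.values.shape, np.nan)
    for _, row in units.units.iterrows():
        p = cfg.litho_params[row["lithology"]]
        init, rbsr = p.draw(rng, 1)
        rb87 = rbsr_weight_to_87rb86sr(rbsr, init)
        ratio = float(present_day_ratio(init[0], rb87[0], row["mean_age"]))
        vals[unit_grid.values == row["unit_id"]] = ratio
    return Grid(unit_grid.spec, vals, name="r.bedrock_true")


def aerosol_fields(cfg: SyntheticConfig) -> tuple[Grid, Grid]:
    """Sea-salt (exponential decay from the western coast) and dust
    (south-to-north linear gradient) deposition fields, scaled to [0, 1]."""
    spec = cfg.spec
    X, Y = spec.cell_centers()
    salt = np.exp(-(X - spec.origin_x) / cfg.salt_efold_m)
    south = spec.origin_y - spec.nrows * spec.cell_size
    frac_north = (Y - south) / (spec.nrows * spec.cell_size)
    dust = 0.2 + 0.8 * (1.0 - frac_north)  # strongest at the southern edge
    return (Grid(spec, salt, name="r.salt"), Grid(spec, dust, name="r.dust"))


def generate_bioavailable(
    cfg: SyntheticConfig,
    bedrock: Grid,
    litho_grid: Grid,
    salt: Grid,
    dust: Grid,
) -> Grid:
    """Three-endmember mixing of bedrock, sea-salt and dust Sr.

    Per cell: R = (f_bed·R_bed + f_salt·R_salt + f_dust·R_dust) / Σf with
    f_salt, f_dust proportional to the flux fields and f_bed set by
    lithology.  Linear mixing of ratios (no Sr-concentration weighting) is
    a documented simplification; the result is bounded by the endmembers.
    """
    codes = cfg.litho_codes
    w = np.array([cfg.bed_weight[c] for c in codes])
    f_bed = w[litho_grid.values.astype(int)]
    f_salt = cfg.salt_scale * salt.values
    f_dust = cfg.dust_scale * dust.values
    total = f_bed + f_salt + f_dust
    if np.any(total <= 0):
        raise ValueError("all source fluxes are zero at some cell")
    mix = (f_bed * bedrock.values + f_salt * cfg.salt_ratio
           + f_dust * cfg.dust_ratio) / total
    return Grid(bedrock.spec, mix, name="r.bio_true")


def _median_sd_factor(record_probs) -> float:
    """Median of the per-site sample-SD statistic in units of the record SD.

    For n iid normal records, SD/σ ~ χ(n−1)/√(n−1); the statistic uses
    only sites with ≥ 2 records.  Drawing records with SD σ/factor makes
    the *observable* median within-site SD equal the configured value.
    """
    probs = np.asarray(record_probs, dtype=float)
    probs = probs / probs.sum()
    qual = [(n, p) for n, p in zip(range(1, len(probs) + 1), probs) if n >= 2]
    total = sum(p for _, p in qual)
    if total == 0:
        return 1.0
    def cdf(m):
        return sum(p / total * chi.cdf(m * np.sqrt(n - 1), df=n - 1)
                   for n, p in qual) - 0.5
    return float(brentq(cdf, 1e-6, 10.0))


def sample_sites(
    cfg: SyntheticConfig,
    bio_grid: Grid,
    seed: int | None = None,
    site_bias: Mapping[str, float] | None = None,
    litho_grid: Grid | None = None,
) -> SampleTable:
    """Draw noisy multi-substrate samples from the true surface.

    Sites are distinct cells (optionally biased toward given lithologies);
    each gets 1–3 substrate records.  A site-level offset (SD
    ``measurement_sd``) is shared by the site's records — sites come from
    one study each — while substrate scatter is per record, with the
    record SD calibrated so the median within-site SD statistic equals
    ``substrate_sd``.
    """
    seed = cfg.seed if seed is None else seed
    rng = _stage_rng(seed, 4)
    spec = bio_grid.spec
    ncells = spec.nrows * spec.ncols
    if cfg.n_sites > ncells:
        raise ValueError("more sites than cells")
    if site_bias is not None:
        if litho_grid is None:
            raise ValueError("site_bias requires the lithology grid")
        codes = cfg.litho_codes
        wmap = np.array([site_bias.get(c, 1.0) for c in codes])
        wcell = wmap[litho_grid.values.astype(int)].ravel()
        p = wcell / wcell.sum()
        cells = rng.choice(ncells, size=cfg.n_sites, replace=False, p=p)
    else:
        cells = rng.choice(ncells, size=cfg.n_sites, replace=False)
    rows_i, cols_i = np.unravel_index(cells, (spec.nrows, spec.ncols))

    # jitter inside the cell, then back-project to WGS84 coordinates
    jx = rng.uniform(0.2, 0.8, cfg.n_sites)
    jy = rng.uniform(0.2, 0.8, cfg.n_sites)
    x = spec.origin_x + (cols_i + jx) * spec.cell_size
    y = spec.origin_y - (rows_i + jy) * spec.cell_size
    lon, lat = spec.crs.to_lonlat(x, y)

    probs = np.asarray(cfg.records_per_site_probs, dtype=float)
    probs = probs / probs.sum()
    n_rec = rng.choice(np.arange(1, len(probs) + 1), size=cfg.n_sites, p=probs)
    site_offset = rng.normal(0.0, cfg.measurement_sd, cfg.n_sites)
    sd_rec = (cfg.substrate_sd / _median_sd_factor(probs)
              if cfg.substrate_sd > 0 else 0.0)

    substrates = np.array(["plant", "soil", "water"])
    recs = []
    truth = bio_grid.values[rows_i, cols_i]
    for s in range(cfg.n_sites):
        subs = rng.choice(3, size=n_rec[s], replace=False)
        for k in range(n_rec[s]):
            ratio = truth[s] + site_offset[s] + (
                rng.normal(0.0, sd_rec) if sd_rec > 0 else 0.0)
            recs.append({
                "site_id": f"S{s:05d}",
                "longitude": lon[s],
                "latitude": lat[s],
                "substrate": substrates[subs[k]],
                "ratio": ratio,
                "source": "synthetic",
            })
    return SampleTable(pd.DataFrame(recs))


@dataclass
class Benchmark:
    """The standard synthetic test bed: truth, covariate stack, samples."""

    truth: SyntheticTruth
    stack: CovariateStack
    bedrock_model: BedrockPrediction
    cfg: SyntheticConfig

    def matrix(self):
        """Regression matrix of the benchmark (extracted at sample sites)."""
        return extract_at_sites(self.stack, self.truth.samples)


def generate_benchmark(cfg: SyntheticConfig | None = None,
                       seed: int | None = None) -> Benchmark:
    """Build the full synthetic study region and its covariate stack.

    Stack layers: lithology class (categorical), unit mean age, the three
    bedrock-model quantile layers (r.m1, r.srsrq1, r.srsrq3), sea-salt and
    dust deposition.
    """
    cfg = cfg or SyntheticConfig()
    seed = cfg.seed if seed is None else seed
    unit_grid, litho_grid, age_grid, units = generate_geology(cfg, seed)
    salt, dust = aerosol_fields(cfg)
    bed_true = true_bedrock(cfg, units, unit_grid, seed)
    bio = generate_bioavailable(cfg, bed_true, litho_grid, salt, dust)
    bed_seed = int(np.random.SeedSequence([seed, 3]).generate_state(1)[0] % (2**31))
    bmodel = rasterize_bedrock(units, unit_grid, cfg.litho_params,
                               BedrockConfig(seed=bed_seed))
    samples = sample_sites(cfg, bio, seed, litho_grid=litho_grid)
    truth = SyntheticTruth(unit_grid, litho_grid, age_grid, bed_true,
                           salt, dust, bio, units, samples)
    stack = CovariateStack([litho_grid, age_grid, *bmodel.layers, salt, dust])
    return Benchmark(truth, stack, bmodel, cfg)
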