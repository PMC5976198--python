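"""Sample tables of georeferenced bioavailable ⁸⁷Sr/⁸⁶Sr measurements.

A sample table holds one record per analysis: site id, WGS84 coordinates,
substrate (plant, soil, water, rock, animal — or ``excluded`` for
substrates such as aerosol dust or flying insects whose Sr is non-local),
the measured ratio and a source label.  A site may carry several records
(multiple substrates and/or replicates); modelling uses one target value
per site, the median of its retained records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import CovariateStack
from .projection import CRS, transform

SUBSTRATES = ("plant", "soil", "water", "rock", "animal", "excluded")
CSV_COLUMNS = ["site_id", "longitude", "latitude", "substrate", "ratio", "source"]


@dataclass
class SampleTable:
    """Wrapper around a records DataFrame with schema validation."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = set(CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"sample table missing columns: {sorted(missing)}")
        if len(df) == 0:
            raise ValueError("empty sample table")
        if not df["longitude"].between(-180, 180).all():
            raise ValueError("longitude outside [-180, 180]")
        if not df["latitude"].between(-90, 90).all():
            raise ValueError("latitude outside [-90, 90]")
        if not (df["ratio"] > 0.69).all():
            raise ValueError("ratio at or below 0.69 (implausible for 87Sr/86Sr)")
        bad = set(df["substrate"]) - set(SUBSTRATES)
        if bad:
            raise ValueError(f"unknown substrate labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def read_csv(cls, path) -> "SampleTable":
        return cls(pd.read_csv(path))

    def write_csv(self, path) -> None:
        self.records.to_csv(Path(path), index=False, columns=CSV_COLUMNS)

    def site_table(self) -> pd.DataFrame:
        """One row per site: coordinates and the aggregated target ratio.

        Excluded-substrate records are dropped first; sites with no
        remaining records are absent from the result.
        """
        kept = self.records[self.records["substrate"] != "excluded"]
        if len(kept) == 0:
            raise ValueError("all records excluded; no sites to aggregate")
        agg = kept.groupby("site_id").agg(
            longitude=("longitude", "first"),
            latitude=("latitude", "first"),
            ratio=("ratio", "median"),
            n_records=("ratio", "size"),
        )
        return agg.reset_index()


def aggregate_site_ratios(records: pd.DataFrame) -> float | None:
    """Aggregate one site's records to its target ratio (median).

    Excluded substrates are removed first; returns None if nothing remains.
    """
    kept = records[records["substrate"] != "excluded"]["ratio"]
    if len(kept) == 0:
        return None
    return float(kept.median())


@dataclass
class RegressionMatrix:
    """Design matrix for the regression engine.

    ``data`` has one row per retained site: projected coordinates ``x, y``,
    one column per covariate (transform tags already applied) and the
    aggregated target column ``ratio``; indexed by ``site_id``.
    """

    data: pd.DataFrame
    covariate_names: list[str]
    categorical: list[str]
    n_dropped: int = 0

    @property
    def X(self) -> np.ndarray:
        return self.data[self.covariate_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.data["ratio"].to_numpy(dtype=float)

    @property
    def coords(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(dtype=float)

    def subset_covariates(self, names) -> "RegressionMatrix":
        names = list(names)
        unknown = set(names) - set(self.covariate_names)
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")
        cols = ["x", "y", *names, "ratio"]
        return RegressionMatrix(
            self.data[cols].copy(),
            names,
            [c for c in self.categorical if c in names],
            self.n_dropped,
        )


def extract_at_sites(stack: CovariateStack, samples: SampleTable) -> RegressionMatrix:
    """Extract covariate values at sample sites and build the regression matrix.

    Sites are projected into the stack CRS and read from the pixel containing
    the point (cell-centre value, half-open pixel bounds).  Sites outside the
    stack extent or hitting missing data in any layer are dropped and counted.
    """
    sites = samples.site_table()
    spec = stack.spec
    x, y = transform(CRS("wgs84"), spec.crs, sites["longitude"].to_numpy(),
                     sites["latitude"].to_numpy())
    row, col = spec.index_of(x, y)
    inside = spec.contains(row, col)

    tstack = stack.transformed()
    cols: dict[str, np.ndarray] = {}
    for g in tstack.layers:
        vals = np.full(len(sites), np.nan)
        vals[inside] = g.values[row[inside], col[inside]]
        cols[g.name] = vals

    df = pd.DataFrame(cols)
    df.insert(0, "site_id", sites["site_id"].to_numpy())
    df.insert(1, "x", x)
    df.insert(2, "y", y)
    df["ratio"] = sites["ratio"].to_numpy()

    complete = df[stack.names].notna().all(axis=1).to_numpy() & inside
    n_dropped = int((~complete).sum())
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} site(s) outside the stack extent or on missing data"
        )
    df = df.loc[complete].set_index("site_id")
    if len(df) == 0:
        raise ValueError("no sites retained after extraction")
    categorical = [g.name for g in stack.layers if g.kind == "categorical"]
    return RegressionMatrix(df, list(stack.names), categorical, n_dropped)
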