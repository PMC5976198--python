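"""Raster grids, covariate stacks, resampling and transforms.

A :class:`Grid` is a single georeferenced raster layer: a 2-D value array
anchored at a top-left origin, row-major, north-up, with square cells.
Pixels follow the half-open convention — a point (x, y) belongs to column
``floor((x - origin_x)/cell_size)`` and row ``floor((origin_y - y)/cell_size)``
— and cell values are located at cell centres for interpolation purposes.
Missing data is NaN (categorical codes are stored as floats with NaN for
missing, which keeps one array dtype throughout).

On-disk format is the ESRI ASCII grid (``.asc``) plus a small JSON sidecar
(``.asc.json``) carrying the CRS id, layer kind, name and categorical code
list.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .projection import CRS, transform

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry shared by aligned grids: CRS, origin, cell size, shape."""

    crs_id: str
    origin_x: float
    origin_y: float
    cell_size: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError("grid shape must be positive")
        CRS(self.crs_id)

    @property
    def crs(self) -> CRS:
        return CRS(self.crs_id)

    def cell_centers(self):
        """Return (X, Y) arrays of cell-centre coordinates, shape (nrows, ncols)."""
        cols = self.origin_x + (np.arange(self.ncols) + 0.5) * self.cell_size
        rows = self.origin_y - (np.arange(self.nrows) + 0.5) * self.cell_size
        return np.meshgrid(cols, rows)

    def index_of(self, x, y):
        """Row/col of the pixel containing each point (half-open bounds).

        Points outside the extent get indices outside [0, nrows/ncols).
        """
        col = np.floor((np.asarray(x, float) - self.origin_x) / self.cell_size)
        row = np.floor((self.origin_y - np.asarray(y, float)) / self.cell_size)
        return row.astype(int), col.astype(int)

    def contains(self, row, col):
        row = np.asarray(row)
        col = np.asarray(col)
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)


@dataclass
class Grid:
    """One raster layer.

    Parameters
    ----------
    spec : GridSpec
        Geometry and CRS.
    values : ndarray of shape (nrows, ncols)
        Cell values; NaN marks missing.
    kind : {"continuous", "categorical"}
    name : str
        Layer label, e.g. ``"r.m1"`` or ``"r.salt"``.
    codes : sequence of int, optional
        Declared code list for categorical layers.
    """

    spec: GridSpec
    values: np.ndarray
    kind: str = "continuous"
    name: str = "layer"
    codes: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.nrows, self.spec.ncols):
            raise ValueError(
                f"values shape {self.values.shape} != grid shape "
                f"({self.spec.nrows}, {self.spec.ncols})"
            )
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown grid kind {self.kind!r}")
        if self.kind == "categorical":
            self.codes = tuple(sorted({int(c) for c in self.codes}))
            present = np.unique(self.values[np.isfinite(self.values)])
            if self.codes:
                bad = set(present.astype(int)) - set(self.codes)
                if bad:
                    raise ValueError(f"categorical values outside code list: {sorted(bad)}")
            else:
                self.codes = tuple(int(c) for c in present)

    def copy_with(self, **kw) -> "Grid":
        g = Grid(self.spec, self.values.copy(), self.kind, self.name, self.codes)
        for k, v in kw.items():
            setattr(g, k, v)
        return g

    # ------------------------------------------------------------------ I/O
    def write_ascii(self, path) -> None:
        """Write as ESRI ASCII grid with a JSON metadata sidecar."""
        path = Path(path)
        s = self.spec
        vals = np.where(np.isfinite(self.values), self.values, NODATA)
        with open(path, "w") as fh:
            fh.write(f"ncols {s.ncols}\n")
            fh.write(f"nrows {s.nrows}\n")
            fh.write(f"xllcorner {s.origin_x!r}\n")
            fh.write(f"yllcorner {(s.origin_y - s.nrows * s.cell_size)!r}\n")
            fh.write(f"cellsize {s.cell_size!r}\n")
            fh.write(f"NODATA_value {NODATA:g}\n")
            for row in vals:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")
        meta = {"crs_id": s.crs_id, "kind": self.kind, "name": self.name,
                "codes": list(self.codes)}
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)

    @classmethod
    def read_ascii(cls, path) -> "Grid":
        path = Path(path)
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        nodata = header.get("nodata_value", NODATA)
        data = np.where(data == nodata, np.nan, data)
        ncols, nrows = int(header["ncols"]), int(header["nrows"])
        cell = header["cellsize"]
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = {"crs_id": "wgs84", "kind": "continuous", "name": path.stem, "codes": []}
        if sidecar.exists():
            meta.update(json.loads(sidecar.read_text()))
        spec = GridSpec(
            crs_id=meta["crs_id"],
            origin_x=header["xllcorner"],
            origin_y=header["yllcorner"] + nrows * cell,
            cell_size=cell,
            nrows=nrows,
            ncols=ncols,
        )
        return cls(spec, data, kind=meta["kind"], name=meta["name"], codes=meta["codes"])


# ---------------------------------------------------------------- operations

def reproject_resample(grid: Grid, target: GridSpec, method: str = "auto") -> Grid:
    """Resample ``grid`` onto ``target``, reprojecting between CRSs if needed.

    ``method="auto"`` resolves to bilinear for continuous layers and nearest
    neighbour for categorical ones (the standard rule for covariate bricks).
    Bilinear interpolates between the four surrounding cell centres; output
    cells whose neighbourhood includes missing or out-of-extent source cells
    fall back to the nearest source value, so continuous outputs always lie
    within the range of contributing input cells.
    """
    if method == "auto":
        method = "bilinear" if grid.kind == "continuous" else "nearest"
    if method not in ("bilinear", "nearest"):
        raise ValueError(f"unknown resampling method {method!r}")
    if method == "bilinear" and grid.kind == "categorical":
        raise ValueError("bilinear resampling is invalid for categorical grids")

    src = grid.spec
    tx, ty = target.cell_centers()
    sx, sy = transform(target.crs, src.crs, tx.ravel(), ty.ravel())

    # fractional index in cell-centre coordinates
    fc = (sx - src.origin_x) / src.cell_size - 0.5
    fr = (src.origin_y - sy) / src.cell_size - 0.5

    out = np.full(tx.size, np.nan)
    vals = grid.values

    r_near = np.round(fr).astype(int)
    c_near = np.round(fc).astype(int)
    inside = src.contains(r_near, c_near)
    if not inside.any():
        warnings.warn("target grid has no overlap with source grid; output all-missing")
    out[inside] = vals[r_near[inside], c_near[inside]]

    if method == "bilinear":
        r0 = np.floor(fr).astype(int)
        c0 = np.floor(fc).astype(int)
        interp = (
            (r0 >= 0) & (r0 + 1 < src.nrows) & (c0 >= 0) & (c0 + 1 < src.ncols)
        )
        if interp.any():
            rr, cc = r0[interp], c0[interp]
            wr = (fr[interp] - rr)
            wc = (fc[interp] - cc)
            v00 = vals[rr, cc]
            v01 = vals[rr, cc + 1]
            v10 = vals[rr + 1, cc]
            v11 = vals[rr + 1, cc + 1]
            bil = (
                v00 * (1 - wr) * (1 - wc)
                + v01 * (1 - wr) * wc
                + v10 * wr * (1 - wc)
                + v11 * wr * wc
            )
            ok = np.isfinite(bil)
            idx = np.flatnonzero(interp)[ok]
            out[idx] = bil[ok]

    out = out.reshape(target.nrows, target.ncols)
    return Grid(target, out, kind=grid.kind, name=grid.name, codes=grid.codes)


def apply_transform(grid: Grid, tag: str) -> Grid:
    """Apply a per-layer transform tag (``none`` or natural ``log``)."""
    if tag == "none":
        return grid
    if tag != "log":
        raise ValueError(f"unknown transform tag {tag!r}")
    if grid.kind != "continuous":
        raise ValueError("log transform only applies to continuous grids")
    finite = np.isfinite(grid.values)
    bad = int(np.sum(finite & (grid.values <= 0)))
    if bad:
        raise ValueError(f"log transform: {bad} non-positive cell(s) in layer {grid.name!r}")
    out = grid.values.copy()
    out[finite] = np.log(out[finite])
    return Grid(grid.spec, out, kind=grid.kind, name=grid.name, codes=grid.codes)


@dataclass
class CovariateStack:
    """Ordered, aligned covariate layers with per-layer transform tags."""

    layers: list[Grid]
    transform_tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("empty covariate stack")
        names = [g.name for g in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate layer names in stack")
        spec0 = self.layers[0].spec
        for g in self.layers[1:]:
            if g.spec != spec0:
                raise ValueError(f"layer {g.name!r} is not aligned with the stack grid")
        for name, tag in self.transform_tags.items():
            if name not in names:
                raise ValueError(f"transform tag for unknown layer {name!r}")
            if tag not in ("none", "log"):
                raise ValueError(f"unknown transform tag {tag!r}")
            layer = self.layers[names.index(name)]
            if tag == "log" and layer.kind != "continuous":
                raise ValueError("log tag on a categorical layer")

    @property
    def spec(self) -> GridSpec:
        return self.layers[0].spec

    @property
    def names(self) -> list[str]:
        return [g.name for g in self.layers]

    def layer(self, name: str) -> Grid:
        for g in self.layers:
            if g.name == name:
                return g
        raise KeyError(name)

    def transformed(self) -> "CovariateStack":
        """Return a stack with all transform tags applied (tags reset to none)."""
        layers = [
            apply_transform(g, self.transform_tags.get(g.name, "none"))
            for g in self.layers
        ]
        return CovariateStack(layers, {})

    def as_array(self) -> np.ndarray:
        """Stack values as (n_layers, nrows, ncols), transforms applied."""
        return np.stack([g.values for g in self.transformed().layers])

    def subset(self, names: Sequence[str]) -> "CovariateStack":
        layers = [self.layer(n) for n in names]
        tags = {n: self.transform_tags[n] for n in names if n in self.transform_tags}
        return CovariateStack(layers, tags)

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = []
        for g in self.layers:
            fname = f"{g.name}.asc"
            g.write_ascii(directory / fname)
            manifest.append(
                {"path": fname, "kind": g.kind,
                 "transform": self.transform_tags.get(g.name, "none")}
            )
        (directory / "stack.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def read(cls, directory) -> "CovariateStack":
        directory = Path(directory)
        manifest = json.loads((directory / "stack.json").read_text())
        layers, tags = [], {}
        for entry in manifest:
            g = Grid.read_ascii(directory / entry["path"])
            layers.append(g)
            if entry.get("transform", "none") != "none":
                tags[g.name] = entry["transform"]
        return cls(layers, tags)
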