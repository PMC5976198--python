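"""Ordinary kriging with automatic variogram fitting.

The geostatistical comparison model: an empirical semivariogram is binned
from point pairs, the best of the spherical / exponential / Gaussian
families is fitted by pair-count-weighted least squares from seeded
multi-starts, and predictions solve the ordinary-kriging system (weights
constrained to sum to one via a Lagrange multiplier).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist, pdist, squareform

FAMILIES = ("spherical", "exponential", "gaussian")


def _model_gamma(family: str, h, nugget: float, psill: float, rng: float):
    """Semivariance γ(h) for the named model family."""
    h = np.asarray(h, dtype=float)
    if family == "spherical":
        x = np.clip(h / rng, 0.0, 1.0)
        struct = 1.5 * x - 0.5 * x**3
    elif family == "exponential":
        struct = 1.0 - np.exp(-h / rng)
    elif family == "gaussian":
        struct = 1.0 - np.exp(-((h / rng) ** 2))
    else:
        raise ValueError(f"unknown variogram family {family!r}")
    out = nugget + psill * struct
    return np.where(h > 0, out, 0.0)  # γ(0) = 0 by definition


@dataclass
class Variogram:
    family: str
    nugget: float
    psill: float
    range_: float
    bins: np.ndarray | None = None  # columns: lag midpoint, semivariance, pair count
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.psill < 0:
            raise ValueError("nugget and partial sill must be >= 0")
        if self.range_ <= 0:
            raise ValueError("range must be > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.psill

    def __call__(self, h):
        return _model_gamma(self.family, h, self.nugget, self.psill, self.range_)


def empirical_variogram(coords, values, n_bins: int = 15, max_lag: float | None = None):
    """Binned empirical semivariogram.

    Per bin, semivariance = ½ · mean squared value difference over point
    pairs whose separation falls in the bin.  Returns an array with columns
    (lag midpoint, semivariance, pair count); empty bins are dropped with a
    warning.  ``max_lag`` defaults to half the maximum pairwise distance.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(coords) < 10:
        raise ValueError("need at least 10 sites for an empirical variogram")
    d = pdist(coords)
    if max_lag is None:
        max_lag = float(d.max()) / 2.0
    if max_lag <= 0:
        raise ValueError("max_lag must be > 0")
    dv = pdist(values[:, None], metric="sqeuclidean") * 0.5
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    which = np.digitize(d, edges[1:-1])
    sel = d <= max_lag
    rows = []
    n_empty = 0
    for b in range(n_bins):
        m = sel & (which == b)
        cnt = int(m.sum())
        if cnt == 0:
            n_empty += 1
            continue
        rows.append(((edges[b] + edges[b + 1]) / 2.0, float(dv[m].mean()), cnt))
    if n_empty:
        warnings.warn(f"dropped {n_empty} empty variogram bin(s)")
    return np.array(rows)


def fit_variogram(bins: np.ndarray, seed: int = 0, n_starts: int = 8) -> Variogram:
    """Fit the best model family by pair-count-weighted least squares.

    Seeded multi-start (log-uniform range and sill starts) per family; the
    family with the lowest weighted SSE wins.  All-zero semivariances yield
    a degenerate pure-nugget model.
    """
    bins = np.asarray(bins, dtype=float)
    if bins.ndim != 2 or bins.shape[0] < 3:
        raise ValueError("need >= 3 non-empty variogram bins")
    lag, gamma, cnt = bins[:, 0], bins[:, 1], bins[:, 2]
    if np.allclose(gamma, 0.0):
        return Variogram("spherical", 0.0, 0.0, max(lag.max(), 1.0),
                         bins=bins, degenerate=True)

    w = np.sqrt(cnt)
    gmax = gamma.max()
    lmax = lag.max()
    rng = np.random.default_rng(seed)
    best: Variogram | None = None
    best_sse = np.inf
    for family in FAMILIES:
        for _ in range(n_starts):
            x0 = np.array([
                rng.uniform(0.0, 0.3) * gmax,        # nugget
                rng.uniform(0.5, 1.5) * gmax,        # partial sill
                np.exp(rng.uniform(np.log(lmax / 20), np.log(lmax))),  # range
            ])
            res = least_squares(
                lambda p: w * (_model_gamma(family, lag, *np.abs(p)) - gamma),
                x0,
                bounds=([0.0, 0.0, lmax * 1e-4], [gmax * 2, gmax * 5, lmax * 10]),
                method="trf",
                max_nfev=200,
            )
            sse = float(np.sum(res.fun**2))
            if sse < best_sse - 1e-15 * gmax**2:
                best_sse = sse
                n0, ps, rg = res.x
                best = Variogram(family, float(n0), float(ps), float(rg), bins=bins)
    assert best is not None
    return best


def _average_duplicates(coords, values):
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    uniq, inv = np.unique(coords, axis=0, return_inverse=True)
    if len(uniq) == len(coords):
        return coords, values
    sums = np.zeros(len(uniq))
    counts = np.zeros(len(uniq))
    np.add.at(sums, inv, values)
    np.add.at(counts, inv, 1.0)
    return uniq, sums / counts


def krige(coords, values, variogram: Variogram, query, return_weights: bool = False):
    """Ordinary-kriging prediction (+ kriging variance) at query points.

    Solves, per query q, the system ``[[Γ, 1],[1ᵀ, 0]] [λ; μ] = [γ_q; 1]``
    where Γ holds semivariances between data points and γ_q those between
    data points and the query.  Duplicate data coordinates are averaged
    first.  Singular systems fall back to the global mean with a flag.
    """
    coords, values = _average_duplicates(coords, values)
    n = len(coords)
    if n < 2:
        raise ValueError("ordinary kriging needs >= 2 distinct sites")
    query = np.atleast_2d(np.asarray(query, dtype=float))

    d_dd = squareform(pdist(coords))
    d_dq = cdist(coords, query)
    gamma_dd = variogram(d_dd)
    gamma_dq = variogram(d_dq)

    # Smooth models (the Gaussian family especially) with a near-zero
    # nugget yield numerically singular systems whose "solutions" carry
    # huge oscillating weights.  If the system is ill-conditioned, add the
    # smallest numerical nugget (relative to the sill) that tames it.
    sill = max(variogram.sill, float(gamma_dd.max()), 1e-300)
    a = np.zeros((n + 1, n + 1))
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    for rel in (0.0, 1e-8, 1e-6, 1e-4):
        a[:n, :n] = gamma_dd + rel * sill * (d_dd > 0)
        if np.linalg.cond(a) <= 1e10:
            break
    if rel > 0:
        warnings.warn(
            f"ill-conditioned kriging system; added numerical nugget "
            f"{rel:g} x sill")
        gamma_dq = gamma_dq + rel * sill * (d_dq > 0)
    b = np.vstack([gamma_dq, np.ones(query.shape[0])])

    flags = np.zeros(query.shape[0], dtype=bool)
    try:
        sol = np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        sol = None
    if sol is None or not np.all(np.isfinite(sol)):
        warnings.warn("singular kriging system; falling back to the global mean")
        preds = np.full(query.shape[0], values.mean())
        var = np.full(query.shape[0], np.nan)
        flags[:] = True
        weights = np.full((query.shape[0], n), 1.0 / n)
    else:
        weights = sol[:n].T
        mu = sol[n]
        preds = weights @ values
        var = np.einsum("qn,nq->q", weights, gamma_dq) + mu
        var = np.maximum(var, 0.0)
    if return_weights:
        return preds, var, flags, weights
    return preds, var, flags


@dataclass
class OrdinaryKriging:
    """fit/predict learner adapter around :func:`krige` (registry name "ok")."""

    n_bins: int = 15
    max_lag: float | None = None
    seed: int = 0
    variogram: Variogram | None = field(default=None, repr=False)
    _coords: np.ndarray | None = field(default=None, repr=False)
    _values: np.ndarray | None = field(default=None, repr=False)

    uses_coords = True

    def fit(self, X, y, coords=None):
        if coords is None:
            raise ValueError("ordinary kriging requires site coordinates")
        self._coords, self._values = _average_duplicates(coords, y)
        bins = empirical_variogram(self._coords, self._values,
                                   n_bins=self.n_bins, max_lag=self.max_lag)
        self.variogram = fit_variogram(bins, seed=self.seed)
        return self

    def predict(self, X, coords=None):
        if coords is None:
            raise ValueError("ordinary kriging requires query coordinates")
        preds, _, _ = krige(self._coords, self._values, self.variogram, coords)
        return preds
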