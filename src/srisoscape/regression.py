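"""Model training and evaluation for site-level ⁸⁷Sr/⁸⁶Sr regression.

This module owns the methodological scaffolding around the learners:
repeated k-fold cross-validation with shared fold assignments, two-stage
variable selection (importance screening against a noise probe, then
forward CV), permutation importance, partial dependence, paired Wilcoxon
model comparison, and covariate ablations.  The tree ensemble itself is
scikit-learn's random forest; a VIF-screened linear model and ordinary
kriging are the baselines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .kriging import OrdinaryKriging
from .samples import RegressionMatrix

# --------------------------------------------------------------- metrics


def rmse(observed, predicted) -> float:
    """Root mean squared error."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    if observed.size < 1:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def r_squared(observed, predicted, kind: str = "pearson") -> float:
    """R²: squared Pearson correlation of observed vs predicted (default),
    or the 1 − SSE/SST coefficient of determination (``kind="ss"``)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    if observed.size < 2:
        raise ValueError("need at least two observations")
    if kind == "ss":
        sst = np.sum((observed - observed.mean()) ** 2)
        if sst == 0:
            return float("nan")
        return float(1.0 - np.sum((observed - predicted) ** 2) / sst)
    if np.std(observed) == 0 or np.std(predicted) == 0:
        return float("nan")  # undefined: zero variance
    return float(np.corrcoef(observed, predicted)[0, 1] ** 2)


# --------------------------------------------------------------- learners


class MeanLearner:
    """Intercept-only baseline: predicts the training mean."""

    uses_coords = False

    def fit(self, X, y, coords=None):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X, coords=None):
        return np.full(np.asarray(X).shape[0], self.mean_)


class RandomForestLearner:
    """Random forest with OOB-resolved ``max_features``.

    500 trees; the number of covariates tried per split is chosen from
    {⌈p/3⌉, ⌈√p⌉, p} by out-of-bag RMSE, computed entirely from the
    training data it is given (so CV folds stay honest).  Pass
    ``max_features`` explicitly to skip the search.
    """

    uses_coords = False

    def __init__(self, n_estimators: int = 500, max_features=None, seed: int = 0,
                 min_samples_leaf: int = 1):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.seed = seed
        self.min_samples_leaf = min_samples_leaf

    def _grid(self, p: int):
        cand = sorted({min(p, max(1, math.ceil(p / 3))),
                       min(p, max(1, math.ceil(math.sqrt(p)))),
                       p})
        return cand

    def fit(self, X, y, coords=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        p = X.shape[1]
        if self.max_features is not None:
            choices = [min(self.max_features, p)]
        else:
            choices = self._grid(p)
        best, best_oob = None, np.inf
        for mf in choices:
            rf = RandomForestRegressor(
                n_estimators=self.n_estimators,
                max_features=mf,
                min_samples_leaf=self.min_samples_leaf,
                oob_score=len(choices) > 1,
                bootstrap=True,
                random_state=self.seed,
                n_jobs=1,
            )
            rf.fit(X, y)
            if len(choices) == 1:
                best = rf
                break
            oob_rmse = rmse(y, rf.oob_prediction_)
            if oob_rmse < best_oob:
                best_oob, best = oob_rmse, rf
        self.model_ = best
        self.max_features_ = best.max_features
        return self

    def predict(self, X, coords=None):
        return self.model_.predict(np.asarray(X, dtype=float))


class LinearLearner:
    """Generalized linear baseline with multicollinearity screening.

    Categorical covariates are one-hot encoded; covariates with variance
    inflation factor above ``vif_threshold`` are removed recursively before
    an ordinary least-squares fit.
    """

    uses_coords = False

    def __init__(self, vif_threshold: float = 10.0, categorical: Sequence[str] = (),
                 names: Sequence[str] = ()):
        self.vif_threshold = vif_threshold
        self.categorical = list(categorical)
        self.names = list(names)

    def _design(self, X):
        X = np.asarray(X, dtype=float)
        if not self.categorical or not self.names:
            return X
        cols = []
        for j, name in enumerate(self.names):
            if name in self.categorical:
                for code in self.levels_[name]:
                    cols.append((X[:, j] == code).astype(float))
            else:
                cols.append(X[:, j])
        return np.column_stack(cols)

    def fit(self, X, y, coords=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.levels_ = {}
        if self.categorical and self.names:
            for j, name in enumerate(self.names):
                if name in self.categorical:
                    # drop-first encoding to avoid the dummy trap
                    self.levels_[name] = sorted(np.unique(X[:, j]))[1:]
        D = self._design(X)
        keep = list(range(D.shape[1]))
        while len(keep) > 1:
            vifs = _vif(D[:, keep])
            worst = int(np.argmax(vifs))
            if vifs[worst] <= self.vif_threshold:
                break
            keep.pop(worst)
        self.keep_ = keep
        A = np.column_stack([np.ones(len(y)), D[:, keep]])
        self.coef_, *_ = np.linalg.lstsq(A, y, rcond=None)
        return self

    def predict(self, X, coords=None):
        D = self._design(np.asarray(X, dtype=float))
        A = np.column_stack([np.ones(D.shape[0]), D[:, self.keep_]])
        return A @ self.coef_


def _vif(D: np.ndarray) -> np.ndarray:
    """Variance inflation factors of the columns of D."""
    n, p = D.shape
    out = np.zeros(p)
    for j in range(p):
        yj = D[:, j]
        others = np.column_stack([np.ones(n), np.delete(D, j, axis=1)])
        pred, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ pred
        sst = np.sum((yj - yj.mean()) ** 2)
        r2 = 0.0 if sst == 0 else max(0.0, 1.0 - np.sum(resid**2) / sst)
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


#: learner registry: name -> factory(seed, matrix) -> fit/predict object
LEARNERS: dict[str, Callable] = {}


def register_learner(name: str, factory: Callable) -> None:
    LEARNERS[name] = factory


register_learner("rf", lambda seed, matrix, **kw: RandomForestLearner(seed=seed, **kw))
register_learner(
    "glm",
    lambda seed, matrix, **kw: LinearLearner(
        categorical=matrix.categorical, names=matrix.covariate_names, **kw
    ),
)
register_learner("ok", lambda seed, matrix, **kw: OrdinaryKriging(seed=seed, **kw))
register_learner("mean", lambda seed, matrix, **kw: MeanLearner())


def make_learner(spec: str | Mapping, seed: int, matrix: RegressionMatrix):
    """Instantiate a registered learner from a name or {name, params} mapping."""
    if isinstance(spec, str):
        name, params = spec, {}
    else:
        spec = dict(spec)
        name = spec.pop("name")
        params = spec
    if name not in LEARNERS:
        raise KeyError(f"unknown learner {name!r}; registered: {sorted(LEARNERS)}")
    return LEARNERS[name](seed, matrix, **params)


# --------------------------------------------------------------- CV scheme


@dataclass(frozen=True)
class CVScheme:
    """Repeated k-fold cross-validation (default 10-fold, 5 repeats).

    ``train_fraction`` optionally subsamples each repeat's training pool
    before folding (kept for parity with descriptions that pair k-fold
    with an 80% training share); ``None`` uses plain k-fold.
    """

    k: int = 10
    repeats: int = 5
    train_fraction: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("need k >= 2 folds")
        if self.repeats < 1:
            raise ValueError("need >= 1 repeat")
        if self.train_fraction is not None and not (0 < self.train_fraction <= 1):
            raise ValueError("train_fraction must be in (0, 1]")

    def fold_assignments(self, n: int) -> np.ndarray:
        """(repeats, n) array of fold labels; -1 marks rows left out of a repeat.

        Deterministic in (n, scheme): two models evaluated under the same
        scheme share folds exactly, as paired comparison requires.
        """
        if self.k > n:
            raise ValueError("more folds than sites")
        out = np.full((self.repeats, n), -1, dtype=int)
        for r in range(self.repeats):
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, r]))
            idx = rng.permutation(n)
            if self.train_fraction is not None:
                idx = idx[: max(self.k, int(round(self.train_fraction * n)))]
            labels = np.arange(len(idx)) % self.k
            out[r, idx] = labels
        return out


@dataclass
class CVMetrics:
    """Per-fold metrics plus the fold assignments they came from."""

    table: pd.DataFrame  # columns: repeat, fold, rmse, r2, n_test
    assignments: np.ndarray

    @property
    def mean_rmse(self) -> float:
        return float(self.table["rmse"].mean())

    @property
    def sd_rmse(self) -> float:
        return float(self.table["rmse"].std(ddof=1))

    @property
    def mean_r2(self) -> float:
        return float(self.table["r2"].mean())

    def summary(self) -> dict:
        return {
            "mean_rmse": self.mean_rmse,
            "sd_rmse": self.sd_rmse,
            "mean_r2": self.mean_r2,
            "sd_r2": float(self.table["r2"].std(ddof=1)),
            "n_folds": int(len(self.table)),
        }


def cross_validate(
    matrix: RegressionMatrix,
    learner_spec,
    scheme: CVScheme = CVScheme(),
) -> CVMetrics:
    """Repeated k-fold CV of a learner on the regression matrix.

    All model choices (including any hyperparameter search a learner does
    internally) happen inside the training folds; metrics are computed on
    held-out sites only.
    """
    X, y, coords = matrix.X, matrix.y, matrix.coords
    n = len(y)
    assign = scheme.fold_assignments(n)
    rows = []
    for r in range(scheme.repeats):
        for f in range(scheme.k):
            test = assign[r] == f
            train = (assign[r] >= 0) & ~test
            if test.sum() < 2 or train.sum() < 2:
                raise ValueError(f"fold {f} of repeat {r} has fewer than 2 sites")
            seed = int(np.random.SeedSequence([scheme.seed, r, f]).generate_state(1)[0] % (2**31))
            learner = make_learner(learner_spec, seed, matrix)
            learner.fit(X[train], y[train], coords=coords[train])
            pred = learner.predict(X[test], coords=coords[test])
            rows.append({
                "repeat": r, "fold": f,
                "rmse": rmse(y[test], pred),
                "r2": r_squared(y[test], pred),
                "n_test": int(test.sum()),
            })
    return CVMetrics(pd.DataFrame(rows), assign)


@dataclass
class TrainedModel:
    """A learner fitted on the full matrix, with its CV metrics."""

    learner_name: str
    learner: object
    covariates: list[str]
    matrix: RegressionMatrix
    cv: CVMetrics | None = None

    @property
    def residuals(self) -> np.ndarray:
        pred = self.learner.predict(self.matrix.X, coords=self.matrix.coords)
        return self.matrix.y - pred


def train(
    matrix: RegressionMatrix,
    learner_spec,
    scheme: CVScheme | None = CVScheme(),
    seed: int = 0,
) -> TrainedModel:
    """Fit a learner on all sites, optionally attaching CV metrics."""
    cv = cross_validate(matrix, learner_spec, scheme) if scheme is not None else None
    learner = make_learner(learner_spec, seed, matrix)
    learner.fit(matrix.X, matrix.y, coords=matrix.coords)
    name = learner_spec if isinstance(learner_spec, str) else learner_spec["name"]
    return TrainedModel(name, learner, list(matrix.covariate_names), matrix, cv)


# ----------------------------------------------------- importance/selection


def permutation_importance(
    model: TrainedModel,
    matrix: RegressionMatrix | None = None,
    seed: int = 0,
    n_repeats: int = 5,
) -> pd.DataFrame:
    """Permutation importance: mean RMSE increase when one covariate is shuffled.

    Evaluated on ``matrix`` (defaults to the training matrix), averaged over
    ``n_repeats`` seeded shuffles, returned sorted descending.
    """
    matrix = matrix or model.matrix
    X, y, coords = matrix.X, matrix.y, matrix.coords
    base = rmse(y, model.learner.predict(X, coords=coords))
    rng = np.random.default_rng(seed)
    rows = []
    for j, name in enumerate(matrix.covariate_names):
        deltas = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            deltas.append(rmse(y, model.learner.predict(Xp, coords=coords)) - base)
        rows.append({"covariate": name,
                     "importance": float(np.mean(deltas)),
                     "sd": float(np.std(deltas, ddof=1)) if n_repeats > 1 else 0.0})
    return (pd.DataFrame(rows)
            .sort_values("importance", ascending=False)
            .reset_index(drop=True))


def select_variables(
    matrix: RegressionMatrix,
    learner_spec="rf",
    scheme: CVScheme = CVScheme(),
    n_screen_repeats: int = 3,
    rel_tol: float = 0.01,
    seed: int = 0,
) -> list[str]:
    """Two-stage variable selection for prediction.

    Stage 1 (screening): append a pure-noise probe covariate, fit the
    learner several times, and discard covariates whose mean permutation
    importance does not exceed the probe's maximum importance (the
    data-driven noise threshold).  Stage 2 (forward CV): add the surviving
    covariates in importance order, keeping each only if it improves the
    mean CV RMSE by more than ``rel_tol`` (relative).  Returns the retained,
    ordered subset (at least the single best covariate).
    """
    if len(matrix.covariate_names) < 2:
        return list(matrix.covariate_names)

    rng = np.random.default_rng(seed)
    probe = rng.standard_normal(len(matrix.data))
    probed = matrix.data.copy()
    probe_name = "__noise_probe__"
    probed.insert(len(probed.columns) - 1, probe_name, probe)
    pmat = RegressionMatrix(probed, matrix.covariate_names + [probe_name],
                            matrix.categorical, matrix.n_dropped)

    imp_sum: dict[str, list[float]] = {c: [] for c in pmat.covariate_names}
    for rep in range(n_screen_repeats):
        sub_seed = int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % (2**31))
        m = train(pmat, learner_spec, scheme=None, seed=sub_seed)
        imp = permutation_importance(m, pmat, seed=sub_seed)
        for _, r in imp.iterrows():
            imp_sum[r["covariate"]].append(r["importance"])
    mean_imp = {c: float(np.mean(v)) for c, v in imp_sum.items()}
    threshold = max(mean_imp.pop(probe_name), 0.0)
    ranked = [c for c, v in sorted(mean_imp.items(), key=lambda kv: -kv[1])
              if v > threshold]
    if not ranked:
        ranked = [max(mean_imp, key=mean_imp.get)]

    selected = [ranked[0]]
    best = cross_validate(matrix.subset_covariates(selected), learner_spec, scheme).mean_rmse
    for cand in ranked[1:]:
        trial = cross_validate(
            matrix.subset_covariates(selected + [cand]), learner_spec, scheme
        ).mean_rmse
        if trial < best * (1.0 - rel_tol):
            selected.append(cand)
            best = trial
    return selected


def partial_dependence(
    model: TrainedModel,
    covariate: str,
    probe_values=None,
    matrix: RegressionMatrix | None = None,
) -> pd.DataFrame:
    """Partial dependence of the prediction on one covariate.

    For each probe value v the covariate column is set to v in every row
    and predictions are averaged.  Probes outside the observed range are
    computed but flagged.  The result carries the observed sample deciles
    in ``attrs["deciles"]`` for axis annotation.
    """
    matrix = matrix or model.matrix
    if covariate not in matrix.covariate_names:
        raise KeyError(f"covariate {covariate!r} not in matrix")
    j = matrix.covariate_names.index(covariate)
    col = matrix.X[:, j]
    if probe_values is None:
        probe_values = np.quantile(col, np.linspace(0.02, 0.98, 25))
    probe_values = np.asarray(probe_values, dtype=float)
    lo, hi = col.min(), col.max()
    rows = []
    X = matrix.X
    for v in probe_values:
        Xp = X.copy()
        Xp[:, j] = v
        pred = model.learner.predict(Xp, coords=matrix.coords)
        rows.append({"value": float(v), "mean_prediction": float(np.mean(pred)),
                     "extrapolated": bool(v < lo or v > hi)})
    out = pd.DataFrame(rows)
    out.attrs["deciles"] = np.quantile(col, np.linspace(0.1, 0.9, 9)).tolist()
    return out


# --------------------------------------------------------------- comparison


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    p_value: float
    median_difference: float  # median of (a - b) per-fold RMSE differences

    @property
    def a_better(self) -> bool:
        return self.median_difference < 0


def compare_models(metrics_a: CVMetrics, metrics_b: CVMetrics) -> ComparisonResult:
    """Paired two-sided Wilcoxon signed-rank test on per-fold RMSE.

    Both metric sets must come from identical fold assignments.  Exact null
    distribution for ≤ 25 fold pairs, normal approximation with continuity
    correction above.
    """
    if metrics_a.assignments.shape != metrics_b.assignments.shape or not np.array_equal(
        metrics_a.assignments, metrics_b.assignments
    ):
        raise ValueError("CV fold assignments differ; paired comparison invalid")
    a = metrics_a.table.sort_values(["repeat", "fold"])["rmse"].to_numpy()
    b = metrics_b.table.sort_values(["repeat", "fold"])["rmse"].to_numpy()
    diff = a - b
    nonzero = diff[diff != 0]
    if len(nonzero) == 0:
        return ComparisonResult(float("nan"), 1.0, 0.0)
    method = "exact" if len(nonzero) <= 25 else "approx"
    res = stats.wilcoxon(nonzero, alternative="two-sided", method=method,
                         correction=(method == "approx"))
    return ComparisonResult(float(res.statistic), float(res.pvalue),
                            float(np.median(diff)))


def ablate(
    matrix: RegressionMatrix,
    learner_spec,
    scheme: CVScheme,
    drop: Sequence[str],
) -> CVMetrics:
    """Cross-validate with the listed covariates removed."""
    drop = list(drop)
    unknown = set(drop) - set(matrix.covariate_names)
    if unknown:
        raise ValueError(f"cannot drop unknown covariates: {sorted(unknown)}")
    keep = [c for c in matrix.covariate_names if c not in drop]
    if not keep:
        raise ValueError("cannot drop every covariate")
    return cross_validate(matrix.subset_covariates(keep), learner_spec, scheme)
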