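"""PLS fitting with leave-one-out validation and model quality statistics."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

__all__ = [
    "QsarDataset",
    "PlsModel",
    "ValidationStats",
    "split_train_test",
    "fit_pls_loo",
    "r2_pred",
    "quality_report",
    "field_fractions",
]

COMPONENT_CAP = 10


@dataclass
class QsarDataset:
    """Descriptor matrix, activity vector and split membership."""

    X: pd.DataFrame  # molecules x retained field columns
    y: pd.Series
    columns: pd.DataFrame  # per-column metadata with a 'field' label
    train_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            raise ValueError("X and y must share the molecule index")
        if self.X.isna().to_numpy().any() or self.y.isna().any():
            raise ValueError("dataset contains missing entries")
        if len(self.columns) != self.X.shape[1]:
            raise ValueError("column metadata does not match X")

    @property
    def train(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.train_mask
        return self.X.to_numpy(float)[m], self.y.to_numpy(float)[m]

    @property
    def test(self) -> tuple[np.ndarray, np.ndarray]:
        m = ~self.train_mask
        return self.X.to_numpy(float)[m], self.y.to_numpy(float)[m]


@dataclass
class PlsModel:
    """Fitted PLS model plus training statistics."""

    n_components: int
    coefficients: np.ndarray  # original-scale regression vector
    intercept: float
    x_mean: np.ndarray
    y_mean: float
    q2: float
    q2_by_ncomp: dict[int, float]
    r2: float
    see: float
    f_stat: float
    columns: pd.DataFrame = field(repr=False, default=None)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) @ self.coefficients + self.y_mean


@dataclass(frozen=True)
class ValidationStats:
    """External-test predictions referenced to the training mean."""

    y_test: np.ndarray
    y_pred: np.ndarray
    y_train_mean: float

    @property
    def r2_pred(self) -> float:
        return r2_pred(self.y_test, self.y_pred, self.y_train_mean)


def split_train_test(y: pd.Series, test_fraction: float = 0.25, seed: int = 0) -> np.ndarray:
    """Deterministic ~3:1 split stratified on activity quartiles.

    Returns a boolean train mask aligned with ``y``. Each quartile stratum
    contributes round(n_stratum * test_fraction) test molecules, so both
    sets span the activity range.
    """
    if len(y) < 8:
        raise ValueError("need at least 8 molecules to split")
    rng = np.random.default_rng(seed)
    quartile = pd.qcut(y.rank(method="first"), 4, labels=False)
    # largest-remainder allocation so the overall test count hits the target
    sizes = [int((quartile == q).sum()) for q in range(4)]
    total_test = int(np.floor(len(y) * test_fraction + 0.5))
    quotas = [s * test_fraction for s in sizes]
    counts = [int(np.floor(q)) for q in quotas]
    remainders = np.array(quotas) - np.array(counts)
    for q in np.argsort(-remainders, kind="stable")[: total_test - sum(counts)]:
        counts[q] += 1
    train = np.ones(len(y), dtype=bool)
    for q in range(4):
        members = np.flatnonzero(quartile == q)
        test_idx = rng.choice(members, size=counts[q], replace=False)
        train[test_idx] = False
    return train


def _fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSRegression:
    pls = PLSRegression(n_components=n_components, scale=False)
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            # benign: requested components beyond the informative rank
            warnings.filterwarnings("ignore", message="y residual is constant")
            pls.fit(X, y)
    return pls


def fit_pls_loo(
    X,
    y,
    max_components: int | None = None,
    columns: pd.DataFrame | None = None,
) -> PlsModel:
    """Fit PLS on the training block, choosing components by LOO q^2.

    For each candidate component count a, PRESS is accumulated by refitting
    with each molecule left out; q^2 = 1 - PRESS/SS_total. The optimal count
    is the global argmax of q^2 (ties -> fewer components); the final model
    is refit on the full training block at that count and reports R^2,
    SEE = sqrt(RSS/(N-a-1)) and F = (R^2/a)/((1-R^2)/(N-a-1)).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 5:
        raise ValueError("training set must have at least 5 molecules")
    ss_total = float(((y - y.mean()) ** 2).sum())
    if ss_total == 0:
        raise ValueError("constant activity vector: SS_total is zero")
    cap = min(n - 1, COMPONENT_CAP)
    if max_components is not None:
        if max_components > n - 1:
            raise ValueError("max_components exceeds train size - 1")
        cap = min(cap, max_components)

    q2_by_ncomp: dict[int, float] = {}
    for a in range(1, cap + 1):
        press = 0.0
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            pls = _fit_pls(X[mask], y[mask], a)
            press += float((y[i] - pls.predict(X[i : i + 1]).ravel()[0]) ** 2)
        q2_by_ncomp[a] = 1.0 - press / ss_total

    best = max(q2_by_ncomp, key=lambda a: (q2_by_ncomp[a], -a))
    pls = _fit_pls(X, y, best)
    resid = y - pls.predict(X).ravel()
    rss = float((resid**2).sum())
    r2 = 1.0 - rss / ss_total
    dof = n - best - 1
    see = float(np.sqrt(rss / dof)) if dof > 0 else float("nan")
    f_stat = (r2 / best) / ((1.0 - r2) / dof) if dof > 0 and r2 < 1.0 else float("inf")

    return PlsModel(
        n_components=best,
        coefficients=pls.coef_.reshape(-1),
        intercept=float(pls.intercept_[0]),
        x_mean=pls._x_mean,
        y_mean=float(np.mean(y)),
        q2=q2_by_ncomp[best],
        q2_by_ncomp=q2_by_ncomp,
        r2=r2,
        see=see,
        f_stat=f_stat,
        columns=columns,
    )


def r2_pred(y_test, y_pred, y_train_mean: float) -> float:
    """External predictive r^2 referenced to the training-set mean."""
    y_test = np.asarray(y_test, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_test.size == 0:
        raise ValueError("test set is empty")
    if not np.isfinite(y_train_mean):
        raise ValueError("training mean is not finite")
    denom = float(((y_test - y_train_mean) ** 2).sum())
    if denom == 0:
        raise ValueError(
            "r2_pred undefined: every test activity equals the training mean"
        )
    return 1.0 - float(((y_test - y_pred) ** 2).sum()) / denom


def quality_report(
    q2: float,
    r2: float,
    r2pred: float | None = None,
    q2_threshold: float = 0.5,
    overfit_threshold_pct: float = 25.0,
    r2pred_threshold: float = 0.6,
) -> dict:
    """Pass/fail ledger for the standard model-quality criteria.

    reliable: q^2 > 0.5; no overfit: (R^2 - q^2)/R^2 < 25%; external:
    r^2_pred > 0.6 (skipped when no external stats are supplied).
    """
    overfit_pct = (r2 - q2) / r2 * 100.0 if r2 != 0 else float("inf")
    report = {
        "q2": q2,
        "r2": r2,
        "overfit_pct": overfit_pct,
        "reliable": q2 > q2_threshold,
        "no_overfit": overfit_pct < overfit_threshold_pct,
    }
    if r2pred is not None:
        report["r2_pred"] = r2pred
        report["external_ok"] = r2pred > r2pred_threshold
    return report


def field_fractions(model: PlsModel, X) -> dict[str, float]:
    """Percent of |coefficient|*column-stdev mass per field type (sums to 100)."""
    if model.columns is None or "field" not in model.columns:
        raise ValueError("model carries no per-column field metadata")
    X = np.asarray(X, dtype=float)
    mass = np.abs(model.coefficients) * X.std(axis=0)
    fields = model.columns["field"].to_numpy()
    total = mass.sum()
    out: dict[str, float] = {}
    for f in ("steric", "electrostatic"):
        block = mass[fields == f].sum()
        out[f] = 0.0 if total == 0 else float(block / total * 100.0)
    # exact-sum invariant: assign any residual to the larger block
    resid = 100.0 - sum(out.values())
    if out and total > 0:
        key = max(out, key=out.get)
        out[key] += resid
    return out
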