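"""Blood-pressure regression layer.

Two model families: least-squares polynomial fits (third order by default;
full bivariate basis up to total degree for two inputs) and a small
fully-connected neural network (hidden sizes 20 and 10, quasi-Newton
training) with k-fold cross-validation and a held-out test split.

All errors are reported as RMSE in mmHg.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor

from .physio import BPModelParams

__all__ = [
    "PolyModel",
    "MLPSpec",
    "FittedMLP",
    "EvaluationReport",
    "rmse",
    "fit_poly",
    "fit_mlp",
    "fit_ptt_model",
    "evaluate",
    "FEATURE_SETS",
    "TARGETS",
]

FEATURE_SETS = {
    "pwv": ["pwv_mps"],
    "auc": ["auc_s"],
    "pwv+auc": ["pwv_mps", "auc_s"],
}
TARGETS = {"sbp": "sbp_mmhg", "dbp": "dbp_mmhg"}


def rmse(predicted, observed) -> float:
    """Root mean square error between two equal-length vectors."""
    p = np.asarray(predicted, dtype=float).ravel()
    o = np.asarray(observed, dtype=float).ravel()
    if p.size != o.size:
        raise ValueError(f"length mismatch: {p.size} predictions vs {o.size} observations")
    if p.size == 0:
        raise ValueError("need at least one pair")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def _monomial_terms(n_features: int, degree: int) -> list[tuple[int, ...]]:
    """All exponent tuples with total degree <= ``degree``, intercept first."""
    terms = [
        e
        for e in itertools.product(range(degree + 1), repeat=n_features)
        if sum(e) <= degree
    ]
    terms.sort(key=lambda e: (sum(e), e))
    return terms


def _design_matrix(X: np.ndarray, terms: Sequence[tuple[int, ...]]) -> np.ndarray:
    cols = [np.prod(X**np.asarray(e, dtype=float), axis=1) for e in terms]
    return np.column_stack(cols)


@dataclass
class PolyModel:
    """Least-squares polynomial regression model in one or two inputs."""

    degree: int
    feature_names: list[str]
    terms: list[tuple[int, ...]]
    coefficients: np.ndarray

    def predict(self, X) -> np.ndarray:
        X = _as_2d(X, len(self.feature_names))
        return _design_matrix(X, self.terms) @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "feature_names": list(self.feature_names),
            "terms": [list(t) for t in self.terms],
            "coefficients": self.coefficients.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolyModel":
        return cls(
            degree=d["degree"],
            feature_names=list(d["feature_names"]),
            terms=[tuple(t) for t in d["terms"]],
            coefficients=np.asarray(d["coefficients"], dtype=float),
        )


def _as_2d(X, n_features: Optional[int] = None) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if n_features is not None and X.shape[1] != n_features:
        raise ValueError(f"expected {n_features} feature column(s), got {X.shape[1]}")
    return X


def _term_label(term: tuple[int, ...], names: Sequence[str]) -> str:
    if not any(term):
        return "1"
    return "*".join(
        f"{n}^{e}" if e > 1 else n for n, e in zip(names, term) if e > 0
    )


def fit_poly(X, y, degree: int = 3, feature_names: Optional[Sequence[str]] = None) -> PolyModel:
    """Fit a total-degree-``degree`` polynomial by ordinary least squares.

    ``X`` may be a vector (univariate) or an (n, 2) matrix (bivariate, full
    monomial basis up to the total degree). Deterministic. Raises on a
    rank-deficient design, naming the linearly dependent basis terms.
    """
    X = _as_2d(X)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y have different numbers of rows")
    n_features = X.shape[1]
    if n_features > 2:
        raise ValueError("at most two input features are supported")
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(n_features)]
    terms = _monomial_terms(n_features, degree)
    if X.shape[0] < len(terms):
        raise ValueError(
            f"need at least {len(terms)} rows to fit {len(terms)} coefficients, got {X.shape[0]}"
        )
    A = _design_matrix(X, terms)
    rank = np.linalg.matrix_rank(A)
    if rank < len(terms):
        deficient = []
        r = 0
        for k in range(len(terms)):
            new_rank = np.linalg.matrix_rank(A[:, : k + 1])
            if new_rank == r:
                deficient.append(_term_label(terms[k], feature_names))
            r = new_rank
        raise np.linalg.LinAlgError(
            "rank-deficient polynomial design; dependent basis terms: " + ", ".join(deficient)
        )
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return PolyModel(
        degree=degree,
        feature_names=list(feature_names),
        terms=terms,
        coefficients=coef,
    )


def fit_ptt_model(ptt_s, bp_mmhg, a: float = 4.0, b: float = 60.0) -> BPModelParams:
    """Recover the BP-PTT constants (k1, k2) by linear regression of BP on 1/PTT."""
    ptt = np.asarray(ptt_s, dtype=float).ravel()
    bp = np.asarray(bp_mmhg, dtype=float).ravel()
    if np.any(ptt <= 0):
        raise ValueError("ptt values must be positive")
    k1, k2 = np.polyfit(1.0 / ptt, bp, 1)
    return BPModelParams(a=a, b=b, k1=float(k1), k2=float(k2))


@dataclass(frozen=True)
class MLPSpec:
    """Architecture and training protocol of the neural-network regressor.

    Two fully connected hidden layers (sizes 20 and 10), quasi-Newton
    (L-BFGS) loss minimization, k-fold cross-validation with the
    lowest-validation-loss fold model retained for the test set.
    """

    hidden_sizes: tuple[int, ...] = (20, 10)
    activation: str = "tanh"
    max_iters: int = 800
    alpha: float = 1.0
    n_folds: int = 5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")


@dataclass
class FittedMLP:
    """Cross-validated network plus the standardization fitted on its
    training fold (z-score parameters come from training data only)."""

    model: MLPRegressor
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    fold_val_losses: list[float]
    best_fold: int
    converged: bool

    def predict(self, X) -> np.ndarray:
        X = _as_2d(X, self.x_mean.size)
        Xs = (X - self.x_mean) / self.x_std
        return self.model.predict(Xs) * self.y_std + self.y_mean


def _safe_std(v: np.ndarray) -> np.ndarray:
    s = np.where(v == 0, 1.0, v)
    return s


def fit_mlp(X, y, spec: MLPSpec) -> FittedMLP:
    """Train the network with k-fold cross-validation.

    For each fold, inputs and target are standardized using that fold's
    training rows only, the network is trained with L-BFGS, and the
    validation MSE is recorded; the fold model with the lowest validation
    loss is returned. Reproducible given ``spec.seed``. Non-convergence is
    reported as a warning, not an error.
    """
    X = _as_2d(X)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y have different numbers of rows")
    if X.shape[0] < 2 * spec.n_folds:
        raise ValueError(f"need at least {2 * spec.n_folds} rows for {spec.n_folds}-fold CV")
    kf = KFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.seed)
    best: Optional[FittedMLP] = None
    losses: list[float] = []
    for fold, (train_idx, val_idx) in enumerate(kf.split(X)):
        x_mean = X[train_idx].mean(axis=0)
        x_std = _safe_std(X[train_idx].std(axis=0))
        y_mean = float(y[train_idx].mean())
        y_std = float(_safe_std(np.asarray(y[train_idx].std())))
        Xs = (X - x_mean) / x_std
        ys = (y - y_mean) / y_std
        model = MLPRegressor(
            hidden_layer_sizes=tuple(spec.hidden_sizes),
            activation=spec.activation,
            solver="lbfgs",
            alpha=spec.alpha,
            max_iter=spec.max_iters,
            random_state=None if spec.seed is None else spec.seed + fold,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(Xs[train_idx], ys[train_idx])
        converged = model.n_iter_ < spec.max_iters
        val_loss = float(np.mean((model.predict(Xs[val_idx]) - ys[val_idx]) ** 2))
        losses.append(val_loss)
        if best is None or val_loss < min(losses[:-1], default=np.inf):
            best = FittedMLP(
                model=model,
                x_mean=x_mean,
                x_std=x_std,
                y_mean=y_mean,
                y_std=y_std,
                fold_val_losses=losses,
                best_fold=fold,
                converged=converged,
            )
    assert best is not None
    best.fold_val_losses = losses
    if not best.converged:
        warnings.warn(
            f"network did not converge within {spec.max_iters} iterations "
            f"(best fold {best.best_fold}, val MSE {losses[best.best_fold]:.4g})",
            stacklevel=2,
        )
    return best


@dataclass
class EvaluationReport:
    """RMSE grid over feature sets and targets, with partition bookkeeping.

    ``results`` maps "<feature_set>/<target>" to a dict with
    ``poly_train_rmse``, ``poly_test_rmse`` and ``ann_test_rmse`` (mmHg).
    """

    results: dict[str, dict[str, float]]
    n_total: int
    n_train: int
    n_test: int
    excluded_subjects: list[str]
    seed: Optional[int]
    degree: int

    def __post_init__(self) -> None:
        if self.n_train + self.n_test != self.n_total:
            raise ValueError("partition sizes must sum to the cohort size")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        """Human-readable table: one block per target, one row per feature set."""
        lines = []
        for target in TARGETS:
            lines.append(f"RMSE for {target.upper()} (mmHg)")
            lines.append(f"{'Features':<10} {'Poly (train)':>14} {'Poly (test)':>14} {'ANN (test)':>12}")
            for fs in FEATURE_SETS:
                cell = self.results[f"{fs}/{target}"]
                lines.append(
                    f"{fs:<10} {cell['poly_train_rmse']:>14.4f} "
                    f"{cell['poly_test_rmse']:>14.4f} {cell['ann_test_rmse']:>12.4f}"
                )
            lines.append("")
        lines.append(
            f"n={self.n_total} (train {self.n_train} / test {self.n_test}), "
            f"excluded subjects: {', '.join(self.excluded_subjects) or 'none'}, "
            f"seed={self.seed}"
        )
        return "\n".join(lines)


def evaluate(
    features: pd.DataFrame,
    mlp_spec: Optional[MLPSpec] = None,
    degree: int = 3,
    exclude_subjects: Sequence[str] = ("s3",),
    seed: Optional[int] = None,
    test_size: Optional[int] = None,
) -> EvaluationReport:
    """Full evaluation grid: {PWV, AUC, PWV+AUC} x {SBP, DBP}.

    Rows of excluded subjects are dropped first (the outlier-exclusion rule).
    A seeded random holdout forms the test set: 25 rows when 200 remain,
    otherwise proportional. Polynomial RMSE is reported on both the training
    partition (fit error) and the test partition; the network's RMSE is on
    the held-out test set only.
    """
    present = set(features["subject_id"].unique())
    missing = [s for s in exclude_subjects if s not in present]
    if missing:
        warnings.warn(f"excluded subject(s) not in table: {missing}", stacklevel=2)
    kept = features[~features["subject_id"].isin(list(exclude_subjects))].reset_index(drop=True)
    n = len(kept)
    if mlp_spec is None:
        mlp_spec = MLPSpec(seed=seed)
    if n < 2 * mlp_spec.n_folds:
        raise ValueError(f"need at least {2 * mlp_spec.n_folds} usable rows, got {n}")
    if test_size is None:
        test_size = max(1, int(round(n * 25 / 200)))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = perm[:test_size]
    train_idx = perm[test_size:]

    results: dict[str, dict[str, float]] = {}
    for fs_name, cols in FEATURE_SETS.items():
        X = kept[cols].to_numpy(dtype=float)
        for target_name, target_col in TARGETS.items():
            y = kept[target_col].to_numpy(dtype=float)
            poly = fit_poly(X[train_idx], y[train_idx], degree=degree, feature_names=cols)
            ann = fit_mlp(X[train_idx], y[train_idx], mlp_spec)
            results[f"{fs_name}/{target_name}"] = {
                "poly_train_rmse": rmse(poly.predict(X[train_idx]), y[train_idx]),
                "poly_test_rmse": rmse(poly.predict(X[test_idx]), y[test_idx]),
                "ann_test_rmse": rmse(ann.predict(X[test_idx]), y[test_idx]),
            }
    return EvaluationReport(
        results=results,
        n_total=n,
        n_train=int(train_idx.size),
        n_test=int(test_idx.size),
        excluded_subjects=list(exclude_subjects),
        seed=seed,
        degree=degree,
    )
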