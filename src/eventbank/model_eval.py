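"""Elastic-net scoring and Mann-Whitney AUC with confidence intervals.

One logistic regression with elastic-net regularisation is fitted per
(feature set, horizon) pair on the derivation cohort, with the
regularisation strength chosen by cross-validated AUC; validation-set
discrimination is summarised as the AUC (c-statistic), i.e. the
normalised Mann-Whitney U statistic, with a 95% confidence interval
from the Hanley-McNeil variance approximation (a DeLong variance is
available behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm, rankdata
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .assembly import FeatureMatrix
from .cohort import CohortSplit

DEFAULT_CS = (0.01, 0.1, 1.0)


class DegenerateLabelsError(ValueError):
    """Raised when labels contain a single class."""


@dataclass
class ModelConfig:
    l1_ratio: float = 0.5
    Cs: tuple[float, ...] = DEFAULT_CS
    cv_folds: int = 5
    max_iter: int = 200
    tol: float = 1e-3
    seed: int = 0


@dataclass
class FitResult:
    feature_set_name: str
    horizon_months: int | None
    coefficients: dict[str, float]
    intercept: float
    hyperparams: dict

    def score(self, X: np.ndarray, column_names: Sequence[str]) -> np.ndarray:
        beta = np.array([self.coefficients.get(c, 0.0) for c in column_names])
        z = X @ beta + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


@dataclass
class AUCReport:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


def _check_labels(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("labels contain a single class")


def fit_elastic_net(
    X: np.ndarray,
    y: Sequence[int],
    config: ModelConfig | None = None,
    column_names: Sequence[str] | None = None,
    feature_set_name: str = "",
    horizon_months: int | None = None,
) -> FitResult:
    """Elastic-net logistic regression, C tuned by k-fold CV on AUC.

    Deterministic for a given seed (fold assignment and saga shuffling
    are both seeded).  The design matrix is passed to the solver in CSR
    form when it is mostly zeros.
    """
    config = config or ModelConfig()
    y = np.asarray(y, dtype=int)
    _check_labels(y)
    if column_names is None:
        column_names = [f"x{i}" for i in range(X.shape[1])]
    nnz = X.nnz if sp.issparse(X) else np.count_nonzero(X)
    if nnz == 0:
        # intercept-only solution: saga's step size degenerates on an
        # all-zero design, so return the closed form directly
        prevalence = y.mean()
        return FitResult(
            feature_set_name=feature_set_name,
            horizon_months=horizon_months,
            coefficients={c: 0.0 for c in column_names},
            intercept=float(np.log(prevalence / (1 - prevalence))),
            hyperparams={"l1_ratio": config.l1_ratio, "C": None, "seed": config.seed},
        )
    Xs = X

    # CSR speeds saga up on mostly-zero designs; keep dense degenerate
    # all-zero matrices (sparse saga dampens the intercept update)
    if not sp.issparse(X) and X.size and 0 < np.count_nonzero(X) / X.size < 0.5:
        Xs = sp.csr_matrix(X)
    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    model = LogisticRegressionCV(
        Cs=list(config.Cs),
        cv=cv,
        penalty="elasticnet",
        solver="saga",
        l1_ratios=[config.l1_ratio],
        scoring="roc_auc",
        max_iter=config.max_iter,
        tol=config.tol,
        random_state=config.seed,
        n_jobs=1,
        refit=True,
    )
    with warnings.catch_warnings():
        # iteration cap is a deliberate compute/accuracy trade-off, and the
        # LogisticRegressionCV penalty-spelling deprecation is cosmetic
        warnings.filterwarnings("ignore", category=FutureWarning)
        from sklearn.exceptions import ConvergenceWarning

        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        model.fit(Xs, y)
    coefs = model.coef_.ravel()
    return FitResult(
        feature_set_name=feature_set_name,
        horizon_months=horizon_months,
        coefficients={c: float(b) for c, b in zip(column_names, coefs)},
        intercept=float(model.intercept_[0]),
        hyperparams={
            "l1_ratio": config.l1_ratio,
            "C": float(model.C_[0]),
            "seed": config.seed,
        },
    )


def auc_mann_whitney(
    scores: Sequence[float],
    labels: Sequence[int],
    ci_method: str = "hanley-mcneil",
) -> AUCReport:
    """AUC as the normalised Mann-Whitney U, ties scored half.

    The 95% CI uses the Hanley-McNeil variance by default, or the
    DeLong structural-components variance with ``ci_method="delong"``;
    either way the interval is clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_labels(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    n1, n0 = len(pos), len(neg)
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)
    if ci_method == "delong":
        se = _delong_se(pos, neg)
    else:
        q1 = auc / (2.0 - auc)
        q2 = 2.0 * auc**2 / (1.0 + auc)
        var = (
            auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
        ) / (n1 * n0)
        se = float(np.sqrt(max(var, 0.0)))
    z = norm.ppf(0.975)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    lo, hi = min(lo, auc), max(hi, auc)
    return AUCReport(auc=float(auc), ci_low=lo, ci_high=hi, n_pos=n1, n_neg=n0)


def _delong_se(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the AUC via placement values."""
    n1, n0 = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    mid = rankdata(all_scores)
    v10 = (mid[:n1] - rankdata(pos)) / n0
    v01 = 1.0 - (mid[n1:] - rankdata(neg)) / n1
    var = np.var(v10, ddof=1) / n1 + np.var(v01, ddof=1) / n0
    return float(np.sqrt(max(var, 0.0)))


def evaluate_feature_set(
    matrix: FeatureMatrix,
    labels_by_horizon: dict[int, np.ndarray],
    derivation_mask: np.ndarray,
    config: ModelConfig | None = None,
) -> list[dict]:
    """Fit on derivation rows and report validation AUC per horizon."""
    config = config or ModelConfig()
    rows = []
    deriv = np.asarray(derivation_mask, dtype=bool)
    valid = ~deriv
    if valid.sum() == 0:
        raise ValueError("validation cohort is empty")
    for horizon, y in sorted(labels_by_horizon.items()):
        y = np.asarray(y, dtype=int)
        fit = fit_elastic_net(
            matrix.values[deriv],
            y[deriv],
            config=config,
            column_names=matrix.column_names,
            feature_set_name=matrix.feature_set_name,
            horizon_months=horizon,
        )
        scores = fit.score(matrix.values[valid], matrix.column_names)
        report = auc_mann_whitney(scores, y[valid])
        rows.append(
            {
                "feature_set": matrix.feature_set_name,
                "horizon_months": horizon,
                "auc": report.auc,
                "ci_low": report.ci_low,
                "ci_high": report.ci_high,
                "n_pos": report.n_pos,
                "n_neg": report.n_neg,
                "n_derivation": int(deriv.sum()),
                "n_validation": int(valid.sum()),
                "C": fit.hyperparams["C"],
                "fit": fit,
            }
        )
    return rows


def run_experiment(
    feature_matrices: dict[str, FeatureMatrix],
    labels_by_horizon: dict[int, np.ndarray],
    derivation_mask: np.ndarray,
    horizons: Sequence[int] | None = None,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """One AUC report per (feature set, horizon): the results table.

    All matrices must be built on the same assessment points (the
    labels and split mask are shared across sets).
    """
    horizons = list(horizons) if horizons is not None else sorted(labels_by_horizon)
    labels = {h: labels_by_horizon[h] for h in horizons}
    rows = []
    for name, matrix in feature_matrices.items():
        rows.extend(
            evaluate_feature_set(matrix, labels, derivation_mask, config=config)
        )
    df = pd.DataFrame(rows)
    return df.drop(columns=["fit"]), {
        (r["feature_set"], r["horizon_months"]): r["fit"] for r in rows
    }
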