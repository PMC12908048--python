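"""Prognostic modelling: univariate screening, logistic regression, ROC AUC,
and Harrell-style bootstrap optimism correction.

The screening rule keeps predictors whose single-covariate logistic Wald p
falls below ``screen_alpha`` (default 0.10). Internal validation repeats the
*entire* modelling process — screening included — inside each bootstrap
resample: the model is refit on the resample, its AUC on the resample
("boot") minus its AUC on the original data ("test") estimates the optimism
of that replicate, and

    corrected AUC = apparent AUC − mean optimism

with a percentile confidence interval over the per-replicate corrected
values. Repeating the screening inside the loop is what makes the optimism
estimate cover selection uncertainty as well as coefficient overfit.

Logistic fits use a direct Newton–Raphson (IRLS) solver: the bootstrap loop
performs tens of thousands of small fits and needs per-fit overhead in the
tens of microseconds. On complete separation (or a singular Hessian) the fit
falls back to ridge with lambda = 0.01 n, flagged on the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ValidationError

__all__ = [
    "ModelSpec",
    "LogisticFit",
    "PrognosisResult",
    "fit_logistic",
    "univariate_screen",
    "auc",
    "bootstrap_optimism",
]

_MAX_ABS_COEF = 15.0  # beyond this, treat as (near-)separation


@dataclass
class ModelSpec:
    outcome: str
    candidates: list[str]
    screen_alpha: float = 0.10
    penalty: float | None = None  # explicit ridge lambda, or None

    def validate(self) -> None:
        if self.outcome in self.candidates:
            raise ValidationError("outcome must not be among candidate predictors")
        if not (0 < self.screen_alpha <= 1):
            raise ValidationError("screen_alpha must lie in (0, 1]")
        if not self.candidates:
            raise ValidationError("candidate predictor list is empty")


@dataclass
class LogisticFit:
    predictors: list[str]
    params: np.ndarray  # intercept first
    bse: np.ndarray
    pvalues: np.ndarray  # Wald, two-sided
    converged: bool
    penalized: bool
    ridge_lambda: float = 0.0

    def predict(self, X: np.ndarray) -> np.ndarray:
        eta = self.params[0] + X @ self.params[1:]
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))

    def coefficient_table(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        names = ["intercept"] + self.predictors
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "p": self.pvalues,
                "ci_low": self.params - z * self.bse,
                "ci_high": self.params + z * self.bse,
            },
            index=names,
        )


@dataclass
class PrognosisResult:
    selected: list[str]
    coefficients: pd.DataFrame
    apparent_auc: float
    optimism: float
    corrected_auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int | None
    n_redraws: int = 0
    penalized: bool = False
    screen_records: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# core solver
# ---------------------------------------------------------------------------

def _irls(X: np.ndarray, y: np.ndarray, ridge: float = 0.0,
          max_iter: int = 60, tol: float = 1e-9):
    """Newton–Raphson logistic fit; X already includes the intercept column.

    Ridge penalty (if any) applies to slopes only, not the intercept.
    Returns (beta, cov, converged); raises LinAlgError on a singular Hessian.
    """
    n, p = X.shape
    beta = np.zeros(p)
    pen = np.zeros(p)
    pen[1:] = ridge
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -500, 500)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = X.T @ (y - mu) - pen * beta
        hess = (X * w[:, None]).T @ X + np.diag(pen)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -500, 500)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    hess = (X * w[:, None]).T @ X + np.diag(pen)
    cov = np.linalg.inv(hess)
    return beta, cov, converged


def fit_logistic(
    data: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    penalty: float | None = None,
) -> LogisticFit:
    """Maximum-likelihood logistic regression of a binary outcome.

    With complete separation (non-convergent or exploding coefficients, or a
    singular Hessian) the fit automatically falls back to ridge with
    lambda = 0.01 n, and the result is flagged ``penalized``.
    """
    y = data[outcome].to_numpy(dtype=float)
    uniq = np.unique(y)
    if not np.isin(uniq, [0.0, 1.0]).all() or uniq.size > 2:
        raise ValidationError(f"outcome {outcome!r} must be binary 0/1")
    n = len(y)
    raw = np.column_stack([data[p].to_numpy(dtype=float) for p in predictors]) if predictors \
        else np.empty((n, 0))
    if penalty is None and n <= raw.shape[1] + 1:
        raise ValidationError("need n > number of predictors + 1 for an unpenalized fit")

    # standardize internally (exact affine reparameterisation of the ML fit);
    # keeps the Hessian well-conditioned across assay-unit scales
    m = raw.mean(axis=0) if raw.size else np.zeros(0)
    s = raw.std(axis=0, ddof=0) if raw.size else np.zeros(0)
    if (s == 0).any():
        bad = [predictors[i] for i in np.flatnonzero(s == 0)]
        raise ValidationError(f"zero-variance predictors: {bad}")
    X = np.column_stack([np.ones(n), (raw - m) / s]) if raw.size else np.ones((n, 1))

    ridge = float(penalty) if penalty is not None else 0.0
    penalized = penalty is not None
    try:
        beta, cov, converged = _irls(X, y, ridge=ridge)
        if not penalized and (not converged or np.abs(beta).max() > _MAX_ABS_COEF
                              or not np.isfinite(cov).all()):
            raise np.linalg.LinAlgError("separation suspected")
    except np.linalg.LinAlgError:
        ridge = 1e-2 * n  # on the standardized scale
        beta, cov, converged = _irls(X, y, ridge=ridge)
        penalized = True

    # back-transform to the original predictor scale
    p = len(predictors)
    jac = np.zeros((p + 1, p + 1))
    jac[0, 0] = 1.0
    if p:
        jac[0, 1:] = -m / s
        jac[np.arange(1, p + 1), np.arange(1, p + 1)] = 1.0 / s
    beta = jac @ beta
    cov = jac @ cov @ jac.T
    bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        zvals = beta / bse
    pvals = 2 * stats.norm.sf(np.abs(zvals))
    pvals = np.where(np.isfinite(pvals), pvals, 0.0)
    return LogisticFit(list(predictors), beta, bse, pvals, converged, penalized, ridge)


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def univariate_screen(
    data: pd.DataFrame, spec: ModelSpec, min_events: int = 10, records: list | None = None
) -> list[str]:
    """Keep candidates whose single-covariate logistic Wald p < screen_alpha.

    Zero-variance predictors are skipped with a warning record; complete
    separation counts as p = 0 (the predictor is selected, flagged).
    """
    spec.validate()
    y = data[spec.outcome].to_numpy(dtype=float)
    events = int(min(y.sum(), len(y) - y.sum()))
    if events < min_events:
        raise ValidationError(f"need >= {min_events} events in each class, got {events}")
    selected = []
    for name in spec.candidates:
        x = data[name].to_numpy(dtype=float)
        if np.ptp(x[~np.isnan(x)]) == 0:
            if records is not None:
                records.append({"predictor": name, "status": "skipped_zero_variance"})
            continue
        fit = fit_logistic(data, spec.outcome, [name])
        p = 0.0 if fit.penalized else float(fit.pvalues[1])
        if records is not None:
            records.append({"predictor": name, "p": p,
                            "status": "separation" if fit.penalized else "ok"})
        if p < spec.screen_alpha:
            selected.append(name)
    return selected


# ---------------------------------------------------------------------------
# discrimination
# ---------------------------------------------------------------------------

def auc(scores, labels) -> float:
    """Rank-based (Mann–Whitney) AUC with mid-ranks for ties; equals the
    trapezoidal ROC area."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present to compute AUC")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold), thresholds descending."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    order = np.argsort(-scores, kind="stable")
    s, lab = scores[order], labels[order]
    n_pos = lab.sum()
    n_neg = len(lab) - n_pos
    tps = np.cumsum(lab)
    fps = np.cumsum(1 - lab)
    # keep last point of each tied-threshold block
    keep = np.r_[np.diff(s) != 0, True]
    return pd.DataFrame(
        {
            "threshold": np.r_[np.inf, s[keep]],
            "fpr": np.r_[0.0, fps[keep] / n_neg],
            "tpr": np.r_[0.0, tps[keep] / n_pos],
        }
    )


# ---------------------------------------------------------------------------
# bootstrap optimism
# ---------------------------------------------------------------------------

def _screen_fit_score(data: pd.DataFrame, spec: ModelSpec, min_events: int):
    """Screen, fit and return (selected, fit, scores-on-this-data)."""
    selected = univariate_screen(data, spec, min_events=min_events)
    if not selected:
        return [], None, np.full(len(data), 0.5)
    fit = fit_logistic(data, spec.outcome, selected, penalty=spec.penalty)
    X = data[selected].to_numpy(dtype=float)
    return selected, fit, fit.predict(X)


def bootstrap_optimism(
    data: pd.DataFrame,
    spec: ModelSpec,
    n_boot: int = 1000,
    seed: int | None = 0,
    min_events: int = 10,
    _index_sampler=None,
) -> PrognosisResult:
    """Harrell bootstrap optimism correction of the screened logistic model.

    Fully deterministic given ``seed``. A resample missing one outcome class
    is redrawn (count reported on the result).
    """
    spec.validate()
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    n = len(data)
    y = data[spec.outcome].to_numpy(dtype=float)

    screen_records: list = []
    selected = univariate_screen(data, spec, min_events=min_events, records=screen_records)
    if selected:
        fit = fit_logistic(data, spec.outcome, selected, penalty=spec.penalty)
        scores = fit.predict(data[selected].to_numpy(dtype=float))
        coef = fit.coefficient_table()
        penalized = fit.penalized
    else:
        fit = None
        scores = np.full(n, 0.5)
        coef = pd.DataFrame(columns=["coef", "se", "p", "ci_low", "ci_high"])
        penalized = False
    apparent = auc(scores, y) if selected else 0.5

    rng = np.random.default_rng(seed)
    sampler = _index_sampler or (lambda r, m: r.integers(0, m, m))
    optimisms = np.empty(n_boot)
    n_redraws = 0
    for b in range(n_boot):
        while True:
            idx = np.asarray(sampler(rng, n))
            yb = y[idx]
            if 0 < yb.sum() < len(yb):
                break
            n_redraws += 1
        boot = data.iloc[idx]
        sel_b, fit_b, scores_b = _screen_fit_score(boot, spec, min_events=1)
        auc_boot = auc(scores_b, yb) if sel_b else 0.5
        if sel_b:
            scores_orig = fit_b.predict(data[sel_b].to_numpy(dtype=float))
            auc_test = auc(scores_orig, y)
        else:
            auc_test = 0.5
        optimisms[b] = auc_boot - auc_test

    optimism = float(optimisms.mean())
    corrected = apparent - optimism
    corrected_reps = apparent - optimisms
    ci_low, ci_high = np.percentile(corrected_reps, [2.5, 97.5])
    return PrognosisResult(
        selected=selected,
        coefficients=coef,
        apparent_auc=float(apparent),
        optimism=optimism,
        corrected_auc=float(corrected),
        ci_low=float(min(ci_low, corrected)),
        ci_high=float(max(ci_high, corrected)),
        n_boot=n_boot,
        seed=seed,
        n_redraws=n_redraws,
        penalized=penalized,
        screen_records=screen_records,
    )
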