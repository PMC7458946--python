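"""Per-CIF logistic risk models with forward BIC feature selection.

The target is binary: did an audit/inspection activity produce at least
one finding of the given CIF.  Models are plain maximum-likelihood
logistic regressions (no regularization — shrinkage methods proved prone
to absorbing noise in this low signal-to-noise regime); features are
chosen by a greedy forward search minimizing the Bayesian information
criterion on an early-years training window, with correlated feature
pairs barred from co-selection, and the final coefficients are refit on
all years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

from .cif import CIFS, finding_column
from .features import BinaryFeatureMatrix, CORRELATION_SCREEN_THRESHOLD

__all__ = [
    "CIFModel",
    "SeparationError",
    "ConvergenceError",
    "make_binary_outcome",
    "fit_logistic",
    "select_features_bic",
    "refit_on_all_data",
    "predict_probability",
]

GRADIENT_TOL = 1e-8


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE does not exist."""


class ConvergenceError(RuntimeError):
    """The IRLS/Newton iteration failed to reach the gradient tolerance."""


@dataclass
class CIFModel:
    """A fitted logistic risk model for one Clinical Impact Factor."""

    cif: str
    intercept: float
    coefficients: dict[str, float]
    n_train: int
    train_years: tuple[int, int] | None
    log_likelihood: float
    bic: float = field(default=np.nan)

    def __post_init__(self) -> None:
        expected = ((1 + len(self.coefficients)) * np.log(self.n_train)
                    - 2.0 * self.log_likelihood)
        if np.isnan(self.bic):
            self.bic = float(expected)
        elif not np.isclose(self.bic, expected, rtol=0, atol=1e-6):
            raise ValueError("bic inconsistent with k*ln(n) - 2*log_likelihood")

    def to_dict(self) -> dict:
        return {
            "cif": self.cif,
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "n_train": self.n_train,
            "train_years": list(self.train_years) if self.train_years else None,
            "log_likelihood": self.log_likelihood,
            "bic": self.bic,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CIFModel":
        return cls(cif=d["cif"], intercept=float(d["intercept"]),
                   coefficients={k: float(v) for k, v in d["coefficients"].items()},
                   n_train=int(d["n_train"]),
                   train_years=tuple(d["train_years"]) if d.get("train_years") else None,
                   log_likelihood=float(d["log_likelihood"]),
                   bic=float(d["bic"]))


def make_binary_outcome(activities: pd.DataFrame, cif: str) -> pd.Series:
    """Indicator of >= 1 finding of the CIF per activity (index: activity_id).

    Only the absence or presence of findings is modeled; the count
    beyond the first carries no extra weight.
    """
    counts = activities.set_index("activity_id")[finding_column(cif)]
    if (counts < 0).any():
        raise ValueError("finding counts must be non-negative")
    return (counts >= 1).astype(int).rename(cif)


def _check_separation(X: pd.DataFrame, y: np.ndarray) -> None:
    for name in X.columns:
        x = X[name].to_numpy()
        for v in (0, 1):
            side = y[x == v]
            other = y[x != v]
            if side.size and other.size and side.min() == side.max() \
                    and other.min() == other.max() and side[0] != other[0]:
                raise SeparationError(
                    f"feature {name!r} perfectly separates the outcome")


def _years_range(years) -> tuple[int, int] | None:
    if years is None:
        return None
    return (int(min(years)), int(max(years)))


def fit_logistic(X: pd.DataFrame, y: pd.Series | np.ndarray, cif: str = "",
                 train_years=None, maxiter: int = 200) -> CIFModel:
    """Maximum-likelihood logistic fit (Newton/IRLS) of y on binary X.

    ``X`` may have zero columns, in which case the null
    (intercept-only) model is returned in closed form.  Convergence is
    certified by a score-vector norm below 1e-8.

    Raises
    ------
    SeparationError
        If some feature perfectly separates the outcome (no MLE).
    ConvergenceError
        If Newton iteration stops above the gradient tolerance.
    """
    y_arr = np.asarray(y, dtype=float)
    n = y_arr.size
    if X.shape[0] != n:
        raise ValueError("X and y lengths differ")
    if set(np.unique(y_arr)) - {0.0, 1.0}:
        raise ValueError("outcomes must be binary 0/1")

    if X.shape[1] == 0:
        p = y_arr.mean()
        if p in (0.0, 1.0):
            raise SeparationError("outcome is constant; null model undefined")
        ll = float(n * (p * np.log(p) + (1 - p) * np.log(1 - p)))
        return CIFModel(cif=cif, intercept=float(logit(p)), coefficients={},
                        n_train=n, train_years=_years_range(train_years),
                        log_likelihood=ll)

    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant features in design matrix: {constant}")
    if n <= X.shape[1] + 1:
        raise ValueError("need more observations than parameters")
    _check_separation(X, y_arr)

    exog = sm.add_constant(X.to_numpy(float), prepend=True)
    model = sm.Logit(y_arr, exog)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="newton", maxiter=maxiter, tol=1e-12, disp=0)
    except np.linalg.LinAlgError as exc:
        # Singular Hessian: quasi-separation or collinear binary columns.
        raise SeparationError(f"singular Hessian during Newton fit: {exc}")
    grad_norm = float(np.linalg.norm(model.score(res.params)))
    if grad_norm > GRADIENT_TOL:
        raise ConvergenceError(
            f"gradient norm {grad_norm:.2e} after "
            f"{res.mle_retvals.get('iterations', maxiter)} iterations")
    params = np.asarray(res.params, dtype=float)
    return CIFModel(cif=cif, intercept=float(params[0]),
                    coefficients={name: float(b)
                                  for name, b in zip(X.columns, params[1:])},
                    n_train=n, train_years=_years_range(train_years),
                    log_likelihood=float(res.llf))


def _as_frame(X) -> pd.DataFrame:
    return X.values if isinstance(X, BinaryFeatureMatrix) else X


def select_features_bic(X, y: pd.Series | np.ndarray,
                        candidates: Sequence[str] | None = None,
                        cif: str = "", train_years=None,
                        correlation_threshold: float = CORRELATION_SCREEN_THRESHOLD,
                        ) -> CIFModel:
    """Greedy forward feature selection minimizing BIC.

    Starting from the null model, each step adds the candidate whose
    inclusion lowers BIC the most (ties broken alphabetically by feature
    name) and stops when no candidate lowers it.  Candidate pairs whose
    pairwise |Pearson r| exceeds ``correlation_threshold`` are never
    co-selected.  The result is deterministic and invariant to row and
    candidate order.
    """
    frame = _as_frame(X)
    if candidates is None:
        candidates = list(frame.columns)
    missing = [c for c in candidates if c not in frame.columns]
    if missing:
        raise KeyError(f"candidates not in feature matrix: {missing}")
    candidates = sorted(set(candidates))
    usable = [c for c in candidates if frame[c].nunique() > 1]
    dropped = sorted(set(candidates) - set(usable))
    if dropped:
        warnings.warn(f"constant candidates ignored: {dropped}",
                      UserWarning, stacklevel=2)

    current = fit_logistic(frame[[]], y, cif=cif, train_years=train_years)
    if not usable:
        warnings.warn("no usable candidates; returning the null model",
                      UserWarning, stacklevel=2)
        return current

    corr = frame[usable].corr().abs() if len(usable) > 1 else None
    selected: list[str] = []
    while True:
        best: tuple[float, str, CIFModel] | None = None
        for cand in usable:
            if cand in selected:
                continue
            if corr is not None and any(
                    corr.loc[cand, s] > correlation_threshold for s in selected):
                continue
            try:
                trial = fit_logistic(frame[selected + [cand]], y, cif=cif,
                                     train_years=train_years)
            except (SeparationError, ConvergenceError, ValueError):
                continue
            key = (trial.bic, cand)
            if best is None or key < (best[0], best[1]):
                best = (trial.bic, cand, trial)
        if best is None or best[0] >= current.bic:
            break
        current = best[2]
        selected.append(best[1])
    # Canonical coefficient order: alphabetical, matching selection ties.
    current.coefficients = {k: current.coefficients[k]
                            for k in sorted(current.coefficients)}
    return current


def refit_on_all_data(selected: CIFModel, X_full, y_full,
                      train_years=None) -> CIFModel:
    """Refit the selected feature set on the entire data set.

    Feature selection happens once on the early-years window; the final
    coefficients come from a refit of that fixed feature set on all
    years.
    """
    frame = _as_frame(X_full)
    missing = [f for f in selected.coefficients if f not in frame.columns]
    if missing:
        raise KeyError(f"selected features missing from full data: {missing}")
    feats = sorted(selected.coefficients)
    return fit_logistic(frame[feats], y_full, cif=selected.cif,
                        train_years=train_years)


def predict_probability(model: CIFModel, x) -> float | np.ndarray:
    """sigmoid(intercept + sum coef * x) for a feature row or frame.

    The log-odds contributions of the binary features are additive.
    ``x`` may be a mapping / Series (returns a float) or a DataFrame
    (returns an array aligned to its rows); every model feature must be
    present.
    """
    if isinstance(x, pd.DataFrame):
        missing = [f for f in model.coefficients if f not in x.columns]
        if missing:
            raise KeyError(f"feature row lacks model features: {missing}")
        eta = np.full(len(x), model.intercept, dtype=float)
        for f, b in model.coefficients.items():
            eta += b * x[f].to_numpy(float)
        return expit(eta)
    missing = [f for f in model.coefficients if f not in x]
    if missing:
        raise KeyError(f"feature row lacks model features: {missing}")
    eta = model.intercept + sum(b * float(x[f])
                                for f, b in model.coefficients.items())
    return float(expit(eta))
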