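"""Rolling-origin backtesting of the per-CIF risk models.

Audit planning is annual, so model quality is judged by how well each
calendar year can be predicted from all earlier years: one split per
year, training on the strict past.  To avoid rewarding the model for
recognizing studies it has already seen, test-year activities belonging
to studies audited in any earlier year are excluded from the test set
(training keeps them).  Discrimination is measured by the rank-based
AUC, calibration by the Brier score, aggregated as mean +/- standard
error over the annual splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .features import BinaryFeatureMatrix
from .model import (CIFModel, ConvergenceError, SeparationError, fit_logistic,
                    predict_probability)

__all__ = [
    "TimeSeriesSplit",
    "PerformanceSummary",
    "time_series_splits",
    "auc",
    "brier",
    "backtest",
]


@dataclass
class TimeSeriesSplit:
    """One train-on-the-past / test-on-one-year split."""

    train_years: tuple[int, ...]
    test_year: int
    train_ids: list[str]
    test_ids: list[str]
    excluded_ids: dict[str, str]     # activity_id -> exclusion reason

    def __post_init__(self) -> None:
        if max(self.train_years) >= self.test_year:
            raise ValueError("training years must all precede the test year")
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test activity sets overlap")


@dataclass
class PerformanceSummary:
    """Per-split and aggregate backtest metrics for one CIF model."""

    cif: str
    per_split: pd.DataFrame          # columns: test_year, auc, brier, n_test
    mean_auc: float
    se_auc: float
    mean_brier: float
    se_brier: float
    #: pooled test-set predictions across splits (activity_id, test_year,
    #: prediction, outcome) — the raw material of the calibration curve.
    predictions: pd.DataFrame = field(default=None, repr=False)


def time_series_splits(activities: pd.DataFrame) -> list[TimeSeriesSplit]:
    """Annual rolling-origin splits with the prior-audit exclusion rule.

    One split per observed year from the second onward; the test set is
    that year's activities minus those whose study already appears in an
    earlier year.  A split whose test set is emptied entirely by the
    exclusion is dropped with a warning.
    """
    years = sorted(activities["year"].unique())
    if len(years) < 2:
        raise ValueError("need at least two distinct years for backtesting")
    splits: list[TimeSeriesSplit] = []
    for test_year in years[1:]:
        past = activities[activities["year"] < test_year]
        test = activities[activities["year"] == test_year]
        first_seen = past.groupby("study_id")["year"].min()
        excluded = {}
        test_ids = []
        for aid, sid in zip(test["activity_id"], test["study_id"]):
            if sid in first_seen.index:
                excluded[aid] = (f"study {sid} previously audited "
                                 f"(first in {int(first_seen[sid])})")
            else:
                test_ids.append(aid)
        if not test_ids:
            warnings.warn(
                f"test year {test_year}: all activities excluded by the "
                "prior-audit rule; split dropped", UserWarning, stacklevel=2)
            continue
        splits.append(TimeSeriesSplit(
            train_years=tuple(int(y) for y in years if y < test_year),
            test_year=int(test_year),
            train_ids=list(past["activity_id"]),
            test_ids=test_ids,
            excluded_ids=excluded))
    return splits


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve.

    Equals the probability that a random positive outscores a random
    negative; tied score pairs contribute 1/2.

    Raises
    ------
    ValueError
        If only one class is present (the AUC is undefined).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.size != y.size or s.size == 0:
        raise ValueError("scores and labels must be non-empty and aligned")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: only one class present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def brier(probabilities: Sequence[float], labels: Sequence[int]) -> float:
    """Mean squared difference between predicted probability and outcome.

    0 is a perfect, 1 the worst possible calibration.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.size != y.size or p.size == 0:
        raise ValueError("probabilities and labels must be non-empty and aligned")
    return float(np.mean((p - y) ** 2))


def backtest(activities: pd.DataFrame, X, outcomes: pd.Series,
             selected_features: Sequence[str], cif: str = "",
             ) -> PerformanceSummary:
    """Refit-and-score the fixed feature set over all annual splits.

    Feature selection is *not* redone per split: the feature set is
    fixed up front and only the coefficients are refit on each training
    window.  Features constant within a training window are dropped from
    that split's refit (with a warning); splits with a single-class
    training outcome are skipped; a single-class test set yields an
    undefined (NaN) AUC but still contributes its Brier score.
    """
    frame = X.values if isinstance(X, BinaryFeatureMatrix) else X
    missing = [f for f in selected_features if f not in frame.columns]
    if missing:
        raise KeyError(f"selected features missing from matrix: {missing}")
    feats = sorted(selected_features)
    records = []
    pooled = []
    for split in time_series_splits(activities):
        y_tr = outcomes.loc[split.train_ids]
        if y_tr.nunique() < 2:
            warnings.warn(f"test year {split.test_year}: single-class training "
                          "outcome; split skipped", UserWarning, stacklevel=2)
            continue
        X_tr = frame.loc[split.train_ids, feats]
        usable = [f for f in feats if X_tr[f].nunique() > 1]
        if len(usable) < len(feats):
            warnings.warn(
                f"test year {split.test_year}: features constant in training "
                f"window dropped: {sorted(set(feats) - set(usable))}",
                UserWarning, stacklevel=2)
        try:
            model = fit_logistic(X_tr[usable], y_tr, cif=cif,
                                 train_years=split.train_years)
        except (SeparationError, ConvergenceError) as exc:
            warnings.warn(f"test year {split.test_year}: unfittable split "
                          f"({exc}); skipped", UserWarning, stacklevel=2)
            continue
        X_te = frame.loc[split.test_ids, usable]
        p = np.atleast_1d(predict_probability(model, X_te))
        y_te = outcomes.loc[split.test_ids].to_numpy()
        try:
            split_auc = auc(p, y_te)
        except ValueError:
            split_auc = np.nan
        records.append({"test_year": split.test_year, "auc": split_auc,
                        "brier": brier(p, y_te), "n_test": len(split.test_ids)})
        pooled.append(pd.DataFrame({
            "activity_id": split.test_ids, "test_year": split.test_year,
            "prediction": p, "outcome": y_te}))
    if not records:
        raise ValueError("no usable splits for backtesting")
    per_split = pd.DataFrame.from_records(records)

    def _agg(col: str) -> tuple[float, float]:
        v = per_split[col].dropna().to_numpy()
        if v.size == 0:
            return float("nan"), float("nan")
        se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
        return float(v.mean()), se

    mean_auc, se_auc = _agg("auc")
    mean_brier, se_brier = _agg("brier")
    return PerformanceSummary(
        cif=cif, per_split=per_split, mean_auc=mean_auc, se_auc=se_auc,
        mean_brier=mean_brier, se_brier=se_brier,
        predictions=pd.concat(pooled, ignore_index=True))
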