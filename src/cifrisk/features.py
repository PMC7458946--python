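"""Hand-crafted binary feature engineering for audit activities.

Continuous covariates are power-transformed (Yeo-Johnson), standardized
and quantile-binned into 5 segments; rare categorical levels (< 5% of
activities) are pooled; candidate signals are binarized with missing
values mapped to "no" (0).  Two special constructions are included: the
within-study site burden score (a cumulative-distribution rank of how
many other sponsor trials of the same therapeutic area run at the site),
and the randomization x design interaction pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RARE_LEVEL_THRESHOLD",
    "CORRELATION_SCREEN_THRESHOLD",
    "FeatureSpec",
    "BinaryFeatureMatrix",
    "yeo_johnson_transform",
    "bin_into_segments",
    "group_rare_levels",
    "binarize",
    "site_burden_score",
    "interaction_randomization_design",
    "build_feature_matrix",
    "max_abs_pairwise_correlation",
    "default_feature_specs",
]

#: Minimum share of activities a retained binary feature must apply to.
RARE_LEVEL_THRESHOLD = 0.05

#: Pairwise |Pearson r| above which two features are flagged as
#: correlated and refused co-selection during model search.  Chosen above
#: the largest magnitude ever tolerated in practice on this data family
#: (|-0.21|) but low enough to keep coefficients interpretable.
CORRELATION_SCREEN_THRESHOLD = 0.3


def yeo_johnson_transform(values: Sequence[float], lmbda: float | None = None,
                          standardize: bool = True) -> tuple[np.ndarray, float]:
    """Yeo-Johnson power transform, by default MLE-fitted and standardized.

    Parameters
    ----------
    values
        At least two distinct finite values (when standardizing).
    lmbda
        Fix the power parameter instead of estimating it by maximum
        likelihood.  Useful for checking the closed-form branches
        (``lmbda=1`` is the identity for x >= 0, ``lmbda=0`` is
        ``log(x + 1)``).
    standardize
        Center to mean 0 and scale to variance 1 after transforming.

    Returns
    -------
    (transformed, lambda)
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D sample of at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if standardize and np.ptp(x) == 0.0:
        raise ValueError("constant input cannot be standardized")
    if lmbda is None:
        transformed, fitted = stats.yeojohnson(x)
        fitted = float(fitted)
    else:
        transformed, fitted = stats.yeojohnson(x, lmbda=float(lmbda)), float(lmbda)
    transformed = np.asarray(transformed, dtype=float)
    if standardize:
        transformed = (transformed - transformed.mean()) / transformed.std(ddof=0)
    return transformed, fitted


def bin_into_segments(values: Sequence[float], n_segments: int = 5) -> np.ndarray:
    """Assign each value to one of ``n_segments`` quantile segments (1-based).

    Boundaries sit at the empirical quantiles i/n_segments; a value equal
    to a boundary falls in the upper segment (inclusive-lower half-open
    convention).  With fewer distinct values than segments the binning
    collapses to one segment per distinct value, with a warning.
    """
    x = np.asarray(values, dtype=float)
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    distinct = np.unique(x)
    if distinct.size < n_segments:
        warnings.warn(
            f"only {distinct.size} distinct values for {n_segments} segments; "
            "collapsing to distinct-value bins", UserWarning, stacklevel=2)
        return np.searchsorted(distinct, x) + 1
    edges = np.quantile(x, np.arange(1, n_segments) / n_segments)
    return np.searchsorted(edges, x, side="right") + 1


def group_rare_levels(labels: Sequence, threshold: float = RARE_LEVEL_THRESHOLD,
                      pooled_label: str = "other") -> pd.Series:
    """Pool every level with prevalence below ``threshold`` into one level."""
    s = pd.Series(labels)
    if s.empty:
        raise ValueError("empty input")
    prevalence = s.value_counts(normalize=True, dropna=True)
    rare = set(prevalence.index[prevalence < threshold])
    return s.where(~s.isin(rare), pooled_label)


def binarize(labels: Sequence, positive_levels: Iterable) -> np.ndarray:
    """Indicator of membership in ``positive_levels``; missing maps to 0."""
    positive = set(positive_levels)
    if not positive:
        raise ValueError("positive_levels must be non-empty")
    s = pd.Series(labels)
    return (s.notna() & s.isin(positive)).to_numpy(int)


def site_burden_score(sites: pd.DataFrame) -> pd.DataFrame:
    """Within-study cumulative-distribution rank of concurrent-trial counts.

    For each study, sites are ranked (ascending, ties by average rank) by
    ``parallel_trials_same_ta`` and the rank is divided by the number of
    sites, yielding scores in (0, 1]; the higher the score, the more
    sponsor trials run concurrently at the site relative to its study
    peers.
    """
    required = {"site_id", "study_id", "parallel_trials_same_ta"}
    missing = required - set(sites.columns)
    if missing:
        raise ValueError(f"sites table is missing columns {sorted(missing)}")
    if sites.empty:
        raise ValueError("need at least one site")
    grouped = sites.groupby("study_id")["parallel_trials_same_ta"]
    score = grouped.rank(method="average", ascending=True) / grouped.transform("size")
    return pd.DataFrame({
        "site_id": sites["site_id"].to_numpy(),
        "study_id": sites["study_id"].to_numpy(),
        "site_burden_score": score.to_numpy(float),
    })


def interaction_randomization_design(randomized, design):
    """The two combined randomization x design indicators.

    Returns ``(nonrand_parallel_or_sequential, nonrand_single_group)``:
    the first is 1 iff the study is non-randomized with a parallel or
    sequential design, the second iff non-randomized single-group.  At
    most one of the two flags is set.  Accepts scalars or aligned arrays.
    """
    r = np.asarray(randomized, dtype=bool)
    d = np.asarray(design, dtype=object)
    nonrand = ~r
    flag_ps = (nonrand & ((d == "parallel") | (d == "sequential"))).astype(int)
    flag_sg = (nonrand & (d == "single_group")).astype(int)
    if flag_ps.ndim == 0:
        return int(flag_ps), int(flag_sg)
    return flag_ps, flag_sg


@dataclass
class FeatureSpec:
    """Declarative rule producing one binary feature column.

    kind
        ``binary_level``: 1 iff the (rare-level-grouped) categorical
        source value is in ``definition["positive_levels"]``.
        ``threshold``: 1 iff source ``direction`` (gt/ge/lt/le) value.
        ``binned_segment``: Yeo-Johnson -> quantile bins -> 1 iff the
        segment index is in ``definition["positive_segments"]``.
        ``burden_score_band``: 1 iff the within-study site burden score
        compares (gt/lt) against ``definition["threshold"]``.
        ``interaction``: one of the two randomization x design flags,
        selected by ``definition["flag"]``.
    """

    name: str
    source_column: str
    kind: str
    definition: dict = field(default_factory=dict)

    _KINDS = ("binary_level", "threshold", "binned_segment",
              "burden_score_band", "interaction")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"spec {self.name!r}: unknown kind {self.kind!r}")


@dataclass
class BinaryFeatureMatrix:
    """Activities x features 0/1 matrix with per-feature prevalence."""

    values: pd.DataFrame              # index activity_id, int columns in {0,1}
    prevalence: dict[str, float]

    @property
    def activity_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def __len__(self) -> int:
        return len(self.values)


_COMPARATORS = {
    "gt": np.greater, "ge": np.greater_equal,
    "lt": np.less, "le": np.less_equal,
}


def _spec_column(spec: FeatureSpec, merged: pd.DataFrame) -> np.ndarray:
    if spec.kind == "interaction":
        flag = spec.definition.get("flag", spec.name)
        ps, sg = interaction_randomization_design(
            merged["randomized"].fillna(True).to_numpy(),
            merged["design"].to_numpy())
        if flag == "nonrand_parallel_or_sequential":
            return ps
        if flag == "nonrand_single_group":
            return sg
        raise ValueError(f"spec {spec.name!r}: unknown interaction flag {flag!r}")

    if spec.kind == "burden_score_band":
        col = merged["site_burden_score"]
        op = _COMPARATORS[spec.definition.get("direction", "gt")]
        return (col.notna() & op(col.fillna(-np.inf), spec.definition["threshold"])).to_numpy(int)

    if spec.source_column not in merged.columns:
        raise KeyError(
            f"feature spec {spec.name!r} references unknown column "
            f"{spec.source_column!r}")
    col = merged[spec.source_column]

    if spec.kind == "binary_level":
        labels = col
        if spec.definition.get("group_rare", False):
            labels = group_rare_levels(labels)
        return binarize(labels, spec.definition["positive_levels"])

    if spec.kind == "threshold":
        op = _COMPARATORS[spec.definition.get("direction", "gt")]
        value = spec.definition["value"]
        return (col.notna() & op(col.fillna(-np.inf), value)).to_numpy(int)

    if spec.kind == "binned_segment":
        n_seg = spec.definition.get("n_segments", 5)
        positive = set(spec.definition["positive_segments"])
        valid = col.notna().to_numpy()
        out = np.zeros(len(col), dtype=int)
        if valid.sum() >= 2:
            transformed, _ = yeo_johnson_transform(col[valid].to_numpy(float))
            segments = bin_into_segments(transformed, n_segments=n_seg)
            out[valid] = np.isin(segments, list(positive)).astype(int)
        return out

    raise AssertionError(f"unhandled kind {spec.kind!r}")


def build_feature_matrix(activities: pd.DataFrame, studies: pd.DataFrame,
                         sites: pd.DataFrame, specs: Sequence[FeatureSpec],
                         rare_threshold: float = RARE_LEVEL_THRESHOLD,
                         ) -> BinaryFeatureMatrix:
    """Resolve feature specs into the binary activities x features matrix.

    Missing source values always yield 0 ("no").  Features whose
    prevalence falls below ``rare_threshold`` are dropped with a warning:
    near-zero-variance predictors are never handed to the models.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("feature spec names must be unique")
    merged = (activities
              .merge(studies, on="study_id", how="left", validate="many_to_one")
              .merge(sites, on=["site_id", "study_id"], how="left",
                     validate="many_to_one"))
    if not sites.empty:
        merged = merged.merge(site_burden_score(sites),
                              on=["site_id", "study_id"], how="left")
    else:
        merged["site_burden_score"] = np.nan

    values = pd.DataFrame(index=pd.Index(activities["activity_id"],
                                         name="activity_id"))
    prevalence: dict[str, float] = {}
    for spec in specs:
        col = _spec_column(spec, merged)
        prev = float(np.mean(col)) if len(col) else 0.0
        if len(col) and prev < rare_threshold:
            warnings.warn(
                f"feature {spec.name!r} applies to {prev:.1%} of activities "
                f"(< {rare_threshold:.0%}); dropped", UserWarning, stacklevel=2)
            continue
        values[spec.name] = col.astype(np.int8) if hasattr(col, "astype") else col
        prevalence[spec.name] = prev
    return BinaryFeatureMatrix(values=values, prevalence=prevalence)


def max_abs_pairwise_correlation(matrix: BinaryFeatureMatrix | pd.DataFrame,
                                 ) -> tuple[float, tuple[str, str]]:
    """Largest |Pearson correlation| over all feature pairs, with the pair.

    Constant features are excluded (with a warning) since their
    correlation is undefined.
    """
    frame = matrix.values if isinstance(matrix, BinaryFeatureMatrix) else matrix
    constant = [c for c in frame.columns if frame[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant features excluded from correlation screen: "
                      f"{constant}", UserWarning, stacklevel=2)
        frame = frame.drop(columns=constant)
    if frame.shape[1] < 2:
        raise ValueError("need at least two non-constant features")
    corr = frame.corr().to_numpy()
    np.fill_diagonal(corr, 0.0)
    i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
    return float(abs(corr[i, j])), (str(frame.columns[min(i, j)]),
                                    str(frame.columns[max(i, j)]))


def default_feature_specs() -> list[FeatureSpec]:
    """The default candidate feature set for the synthetic data schema.

    Mirrors the risk-factor families the per-CIF models draw on: site
    country, pediatric flag, therapeutic area, phase, the randomization x
    design interaction pair, enrollment and screen-failure thresholds,
    AE-reporting timeliness, screening-duration top segment, and the
    site burden score band.
    """
    from .synthetic import (AE_TIMELY_DAYS, ENROLLED_HIGH, ENROLLED_LOW,
                            SCREEN_FAILURE_HIGH, SITE_BURDEN_HIGH)
    return [
        FeatureSpec("country_us", "country", "binary_level",
                    {"positive_levels": ["US"]}),
        FeatureSpec("pediatric", "pediatric", "binary_level",
                    {"positive_levels": [True]}),
        FeatureSpec("ta_oncology", "therapeutic_area", "binary_level",
                    {"positive_levels": ["oncology"]}),
        FeatureSpec("ta_autoimmune", "therapeutic_area", "binary_level",
                    {"positive_levels": ["autoimmune"]}),
        FeatureSpec("ta_neuro", "therapeutic_area", "binary_level",
                    {"positive_levels": ["neuroscience_psychiatry"]}),
        FeatureSpec("phase_1", "phase", "binary_level",
                    {"positive_levels": ["I"]}),
        FeatureSpec("nonrand_parallel_or_sequential", "randomized", "interaction",
                    {"flag": "nonrand_parallel_or_sequential"}),
        FeatureSpec("nonrand_single_group", "randomized", "interaction",
                    {"flag": "nonrand_single_group"}),
        FeatureSpec("enrolled_lt_5", "patients_enrolled", "threshold",
                    {"value": ENROLLED_LOW, "direction": "lt"}),
        FeatureSpec("enrolled_gt_32", "patients_enrolled", "threshold",
                    {"value": ENROLLED_HIGH, "direction": "gt"}),
        FeatureSpec("screen_failure_gt_0.62", "screen_failure_rate", "threshold",
                    {"value": SCREEN_FAILURE_HIGH, "direction": "gt"}),
        FeatureSpec("ae_timely", "ae_reporting_latency_days", "threshold",
                    {"value": AE_TIMELY_DAYS, "direction": "le"}),
        FeatureSpec("long_screening_per_enrolled",
                    "active_screening_days_per_enrolled", "binned_segment",
                    {"n_segments": 5, "positive_segments": [5]}),
        FeatureSpec("high_site_burden", "parallel_trials_same_ta",
                    "burden_score_band",
                    {"threshold": SITE_BURDEN_HIGH, "direction": "gt"}),
    ]
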