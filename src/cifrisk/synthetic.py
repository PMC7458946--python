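"""Synthetic audit/study/site data with a known ground-truth risk structure.

The generator emulates the descriptive statistics of a large sponsor's
clinical quality-assurance program: roughly 86.7 audit or inspection
activities per calendar year over 2011-2018, of which ~13% are regulatory
inspections, each activity producing 5.9 findings on average, and per-CIF
base rates of activities with at least one finding (consent 55%, data
integrity 84%, protecting primary endpoints 86%, safety 59%, sponsor
oversight 76%).

Ground truth: per-CIF presence of a finding is Bernoulli with probability
sigmoid(intercept_c + sum of true log-odds coefficients over binary
site/study features).  The intercept of each CIF is solved numerically so
that the marginal presence rate over the generated activities equals the
configured base rate.  Given presence, the finding count is
1 + Poisson(mu), with mu chosen so the overall mean findings per activity
matches the configured value.

Studies stay "auditable" for a geometric number of years, so a fraction
of studies is audited in several calendar years — this is what gives the
time-series cross-validation's prior-audit exclusion rule something to
exclude.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cif import CIFS, finding_column

__all__ = [
    "ConfigError",
    "GeneratorConfig",
    "SyntheticDataset",
    "generate_dataset",
    "intercept_for_base_rate",
    "truth_feature_matrix",
    "write_dataset",
    "DEFAULT_BASE_RATES",
    "DEFAULT_TRUE_COEFFICIENTS",
    "DEFAULT_FEATURE_MARGINALS",
]


class ConfigError(ValueError):
    """Raised when a generator configuration is internally inconsistent."""


# ---------------------------------------------------------------------------
# Defaults: the study conditions the generator emulates.
# ---------------------------------------------------------------------------

DEFAULT_BASE_RATES: dict[str, float] = {
    "consent": 0.55,
    "data_integrity": 0.84,
    "protecting_primary_endpoints": 0.86,
    "safety": 0.59,
    "sponsor_oversight": 0.76,
}

# Fixed thresholds that define the ground-truth binary features derived
# from continuous site covariates.  The enrollment and screen-failure
# cut points are the ones the fitted models single out on real data.
SCREEN_FAILURE_HIGH = 0.62
ENROLLED_LOW = 5          # "fewer than 5 patients"
ENROLLED_HIGH = 32        # "more than 32 patients"
AE_TIMELY_DAYS = 2.0      # AE reported within 2 days of onset
SCREENING_DAYS_HIGH = 33.28   # 80th pct of the screening-duration draw
SITE_BURDEN_HIGH = 0.75   # top quarter of the within-study burden score

#: Default ground-truth log-odds coefficients per CIF.  Feature names and
#: coefficient signs mirror the risk factors the per-CIF models identify
#: on real audit data (US sites and pediatric studies raise consent risk,
#: timely AE reporting lowers safety and data-integrity risk, and so on);
#: magnitudes are moderate (0.5-0.9) to emulate a weak-signal regime.
DEFAULT_TRUE_COEFFICIENTS: dict[str, dict[str, float]] = {
    "consent": {
        "country_us": 0.6,
        "pediatric": 0.8,
        "ta_autoimmune": -0.6,
        "long_screening_per_enrolled": -0.5,
    },
    "safety": {
        "ta_oncology": 0.9,
        "ae_timely": -0.8,
    },
    "data_integrity": {
        "enrolled_lt_5": -0.8,
        "screen_failure_gt_0.62": -0.6,
        "high_site_burden": 0.6,
        "ae_timely": -0.6,
    },
    "protecting_primary_endpoints": {
        "phase_1": 0.7,
        "ta_neuro": 0.7,
        "ta_autoimmune": -0.6,
        "high_site_burden": 0.6,
        "screen_failure_gt_0.62": -0.5,
        "enrolled_gt_32": -0.5,
    },
    "sponsor_oversight": {
        "nonrand_parallel_or_sequential": -0.9,
        "nonrand_single_group": -0.5,
        "screen_failure_gt_0.62": -0.5,
        "enrolled_gt_32": -0.5,
    },
}

#: Approximate marginal prevalence of each ground-truth feature among
#: activities under the default covariate distributions (every one is
#: >= 0.05, so engineered features clear the rare-level rule by design).
DEFAULT_FEATURE_MARGINALS: dict[str, float] = {
    "country_us": 0.45,
    "pediatric": 0.10,
    "ta_oncology": 0.50,
    "ta_autoimmune": 0.15,
    "ta_neuro": 0.10,
    "phase_1": 0.15,
    "nonrand_parallel_or_sequential": 0.2275,
    "nonrand_single_group": 0.0875,
    "enrolled_lt_5": 0.16,
    "enrolled_gt_32": 0.15,
    "screen_failure_gt_0.62": 0.3235,
    "ae_timely": 0.4866,
    "long_screening_per_enrolled": 0.20,
    "high_site_burden": 0.25,
}

_PHASES = ("I", "II", "III", "IV")
_PHASE_P = (0.15, 0.30, 0.45, 0.10)
_TAS = ("oncology", "autoimmune", "neuroscience_psychiatry", "other")
_TA_P = (0.50, 0.15, 0.10, 0.25)
_DESIGNS = ("parallel", "single_group", "crossover", "sequential")
_DESIGN_P = (0.55, 0.25, 0.10, 0.10)
_COUNTRIES = ("US", "DE", "UK", "FR", "CH", "ES", "IT", "JP", "CN", "BR", "CA", "AU")
_COUNTRY_P = (0.45, 0.08, 0.07, 0.06, 0.05, 0.05, 0.05, 0.05, 0.04, 0.04, 0.03, 0.03)

_P_RANDOMIZED = 0.65
_P_PEDIATRIC = 0.10
_ENROLL_NB_R = 1.5
_ENROLL_NB_MEAN = 18.0
_SCREENING_LOG_MU = 3.0
_SCREENING_LOG_SIGMA = 0.6
_AE_LATENCY_MEAN = 3.0
_PARALLEL_TRIALS_MEAN = 3.0
_STUDY_PERSISTENCE_P = 0.5   # P(study stops being auditable each year)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic audit-data generator.

    Defaults reproduce the descriptive statistics of the emulated QA
    program (see module docstring).
    """

    n_years: int = 8
    start_year: int = 2011
    audits_per_year: float = 86.7
    inspection_fraction: float = 0.13
    mean_findings_per_audit: float = 5.9
    cif_base_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_RATES))
    n_studies: int = 150
    sites_per_study: tuple[int, int] = (2, 8)
    true_coefficients: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_TRUE_COEFFICIENTS.items()})
    feature_marginals: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_MARGINALS))
    seed: int = 0

    def validate(self) -> None:
        if self.n_years < 1:
            raise ConfigError("n_years must be >= 1")
        if self.audits_per_year <= 0:
            raise ConfigError("audits_per_year must be positive")
        if not 0.0 <= self.inspection_fraction <= 1.0:
            raise ConfigError("inspection_fraction must lie in [0, 1]")
        if set(self.cif_base_rates) != set(CIFS):
            raise ConfigError(
                f"cif_base_rates must have exactly the keys {CIFS}")
        for cif, rate in self.cif_base_rates.items():
            if not 0.0 < rate < 1.0:
                raise ConfigError(f"base rate for {cif} must lie in (0, 1)")
        for name, m in self.feature_marginals.items():
            if m < 0.05 or m > 0.95:
                raise ConfigError(
                    f"feature marginal for {name!r} must lie in [0.05, 0.95]")
        rate_sum = sum(self.cif_base_rates.values())
        if self.mean_findings_per_audit < rate_sum:
            raise ConfigError(
                "mean_findings_per_audit must be at least the sum of the CIF "
                f"base rates ({rate_sum:.3f}): each activity with a positive "
                "CIF contributes at least one finding")
        lo, hi = self.sites_per_study
        if not (1 <= lo <= hi):
            raise ConfigError("sites_per_study must be a range (lo, hi) with 1 <= lo <= hi")
        for cif in self.true_coefficients:
            if cif not in CIFS:
                raise ConfigError(f"true_coefficients has unknown CIF {cif!r}")

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.n_years))


@dataclass
class SyntheticDataset:
    """Generated tables plus the ground truth used to generate them.

    ``activities`` has one row per audit/inspection activity with per-CIF
    finding-count columns ``finding_<cif>``; ``studies`` and ``sites``
    hold the covariates features are engineered from; ``truth`` records
    the intercepts and coefficients of the generating model.
    """

    activities: pd.DataFrame
    studies: pd.DataFrame
    sites: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# Ground-truth feature engineering (what the generating model "sees").
# ---------------------------------------------------------------------------

def truth_feature_matrix(activities: pd.DataFrame, studies: pd.DataFrame,
                         sites: pd.DataFrame) -> pd.DataFrame:
    """Binary ground-truth features per activity, indexed by activity_id.

    These are the features the generating logistic model is defined on.
    The feature-engineering pipeline is expected to reconstruct the same
    columns from the raw tables, which is what makes parameter-recovery
    experiments meaningful.
    """
    merged = (activities[["activity_id", "study_id", "site_id"]]
              .merge(studies, on="study_id", how="left", validate="many_to_one")
              .merge(sites, on=["site_id", "study_id"], how="left",
                     validate="many_to_one"))
    # Within-study burden score: CDF rank of concurrent same-TA trials.
    from .features import site_burden_score  # local import: avoid cycle at import time
    burden = site_burden_score(sites)
    merged = merged.merge(burden, on=["site_id", "study_id"], how="left")

    out = pd.DataFrame(index=pd.Index(merged["activity_id"], name="activity_id"))
    out["country_us"] = (merged["country"] == "US").to_numpy(int)
    out["pediatric"] = merged["pediatric"].to_numpy(int)
    out["ta_oncology"] = (merged["therapeutic_area"] == "oncology").to_numpy(int)
    out["ta_autoimmune"] = (merged["therapeutic_area"] == "autoimmune").to_numpy(int)
    out["ta_neuro"] = (merged["therapeutic_area"] == "neuroscience_psychiatry").to_numpy(int)
    out["phase_1"] = (merged["phase"] == "I").to_numpy(int)
    nonrand = ~merged["randomized"].astype(bool)
    out["nonrand_parallel_or_sequential"] = (
        nonrand & merged["design"].isin(["parallel", "sequential"])).to_numpy(int)
    out["nonrand_single_group"] = (
        nonrand & (merged["design"] == "single_group")).to_numpy(int)
    out["enrolled_lt_5"] = (merged["patients_enrolled"] < ENROLLED_LOW).to_numpy(int)
    out["enrolled_gt_32"] = (merged["patients_enrolled"] > ENROLLED_HIGH).to_numpy(int)
    out["screen_failure_gt_0.62"] = (
        merged["screen_failure_rate"] > SCREEN_FAILURE_HIGH).to_numpy(int)
    out["ae_timely"] = (
        merged["ae_reporting_latency_days"] <= AE_TIMELY_DAYS).to_numpy(int)
    out["long_screening_per_enrolled"] = (
        merged["active_screening_days_per_enrolled"] > SCREENING_DAYS_HIGH).to_numpy(int)
    out["high_site_burden"] = (merged["site_burden_score"] > SITE_BURDEN_HIGH).to_numpy(int)
    return out


# ---------------------------------------------------------------------------
# Intercept calibration.
# ---------------------------------------------------------------------------

def _solve_intercept(target_rate: float, eta: np.ndarray,
                     weights: np.ndarray | None = None) -> float:
    """Intercept b with weighted-mean sigmoid(b + eta) == target_rate."""

    def gap(b: float) -> float:
        p = expit(b + eta)
        mean = float(np.average(p, weights=weights))
        return mean - target_rate

    lo, hi = -30.0, 30.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError("no intercept in [-30, 30] achieves the target rate")
    return float(brentq(gap, lo, hi, xtol=1e-10))


def intercept_for_base_rate(target_rate: float,
                            coefficients: dict[str, float],
                            feature_marginals: dict[str, float],
                            max_enumeration: int = 4096,
                            n_samples: int = 200_000,
                            seed: int = 0) -> float:
    """Intercept giving a population-average event rate of ``target_rate``.

    Features are treated as independent Bernoulli variables with the
    given marginals.  With k nonzero-coefficient features the expectation
    is evaluated exactly by enumerating the 2**k binary support (when it
    fits in ``max_enumeration`` points) or by large-sample averaging
    otherwise, and the intercept is found by root-finding.
    """
    if not 0.0 < target_rate < 1.0:
        raise ValueError("target_rate must lie in (0, 1)")
    active = [(f, c) for f, c in sorted(coefficients.items()) if c != 0.0]
    if not active:
        return float(np.log(target_rate / (1.0 - target_rate)))
    for f, _ in active:
        if f not in feature_marginals:
            raise KeyError(f"no marginal prevalence provided for feature {f!r}")
    k = len(active)
    if 2 ** k <= max_enumeration:
        coefs = np.array([c for _, c in active])
        margs = np.array([feature_marginals[f] for f, _ in active])
        grid = np.array(np.meshgrid(*[[0, 1]] * k, indexing="ij")).reshape(k, -1).T
        eta = grid @ coefs
        w = np.prod(np.where(grid == 1, margs, 1.0 - margs), axis=1)
        return _solve_intercept(target_rate, eta, weights=w)
    rng = np.random.default_rng(seed)
    draws = rng.random((n_samples, k)) < np.array([feature_marginals[f] for f, _ in active])
    eta = draws @ np.array([c for _, c in active])
    return _solve_intercept(target_rate, eta)


# ---------------------------------------------------------------------------
# Generation.
# ---------------------------------------------------------------------------

def _draw_studies(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_studies
    years = cfg.years
    start = rng.integers(0, cfg.n_years, size=n)
    duration = rng.geometric(_STUDY_PERSISTENCE_P, size=n)
    end = np.minimum(start + duration - 1, cfg.n_years - 1)
    return pd.DataFrame({
        "study_id": [f"ST{i:04d}" for i in range(n)],
        "phase": rng.choice(_PHASES, size=n, p=_PHASE_P),
        "therapeutic_area": rng.choice(_TAS, size=n, p=_TA_P),
        "randomized": rng.random(n) < _P_RANDOMIZED,
        "design": rng.choice(_DESIGNS, size=n, p=_DESIGN_P),
        "pediatric": rng.random(n) < _P_PEDIATRIC,
        "first_active_year": np.asarray(years)[start],
        "last_active_year": np.asarray(years)[end],
    })


def _draw_sites(cfg: GeneratorConfig, studies: pd.DataFrame,
                rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = cfg.sites_per_study
    rows = []
    nb_p = _ENROLL_NB_R / (_ENROLL_NB_R + _ENROLL_NB_MEAN)
    for study_id in studies["study_id"]:
        n_sites = int(rng.integers(lo, hi + 1))
        for j in range(n_sites):
            rows.append({
                "site_id": f"{study_id}-S{j:02d}",
                "study_id": study_id,
                "country": rng.choice(_COUNTRIES, p=_COUNTRY_P),
                "patients_enrolled": int(rng.negative_binomial(_ENROLL_NB_R, nb_p)),
                "screen_failure_rate": float(rng.beta(2.0, 2.0)),
                "active_screening_days_per_enrolled": float(
                    rng.lognormal(_SCREENING_LOG_MU, _SCREENING_LOG_SIGMA)),
                "parallel_trials_same_ta": int(rng.poisson(_PARALLEL_TRIALS_MEAN)),
                "ae_reporting_latency_days": float(rng.exponential(_AE_LATENCY_MEAN)),
            })
    return pd.DataFrame(rows)


def generate_dataset(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Generate activities, studies and sites tables with known truth.

    Reproducible: a fixed ``config.seed`` fixes every output bit-for-bit.

    Raises
    ------
    ConfigError
        If the configuration is infeasible, e.g. the target mean findings
        per activity is below the sum of the CIF base rates.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    studies = _draw_studies(cfg, rng)
    sites = _draw_sites(cfg, studies, rng)
    sites_by_study = sites.groupby("study_id")["site_id"].apply(list).to_dict()

    # Activities: Poisson volume per year, assigned to a study active that
    # year (uniformly) and one of its sites (uniformly).
    act_rows = []
    counter = 0
    for year in cfg.years:
        active = studies.loc[
            (studies["first_active_year"] <= year)
            & (studies["last_active_year"] >= year), "study_id"].to_numpy()
        if active.size == 0:        # degenerate tiny configs only
            active = studies["study_id"].to_numpy()
        n_act = int(rng.poisson(cfg.audits_per_year))
        for _ in range(n_act):
            study_id = str(rng.choice(active))
            site_id = str(rng.choice(sites_by_study[study_id]))
            act_rows.append({
                "activity_id": f"A{counter:05d}",
                "year": year,
                "activity_type": "inspection"
                if rng.random() < cfg.inspection_fraction else "audit",
                "study_id": study_id,
                "site_id": site_id,
            })
            counter += 1
    activities = pd.DataFrame(act_rows)

    # Per-CIF presence through the ground-truth logistic model.
    feats = truth_feature_matrix(activities, studies, sites)
    rate_sum = sum(cfg.cif_base_rates.values())
    mu_extra = (cfg.mean_findings_per_audit - rate_sum) / rate_sum
    intercepts: dict[str, float] = {}
    for cif in CIFS:
        coefs = cfg.true_coefficients.get(cif, {})
        eta = np.zeros(len(feats))
        for fname, c in coefs.items():
            if fname not in feats.columns:
                raise ConfigError(
                    f"true coefficient on unknown feature {fname!r} for CIF {cif}")
            eta += c * feats[fname].to_numpy()
        b = _solve_intercept(cfg.cif_base_rates[cif], eta)
        intercepts[cif] = b
        present = rng.random(len(feats)) < expit(b + eta)
        counts = np.where(present, 1 + rng.poisson(mu_extra, size=len(feats)), 0)
        activities[finding_column(cif)] = counts

    truth = {
        "intercepts": intercepts,
        "coefficients": {c: dict(cfg.true_coefficients.get(c, {})) for c in CIFS},
        "mu_extra_findings": mu_extra,
        "thresholds": {
            "screen_failure_high": SCREEN_FAILURE_HIGH,
            "enrolled_low": ENROLLED_LOW,
            "enrolled_high": ENROLLED_HIGH,
            "ae_timely_days": AE_TIMELY_DAYS,
            "screening_days_high": SCREENING_DAYS_HIGH,
            "site_burden_high": SITE_BURDEN_HIGH,
        },
        "config": {k: v for k, v in dataclasses.asdict(cfg).items()
                   if k not in ("true_coefficients",)},
    }
    return SyntheticDataset(activities=activities, studies=studies,
                            sites=sites, truth=truth)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write activities.csv, studies.csv, sites.csv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "activities": out / "activities.csv",
        "studies": out / "studies.csv",
        "sites": out / "sites.csv",
        "truth": out / "truth.json",
    }
    dataset.activities.to_csv(paths["activities"], index=False)
    dataset.studies.to_csv(paths["studies"], index=False)
    dataset.sites.to_csv(paths["sites"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(dataset.truth, fh, indent=2, sort_keys=True)
    return paths
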