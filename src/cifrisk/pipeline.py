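"""End-to-end pipeline: simulate -> features -> fit -> backtest -> calibrate -> report.

Each stage reads its inputs from and persists its outputs into a working
directory, so any stage can be re-run in isolation from the persisted
intermediates and reproduce the downstream outputs bit-identically.
``run_pipeline`` chains all stages for all five CIFs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cif import CIFS, finding_column
from .synthetic import GeneratorConfig, generate_dataset, write_dataset
from .features import (FeatureSpec, build_feature_matrix, default_feature_specs,
                       BinaryFeatureMatrix)
from .model import (CIFModel, make_binary_outcome, select_features_bic,
                    refit_on_all_data)
from .validation import backtest
from .calibration import bin_predictions, fit_step_calibration, CalibrationCurve

__all__ = [
    "PipelineConfig",
    "RunReport",
    "SchemaError",
    "run_pipeline",
    "read_tables",
    "load_feature_specs",
    "save_feature_specs",
    "stage_simulate",
    "stage_features",
    "stage_fit",
    "stage_backtest",
    "stage_calibrate",
    "stage_report",
]

log = logging.getLogger("cifrisk")

ACTIVITY_COLUMNS = ["activity_id", "year", "activity_type", "study_id",
                    "site_id"] + [finding_column(c) for c in CIFS]
STUDY_COLUMNS = ["study_id", "phase", "therapeutic_area", "randomized",
                 "design", "pediatric"]
SITE_COLUMNS = ["site_id", "study_id", "country", "patients_enrolled",
                "screen_failure_rate", "active_screening_days_per_enrolled",
                "parallel_trials_same_ta", "ae_reporting_latency_days"]


class SchemaError(ValueError):
    """Input table does not match the expected schema or breaks references."""


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Either ``generator`` (synthetic data) or ``input_dir`` (pre-existing
    activities/studies/sites CSVs) supplies the raw tables.
    """

    out_dir: str | Path = "cifrisk_run"
    seed: int = 0
    generator: GeneratorConfig | None = None
    input_dir: str | Path | None = None
    feature_specs: list[FeatureSpec] | None = None
    selection_years: tuple[int, int] = (2011, 2015)
    n_bins: int = 4
    ci_level: float = 0.75
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.generator is None and self.input_dir is None:
            self.generator = GeneratorConfig(seed=self.seed)
        elif self.generator is not None:
            self.generator.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "generator" in raw and isinstance(raw["generator"], dict):
            gen = raw["generator"]
            if "sites_per_study" in gen:
                gen["sites_per_study"] = tuple(gen["sites_per_study"])
            raw["generator"] = GeneratorConfig(**gen)
        if "feature_specs" in raw and isinstance(raw["feature_specs"], list):
            raw["feature_specs"] = [FeatureSpec(**s) for s in raw["feature_specs"]]
        if "selection_years" in raw:
            raw["selection_years"] = tuple(raw["selection_years"])
        return cls(**raw)

    def digest(self) -> str:
        # hash of the analysis configuration; the output location is
        # deliberately excluded so re-runs elsewhere hash identically
        payload = dataclasses.asdict(self)
        del payload["out_dir"]
        payload["input_dir"] = (str(payload["input_dir"])
                                if payload["input_dir"] else None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


@dataclass
class RunReport:
    """Final artifacts of a pipeline run, per CIF."""

    coefficients: pd.DataFrame       # cif, feature, coefficient
    performance: pd.DataFrame        # cif, mean_auc, se_auc, mean_brier, ...
    curves: dict[str, CalibrationCurve]
    provenance: dict = field(default_factory=dict)


def save_feature_specs(specs: list[FeatureSpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([dataclasses.asdict(s) for s in specs], fh,
                       sort_keys=False)


def load_feature_specs(path: str | Path) -> list[FeatureSpec]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [FeatureSpec(**s) for s in raw]


def read_tables(data_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame,
                                               pd.DataFrame]:
    """Read and validate activities/studies/sites CSVs from a directory.

    Checks the required columns of each table and the referential
    integrity of the activity table (every study and site it names must
    exist).
    """
    data_dir = Path(data_dir)
    frames = {}
    for name, required in (("activities", ACTIVITY_COLUMNS),
                           ("studies", STUDY_COLUMNS),
                           ("sites", SITE_COLUMNS)):
        path = data_dir / f"{name}.csv"
        if not path.exists():
            raise SchemaError(f"missing input table {path}")
        df = pd.read_csv(path)
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{name}.csv is missing columns {missing}")
        frames[name] = df
    activities, studies, sites = (frames["activities"], frames["studies"],
                                  frames["sites"])
    bad_studies = sorted(set(activities["study_id"]) - set(studies["study_id"]))
    if bad_studies:
        raise SchemaError(
            f"activities reference unknown study_id values: {bad_studies[:10]}")
    site_keys = set(zip(sites["site_id"], sites["study_id"]))
    bad_sites = sorted({sid for sid, stid in
                        zip(activities["site_id"], activities["study_id"])
                        if (sid, stid) not in site_keys})
    if bad_sites:
        raise SchemaError(
            f"activities reference unknown site_id values: {bad_sites[:10]}")
    return activities, studies, sites


# ---------------------------------------------------------------------------
# Stages.  Each persists into <out_dir> and is re-runnable in isolation.
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    data_dir = out / "data"
    if config.input_dir is not None:
        activities, studies, sites = read_tables(config.input_dir)
        data_dir.mkdir(parents=True, exist_ok=True)
        activities.to_csv(data_dir / "activities.csv", index=False)
        studies.to_csv(data_dir / "studies.csv", index=False)
        sites.to_csv(data_dir / "sites.csv", index=False)
    else:
        ds = generate_dataset(config.generator)
        write_dataset(ds, data_dir)
        activities = ds.activities
    log.info("simulate: wrote %d activities to %s", len(activities), data_dir)
    return data_dir


def stage_features(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    activities, studies, sites = read_tables(out / "data")
    specs = config.feature_specs or default_feature_specs()
    save_feature_specs(specs, out / "feature_specs.yaml")
    matrix = build_feature_matrix(activities, studies, sites, specs)
    matrix.values.to_csv(out / "feature_matrix.csv")
    log.info("features: %d activities x %d features", len(matrix),
             len(matrix.feature_names))
    return out / "feature_matrix.csv"


def _load_matrix(out: Path) -> pd.DataFrame:
    return pd.read_csv(out / "feature_matrix.csv", index_col="activity_id")


def stage_fit(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    activities, _, _ = read_tables(out / "data")
    frame = _load_matrix(out)
    lo, hi = config.selection_years
    observed = set(activities["year"].unique())
    window_years = [y for y in observed if lo <= y <= hi]
    if not window_years:
        raise ValueError(
            f"selection window {config.selection_years} contains none of the "
            f"observed years {sorted(observed)}")
    window_ids = activities.loc[activities["year"].isin(window_years),
                                "activity_id"]
    models = {}
    for cif in CIFS:
        y = make_binary_outcome(activities, cif)
        selected = select_features_bic(frame.loc[window_ids], y.loc[window_ids],
                                       cif=cif, train_years=(lo, hi))
        final = (refit_on_all_data(selected, frame, y,
                                   train_years=(int(min(observed)),
                                                int(max(observed))))
                 if selected.coefficients else
                 select_features_bic(frame, y, candidates=[], cif=cif))
        models[cif] = {"selected": selected.to_dict(), "final": final.to_dict()}
        log.info("fit %s: %d features selected, BIC %.1f", cif,
                 len(selected.coefficients), selected.bic)
    with open(out / "models.json", "w") as fh:
        json.dump(models, fh, indent=2, sort_keys=True)
    coef_rows = [{"cif": cif, "feature": f, "coefficient": b}
                 for cif, m in models.items()
                 for f, b in [("(intercept)", m["final"]["intercept"]),
                              *sorted(m["final"]["coefficients"].items())]]
    pd.DataFrame(coef_rows).to_csv(out / "coefficients.csv", index=False)
    return out / "models.json"


def stage_backtest(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    activities, _, _ = read_tables(out / "data")
    frame = _load_matrix(out)
    with open(out / "models.json") as fh:
        models = json.load(fh)
    metric_rows, pred_frames = [], []
    for cif in CIFS:
        feats = sorted(models[cif]["final"]["coefficients"])
        y = make_binary_outcome(activities, cif)
        summary = backtest(activities, frame, y, feats, cif=cif)
        per = summary.per_split.assign(cif=cif)
        metric_rows.append(per)
        pred_frames.append(summary.predictions.assign(cif=cif))
        log.info("backtest %s: mean AUC %.3f, mean Brier %.3f over %d splits",
                 cif, summary.mean_auc, summary.mean_brier, len(per))
    pd.concat(metric_rows, ignore_index=True).to_csv(
        out / "backtest_metrics.csv", index=False)
    pd.concat(pred_frames, ignore_index=True).to_csv(
        out / "cv_predictions.csv", index=False)
    return out / "backtest_metrics.csv"


def stage_calibrate(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    activities, _, _ = read_tables(out / "data")
    preds = pd.read_csv(out / "cv_predictions.csv")
    curves = {}
    for cif in CIFS:
        sub = preds[preds["cif"] == cif]
        base_rate = float(make_binary_outcome(activities, cif).mean())
        bins = bin_predictions(sub["prediction"].to_numpy(),
                               sub["outcome"].to_numpy(), n_bins=config.n_bins)
        curve = fit_step_calibration(bins, base_rate, cif=cif)
        curves[cif] = curve.to_dict()
        log.info("calibrate %s: %d steps, range %.3f-%.3f (delta %.3f)", cif,
                 len(curve.steps), *curve.prediction_range, curve.delta)
    with open(out / "curves.json", "w") as fh:
        json.dump(curves, fh, indent=2, sort_keys=True)
    return out / "curves.json"


def stage_report(config: PipelineConfig) -> RunReport:
    out = Path(config.out_dir)
    with open(out / "models.json") as fh:
        models = json.load(fh)
    with open(out / "curves.json") as fh:
        curves_raw = json.load(fh)
    metrics = pd.read_csv(out / "backtest_metrics.csv")
    curves = {cif: CalibrationCurve.from_dict(d) for cif, d in curves_raw.items()}

    perf_rows = []
    for cif in CIFS:
        per = metrics[metrics["cif"] == cif]
        auc_v = per["auc"].dropna()
        brier_v = per["brier"].dropna()
        curve = curves[cif]
        perf_rows.append({
            "cif": cif,
            "mean_auc": auc_v.mean(), "se_auc": auc_v.sem(ddof=1),
            "mean_brier": brier_v.mean(), "se_brier": brier_v.sem(ddof=1),
            "calibrated_min": curve.prediction_range[0],
            "calibrated_max": curve.prediction_range[1],
            "calibrated_delta": curve.delta,
            "base_rate": curve.base_rate,
            "n_coefficients": len(models[cif]["final"]["coefficients"]),
        })
    performance = pd.DataFrame(perf_rows)
    coefficients = pd.read_csv(out / "coefficients.csv")
    from . import __version__
    provenance = {"config_sha256": config.digest(), "seed": config.seed,
                  "version": __version__}
    performance.to_csv(out / "performance.csv", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump({"performance": perf_rows, "provenance": provenance},
                  fh, indent=2, sort_keys=True, default=float)
    log.info("report: wrote %s", out / "report.json")
    return RunReport(coefficients=coefficients, performance=performance,
                     curves=curves, provenance=provenance)


_STAGES = (stage_simulate, stage_features, stage_fit, stage_backtest,
           stage_calibrate)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage in order for all five CIFs; deterministic per seed."""
    logging.basicConfig(level=config.log_level)
    Path(config.out_dir).mkdir(parents=True, exist_ok=True)
    for stage in _STAGES:
        try:
            stage(config)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage {stage.__name__!r} failed: {exc}") from exc
    return stage_report(config)
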