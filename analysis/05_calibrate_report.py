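"""Calibrate the cross-validated predictions and collate the run report.

Pools each CIF's test-set predictions across the annual splits, divides
their range into 4 equal bins, and fits the CI75 step function: bins
whose 75% confidence interval overlaps the base rate are merged with a
like neighbor or defaulted to the base rate.  The width of the
calibrated range (delta) says how far the model can credibly move the
risk estimate away from the base rate; delta = 0 means the held-out
evidence never leaves it.  Also writes one calibration figure per CIF
and the final performance table.
"""

import json
import sys
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import make_config, parse_args

import pandas as pd

from cifrisk.calibration import (CalibrationCurve, bin_predictions,
                                 plot_calibration)
from cifrisk.model import make_binary_outcome
from cifrisk.pipeline import read_tables, stage_calibrate, stage_report


def main() -> None:
    args = parse_args(__doc__)
    cfg = make_config(args)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stage_calibrate(cfg)
        report = stage_report(cfg)
    out = Path(cfg.out_dir)
    print(report.performance.round(3).to_string(index=False))

    activities, _, _ = read_tables(out / "data")
    preds = pd.read_csv(out / "cv_predictions.csv")
    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    with open(out / "curves.json") as fh:
        curves = json.load(fh)
    for cif, raw in curves.items():
        curve = CalibrationCurve.from_dict(raw)
        sub = preds[preds["cif"] == cif]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bins = bin_predictions(sub["prediction"].to_numpy(),
                                   sub["outcome"].to_numpy(),
                                   n_bins=cfg.n_bins)
        plot_calibration(curve, bins, fig_dir / f"calibration_{cif}.png")
    print(f"figures under {fig_dir}")


if __name__ == "__main__":
    main()
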