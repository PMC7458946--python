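"""Step-function recalibration of cross-validated risk predictions.

The range of the pooled test-set predictions is divided into 4 equal
bins; each bin's observed event rate and its 75% confidence interval
(CI75, Wilson score) are computed.  Bins whose CI75 overlaps the CIF's
base rate are either merged with a neighboring bin or defaulted to the
base rate, so the final step function only deviates from the base rate
where the held-out evidence supports it.  Its extreme steps define the
calibrated prediction range — the band within which the model can be
trusted to move the risk estimate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "CalibrationBin",
    "CalibrationCurve",
    "bin_predictions",
    "ci75",
    "fit_step_calibration",
    "apply_calibration",
    "plot_calibration",
]

CI_LEVEL = 0.75


@dataclass
class CalibrationBin:
    """One predicted-probability bin with its observed event rate.

    The bin covers [lower, upper) — the last bin of a partition is
    closed.  ``observed`` and the CI75 bounds are NaN for empty bins.
    """

    lower: float
    upper: float
    n: int
    n_pos: int

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("bin bounds must satisfy lower < upper")
        if not 0 <= self.n_pos <= self.n:
            raise ValueError("need 0 <= n_pos <= n")

    @property
    def observed(self) -> float:
        return self.n_pos / self.n if self.n else float("nan")

    @property
    def ci(self) -> tuple[float, float]:
        if self.n == 0:
            return (float("nan"), float("nan"))
        return ci75(self.n_pos, self.n)


@dataclass
class CalibrationCurve:
    """Ordered step function from predicted to calibrated probability."""

    steps: list[tuple[tuple[float, float], float]]   # ((lower, upper), value)
    base_rate: float
    cif: str = ""

    def __post_init__(self) -> None:
        for (lo, hi), _ in self.steps:
            if not lo < hi:
                raise ValueError("step ranges must satisfy lower < upper")
        for ((_, hi), _), ((lo2, _), _) in zip(self.steps, self.steps[1:]):
            if not np.isclose(hi, lo2):
                raise ValueError("step ranges must partition the binned range")

    @property
    def prediction_range(self) -> tuple[float, float]:
        values = [v for _, v in self.steps]
        return (min(values), max(values))

    @property
    def delta(self) -> float:
        """Width of the calibrated prediction range (0 iff constant)."""
        lo, hi = self.prediction_range
        return hi - lo

    @property
    def is_constant(self) -> bool:
        return len({v for _, v in self.steps}) == 1

    def to_dict(self) -> dict:
        return {"cif": self.cif, "base_rate": self.base_rate,
                "steps": [{"lower": lo, "upper": hi, "value": v}
                          for (lo, hi), v in self.steps],
                "prediction_range": list(self.prediction_range),
                "delta": self.delta}

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(steps=[((s["lower"], s["upper"]), s["value"])
                          for s in d["steps"]],
                   base_rate=float(d["base_rate"]), cif=d.get("cif", ""))


def bin_predictions(predictions: Sequence[float], outcomes: Sequence[int],
                    n_bins: int = 4) -> list[CalibrationBin]:
    """Divide the prediction range into equal-width bins and count events.

    Bins are range-based (not quantile-based): edges are equally spaced
    between the minimum and maximum predicted value.  Each prediction
    lands in exactly one bin ([lower, upper), last bin closed); empty
    bins are retained with n = 0.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes)
    if p.size == 0 or p.size != y.size:
        raise ValueError("predictions and outcomes must be non-empty and aligned")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lo, hi = float(p.min()), float(p.max())
    if lo == hi:
        warnings.warn("all predictions identical; single degenerate bin",
                      UserWarning, stacklevel=2)
        eps = max(abs(lo) * 1e-9, 1e-9)
        return [CalibrationBin(lo - eps, lo + eps, int(p.size), int(y.sum()))]
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.searchsorted(edges[1:-1], p, side="right")
    return [CalibrationBin(float(edges[b]), float(edges[b + 1]),
                           int(np.sum(idx == b)), int(y[idx == b].sum()))
            for b in range(n_bins)]


def ci75(n_pos: int, n: int, level: float = CI_LEVEL) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion at 75% confidence.

    Wilson is used rather than Wald because calibration bins are small
    and their observed rates often sit near 0 or 1, where the Wald
    interval degenerates.
    """
    if n < 1:
        raise ValueError("CI undefined for n = 0; treat the bin as empty")
    if not 0 <= n_pos <= n:
        raise ValueError("need 0 <= n_pos <= n")
    lo, hi = proportion_confint(n_pos, n, alpha=1.0 - level, method="wilson")
    # snap the exact boundary cases (the score interval is closed there)
    lo = 0.0 if n_pos == 0 else max(float(lo), 0.0)
    hi = 1.0 if n_pos == n else min(float(hi), 1.0)
    return float(lo), float(hi)


def _merge(a: CalibrationBin, b: CalibrationBin) -> CalibrationBin:
    return CalibrationBin(min(a.lower, b.lower), max(a.upper, b.upper),
                          a.n + b.n, a.n_pos + b.n_pos)


def fit_step_calibration(bins: Sequence[CalibrationBin], base_rate: float,
                         cif: str = "") -> CalibrationCurve:
    """Build the step calibration curve from binned held-out predictions.

    Rules, applied in order:

    1. Empty bins are merged (range only) into their nearest non-empty
       neighbor.
    2. While some bin whose CI75 contains the base rate is adjacent to
       another such bin: the two are merged — toward the neighbor whose
       observed rate is closest (ties toward the larger-n neighbor) —
       pooling counts and ranges and recomputing the CI75.  Pooling
       like bins sharpens the interval; a merged bin may end up
       excluding the base rate.
    3. Any remaining bin whose CI75 still contains the base rate gets
       the base rate as its step value; all others get their observed
       rate.

    A curve in which every step equals the base rate is valid — it
    simply flags that the held-out evidence never moves the risk away
    from the base rate.
    """
    if not 0.0 < base_rate < 1.0:
        raise ValueError("base_rate must lie in (0, 1)")
    work = sorted((CalibrationBin(b.lower, b.upper, b.n, b.n_pos) for b in bins),
                  key=lambda b: b.lower)
    if not work or all(b.n == 0 for b in work):
        raise ValueError("need at least one non-empty bin")

    # (1) fold empty bins into the nearest non-empty neighbor's range
    while any(b.n == 0 for b in work):
        i = next(i for i, b in enumerate(work) if b.n == 0)
        neighbors = [j for j in (i - 1, i + 1) if 0 <= j < len(work)]
        neighbors = [j for j in neighbors if work[j].n > 0] or neighbors
        j = neighbors[0]
        work[j] = _merge(work[i], work[j])
        del work[i]

    def contains_base(b: CalibrationBin) -> bool:
        lo, hi = b.ci
        return lo <= base_rate <= hi

    # (2) merge adjacent base-rate-overlapping bins, closest observed first
    while len(work) > 1:
        overlapping = {i for i, b in enumerate(work) if contains_base(b)}
        pair = None
        for i in sorted(overlapping):
            neighbors = [j for j in (i - 1, i + 1)
                         if 0 <= j < len(work) and j in overlapping]
            if neighbors:
                j = min(neighbors,
                        key=lambda j: (abs(work[j].observed - work[i].observed),
                                       -work[j].n))
                pair = (min(i, j), max(i, j))
                break
        if pair is None:
            break
        lo_idx, hi_idx = pair
        work[lo_idx] = _merge(work[lo_idx], work[hi_idx])
        del work[hi_idx]

    # (3) default still-overlapping bins to the base rate
    steps = [((b.lower, b.upper),
              base_rate if contains_base(b) else b.observed) for b in work]
    return CalibrationCurve(steps=steps, base_rate=base_rate, cif=cif)


def apply_calibration(curve: CalibrationCurve, p: float | Sequence[float]):
    """Calibrated probability for raw prediction(s) ``p``.

    Returns the step value of the range containing p; a p on an interior
    edge belongs to the right-hand (higher) step, and predictions
    outside the fitted range clamp to the first/last step.  The output
    always lies within the curve's calibrated prediction range.
    """
    arr = np.atleast_1d(np.asarray(p, dtype=float))
    edges = np.array([lo for (lo, _), _ in curve.steps[1:]])
    values = np.array([v for _, v in curve.steps])
    idx = np.searchsorted(edges, arr, side="right")
    out = values[idx]
    return float(out[0]) if np.isscalar(p) or np.ndim(p) == 0 else out


def plot_calibration(curve: CalibrationCurve, bins: Sequence[CalibrationBin]
                     | None = None, path: str | Path | None = None, ax=None):
    """Step-function calibration plot (observed vs predicted probability)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for (lo, hi), v in curve.steps:
        ax.hlines(v, lo, hi, colors="C0", lw=2)
    ax.axhline(curve.base_rate, ls=":", color="gray", label="base rate")
    if bins:
        for b in bins:
            if b.n:
                mid = 0.5 * (b.lower + b.upper)
                lo_ci, hi_ci = b.ci
                ax.errorbar(mid, b.observed,
                            yerr=[[b.observed - lo_ci], [hi_ci - b.observed]],
                            fmt="o", color="C1", capsize=3)
    ax.set_xlabel("predicted probability")
    ax.set_ylabel("calibrated / observed probability")
    title = f"{curve.cif}: calibrated range Δ={curve.delta:.2f}"
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
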