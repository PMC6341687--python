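"""Compare predicted and empirical restriction-site counts.

Prediction sets spanning several orders of magnitude are compared on a
log10 scale: ordinary least-squares regression of one set on the other
(log-log, for homoscedasticity), and a mean squared error between the
log10 per-base site *frequencies* of two prediction sets, which lands
near zero when the two resources imply near-identical recognition-site
densities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def log_regression(
    x: Sequence[float],
    y: Sequence[float],
    labels: Sequence[str] | None = None,
) -> RegressionResult:
    """OLS of log10(y) on log10(x) with a two-sided slope p-value.

    ``y`` should be the response set (e.g. genome-based predictions) and
    ``x`` the predictor set (e.g. transcriptome-based predictions).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    for arr in (x, y):
        bad = np.flatnonzero(arr <= 0)
        if bad.size:
            name = labels[bad[0]] if labels is not None else f"index {bad[0]}"
            raise ValueError(f"non-positive count for {name}; log transform undefined")
    fit = stats.linregress(np.log10(x), np.log10(y))
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(x),
    )


def prediction_mse(
    freqs_a: Mapping[str, float], freqs_b: Mapping[str, float]
) -> float:
    """Mean over enzymes of squared log10 difference of per-base site
    frequencies between two prediction sets."""
    if set(freqs_a) != set(freqs_b):
        missing = set(freqs_a) ^ set(freqs_b)
        raise ValueError(f"enzyme sets differ: {sorted(missing)}")
    if not freqs_a:
        raise ValueError("empty prediction sets")
    diffs = []
    for enzyme in freqs_a:
        fa, fb = freqs_a[enzyme], freqs_b[enzyme]
        if fa <= 0 or fb <= 0:
            raise ValueError(f"non-positive frequency for enzyme {enzyme}")
        diffs.append((np.log10(fa) - np.log10(fb)) ** 2)
    return float(np.mean(diffs))


def summary_report(
    predictions: Mapping[str, Mapping[str, float]] | None = None,
    insilico_count: float | None = None,
    empirical_counts: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Consolidated summary of predicted and empirical site counts.

    ``predictions`` maps a resource label (e.g. "transcriptome") to
    {model: expected count}; ``empirical_counts`` maps an assembly label
    to its classifier-derived site count.  Empirical entries also report
    a min/max range row.
    """
    rows: list[dict] = []
    for resource, by_model in (predictions or {}).items():
        for model, count in by_model.items():
            rows.append(
                {"method": "prediction", "source": resource, "model": model, "count": count}
            )
    if insilico_count is not None:
        rows.append(
            {"method": "insilico_digest", "source": "genome", "model": "", "count": insilico_count}
        )
    if empirical_counts:
        for label, count in empirical_counts.items():
            rows.append(
                {"method": "mapped_rad_loci", "source": label, "model": "", "count": count}
            )
        values = list(empirical_counts.values())
        rows.append(
            {"method": "mapped_rad_loci_range_min", "source": "all", "model": "",
             "count": min(values)}
        )
        rows.append(
            {"method": "mapped_rad_loci_range_max", "source": "all", "model": "",
             "count": max(values)}
        )
    if not rows:
        raise ValueError("need at least one prediction set or empirical estimate")
    frame = pd.DataFrame(rows, columns=["method", "source", "model", "count"])
    if (frame["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    return frame
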