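"""Model validation and agreement statistics.

Bootstrap model validation fits the candidate linear model on each bootstrap
resample and scores it on the rows *not* drawn into that resample (out-of-bag
rows): this gives an honest, if slightly pessimistic, estimate of predictive
R^2 and RMSE without an external test set.  Bland-Altman analysis quantifies
agreement between measured and model-predicted body composition via the mean
difference and 95% limits of agreement (mean +/- 1.96 SD of the differences).
"""
from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import UsageError
from .selection import _Gram, fit_ols

log = logging.getLogger(__name__)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks).

    Ties receive average ranks.  A constant input has undefined rank
    correlation; NaN is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise UsageError("spearman_rho needs two equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman correlation undefined", RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(scipy.stats.spearmanr(x, y).statistic)


@dataclass
class ValidationResult:
    """Bootstrap out-of-bag validation summary for one linear model."""

    mean_oob_r2: float
    mean_oob_rmse: float
    apparent_r2: float
    apparent_adj_r2: float
    iterations: int
    seed: int | None
    n_redrawn: int = 0
    method: str = "oob"

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def bootstrap_validate(
    exog: pd.DataFrame,
    endog: Sequence[float],
    iterations: int = 2000,
    seed: int | None = None,
    method: str = "oob",
) -> ValidationResult:
    """Bootstrap validation of the linear model ``endog ~ exog``.

    Per iteration, the model is refitted on a bootstrap resample and scored
    either on the out-of-bag rows (``method="oob"``, default) or on the full
    original sample (``method="resample"``).  Out-of-bag R^2 is computed as
    1 - SSE/SST with SST about the out-of-bag mean; it can be negative and
    is reported unclipped.  Iterations with an empty out-of-bag set are
    redrawn.  The apparent (full-data) R^2 and adjusted R^2 are reported
    alongside.
    """
    if iterations < 1:
        raise UsageError("iterations must be >= 1")
    if method not in ("oob", "resample"):
        raise UsageError(f"unknown validation method {method!r}")
    X = pd.DataFrame(exog).astype(float)
    y = np.asarray(endog, dtype=float)
    n = len(y)
    full = fit_ols(X, y) if X.shape[1] else None
    if full is None:
        raise UsageError("validation requires at least one predictor")
    Xn = X.to_numpy()
    design = np.column_stack([np.ones(n), Xn])
    root = np.random.SeedSequence(seed if seed is not None else 0)
    r2s, rmses = [], []
    counter = 0
    n_redrawn = 0
    for _ in range(iterations):
        while True:
            rng = np.random.default_rng(np.random.SeedSequence(root.entropy, spawn_key=(counter,)))
            counter += 1
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
            if method == "oob" and oob.size == 0:
                n_redrawn += 1
                log.debug("empty out-of-bag set; redrawing iteration")
                continue
            gram = _Gram(Xn[idx], y[idx])
            beta = gram.solve(list(range(Xn.shape[1])))
            if beta is None:
                n_redrawn += 1
                continue
            break
        intercept = y[idx].mean() - Xn[idx].mean(axis=0) @ beta
        if method == "oob":
            eval_idx = oob
        else:
            eval_idx = np.arange(n)
        pred = design[eval_idx] @ np.concatenate([[intercept], beta])
        err = y[eval_idx] - pred
        sst = float(np.sum((y[eval_idx] - y[eval_idx].mean()) ** 2))
        sse = float(np.sum(err**2))
        r2s.append(1.0 - sse / sst if sst > 0 else np.nan)
        rmses.append(float(np.sqrt(np.mean(err**2))))
    return ValidationResult(
        mean_oob_r2=float(np.nanmean(r2s)),
        mean_oob_rmse=float(np.mean(rmses)),
        apparent_r2=full.rsquared,
        apparent_adj_r2=full.rsquared_adj,
        iterations=iterations,
        seed=seed,
        n_redrawn=n_redrawn,
        method=method,
    )


@dataclass
class AgreementStats:
    """Bland-Altman agreement between two measurement methods."""

    mean_difference: float
    loa_low: float
    loa_high: float
    proportional_bias_slope: float

    def __iter__(self):
        return iter(
            (self.mean_difference, self.loa_low, self.loa_high, self.proportional_bias_slope)
        )


def bland_altman(measured: Sequence[float], predicted: Sequence[float]) -> AgreementStats:
    """Mean difference, 95% limits of agreement and proportional-bias slope.

    Differences are measured - predicted; the limits are mean(d) +/- 1.96
    SD(d) (the literal 1.96, not a t quantile).  The proportional-bias slope
    is the OLS slope of the differences on the pairwise means.
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape:
        raise UsageError("measured and predicted must have equal length")
    if m.size < 3:
        raise UsageError("Bland-Altman needs at least 3 pairs")
    d = m - p
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    means = (m + p) / 2.0
    if np.ptp(means) == 0:
        slope = 0.0
    else:
        slope = float(np.polyfit(means, d, 1)[0])
    return AgreementStats(
        mean_difference=mean_d,
        loa_low=mean_d - 1.96 * sd_d,
        loa_high=mean_d + 1.96 * sd_d,
        proportional_bias_slope=slope,
    )


def plot_bland_altman(measured, predicted, ax=None):
    """Scatter of differences vs means with the mean and 1.96-SD limit lines."""
    import matplotlib.pyplot as plt

    stats = bland_altman(measured, predicted)
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((m + p) / 2.0, m - p, s=12, alpha=0.6)
    ax.axhline(stats.mean_difference, color="k")
    ax.axhline(stats.loa_low, color="k", linestyle="--")
    ax.axhline(stats.loa_high, color="k", linestyle="--")
    ax.set_xlabel("mean of measured and predicted")
    ax.set_ylabel("measured - predicted")
    return ax
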