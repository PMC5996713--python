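"""Sanity analyses: trial-averaged cross-correlograms and Geweke p-value
distribution summaries.

Lag convention: for channel pair ``(a, b)`` the correlogram value at lag
``k`` is the correlation of ``a`` at time ``t`` with ``b`` at time
``t + k`` — a positive peak lag means ``b`` follows ``a``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from effconn.dataset import Dataset
from effconn.geweke import geweke_index

__all__ = [
    "CrossCorrelogram",
    "PvalueSummary",
    "cross_correlation",
    "cross_correlogram",
    "peak_lag",
    "pvalue_distribution",
]


@dataclass(frozen=True)
class CrossCorrelogram:
    lags: np.ndarray  # ms
    mean_values: np.ndarray
    sd_values: np.ndarray
    pair: tuple[int, int]
    n_examples: int
    normalization: str


@dataclass(frozen=True)
class PvalueSummary:
    scenario_label: str
    pair: tuple[int, int]
    p_values: np.ndarray
    ks_stat: float
    ks_p: float
    log_histogram: tuple[np.ndarray, np.ndarray]  # (counts, bin edges of log10 p)
    n_failed: int


def cross_correlation(
    x: np.ndarray, y: np.ndarray, max_lag: int, normalization: str = "coeff"
) -> np.ndarray:
    """Cross-correlation of two equally sampled series over lags ±max_lag.

    ``coeff`` mean-centers both series and normalizes to correlation
    coefficients in [-1, 1]; ``raw`` averages the plain product.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(x)
    if normalization == "coeff":
        x = x - x.mean()
        y = y - y.mean()
        denom = x.std() * y.std()
        if denom == 0:
            denom = 1.0
    elif normalization == "raw":
        denom = 1.0
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    out = np.empty(2 * max_lag + 1)
    for i, k in enumerate(range(-max_lag, max_lag + 1)):
        if k >= 0:
            v = x[: n - k] @ y[k:] / (n - k)
        else:
            v = x[-k:] @ y[: n + k] / (n + k)
        out[i] = v / denom
    return out


def cross_correlogram(
    dataset: Dataset,
    pair: tuple[int, int],
    max_lag_ms: float = 50.0,
    normalization: str = "coeff",
) -> CrossCorrelogram:
    """Per-example cross-correlation of a channel pair, averaged over examples."""
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    dt = dataset[0].timeseries.sampling_interval
    max_lag = int(round(max_lag_ms / dt))
    rows = np.empty((len(dataset), 2 * max_lag + 1))
    for k, ex in enumerate(dataset):
        if ex.timeseries.sampling_interval != dt:
            raise ValueError("examples have inconsistent sampling intervals")
        rows[k] = cross_correlation(
            ex.timeseries.values[pair[0]], ex.timeseries.values[pair[1]], max_lag, normalization
        )
    lags = np.arange(-max_lag, max_lag + 1) * dt
    return CrossCorrelogram(
        lags=lags,
        mean_values=rows.mean(axis=0),
        sd_values=rows.std(axis=0),
        pair=pair,
        n_examples=len(dataset),
        normalization=normalization,
    )


def peak_lag(correlogram: CrossCorrelogram) -> float:
    """Lag (ms) of the maximum mean value; ties break toward smallest |lag|."""
    vals = correlogram.mean_values
    if np.allclose(vals, vals[0]):
        warnings.warn("flat correlogram: peak lag is degenerate", RuntimeWarning)
    best = vals.max()
    candidates = np.flatnonzero(np.isclose(vals, best, rtol=0, atol=0))
    lags = correlogram.lags[candidates]
    return float(lags[np.argmin(np.abs(lags))])


def pvalue_distribution(
    dataset: Dataset,
    pair: tuple[int, int],
    p: int,
    scenario_label: str = "",
    class_indices: set[int] | None = None,
) -> PvalueSummary:
    """Geweke p-value of ``pair`` (source, target) per example, with a
    Kolmogorov-Smirnov test against Uniform(0, 1).

    ``class_indices`` restricts to examples of the given catalog classes.
    """
    src, tgt = pair
    pvals = []
    n_failed = 0
    for ex in dataset:
        if class_indices is not None and ex.config.class_index not in class_indices:
            continue
        other = 3 - src - tgt
        try:
            res = geweke_index(ex.timeseries.values, tgt, src, other, p)
            pvals.append(res.p_value)
        except (ZeroDivisionError, np.linalg.LinAlgError):
            n_failed += 1
    pvals = np.asarray(pvals)
    if len(pvals) == 0:
        raise ValueError("no examples matched the filter")
    ks_stat, ks_p = stats.kstest(pvals, "uniform")
    logp = np.log10(np.clip(pvals, 1e-300, 1.0))
    counts, edges = np.histogram(logp, bins=30)
    return PvalueSummary(
        scenario_label=scenario_label,
        pair=pair,
        p_values=pvals,
        ks_stat=float(ks_stat),
        ks_p=float(ks_p),
        log_histogram=(counts, edges),
        n_failed=n_failed,
    )
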