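"""Conditional Geweke index of causality in the time domain.

For channels ``(target, source, conditioning)`` the index is the log-ratio
of in-sample residual variances between the reduced lag regression that
omits the source's past and the full regression that includes it.  Scaled
by the usable sample size, the statistic is asymptotically chi-square with
one degree of freedom per excluded lag coefficient under the null of no
causality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "VarFit",
    "GewekeResult",
    "lagged_design",
    "fit_lag_regression",
    "geweke_index",
    "gca_edge_scores",
    "geweke_table",
]


@dataclass(frozen=True)
class VarFit:
    """One least-squares lag regression of a target channel."""

    coefficients: np.ndarray  # (n_channels_included * p,)
    residual_variance: float
    n_obs: int
    p: int
    rank_deficient: bool = False


@dataclass(frozen=True)
class GewekeResult:
    """Conditional causality statistic for one ordered channel pair."""

    F: float
    sigma_full: float
    sigma_reduced: float
    df: int
    scaled_stat: float
    p_value: float


def lagged_design(
    ts: np.ndarray, predictor_channels: tuple[int, ...], target: int, p: int
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix of the ``p`` most recent past values of each predictor.

    Channels are mean-centered first; rows cover ``t = p .. N-1``.  Columns
    are ordered predictor-major, lag 1 first.
    """
    ts = np.asarray(ts, dtype=np.float64)
    M, N = ts.shape
    if N <= p:
        raise ValueError(f"need more than p={p} timepoints, got {N}")
    centered = ts - ts.mean(axis=1, keepdims=True)
    cols = [
        centered[ch, p - lag : N - lag] for ch in predictor_channels for lag in range(1, p + 1)
    ]
    X = np.column_stack(cols) if cols else np.empty((N - p, 0))
    y = centered[target, p:]
    return X, y


def fit_lag_regression(
    ts: np.ndarray, predictor_channels: tuple[int, ...], target: int, p: int
) -> VarFit:
    """Minimum-norm OLS of the target on the predictors' past; in-sample."""
    X, y = lagged_design(ts, predictor_channels, target, p)
    if X.shape[1] == 0:
        resid = y
        coef = np.empty(0)
        rank = 0
    else:
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
    n_obs = len(y)
    return VarFit(
        coefficients=coef,
        residual_variance=float(resid @ resid / n_obs),
        n_obs=n_obs,
        p=p,
        rank_deficient=rank < X.shape[1],
    )


def geweke_index(
    ts: np.ndarray,
    target: int,
    source: int,
    conditioning: int | tuple[int, ...],
    p: int,
) -> GewekeResult:
    """Conditional Geweke index of ``source -> target`` given ``conditioning``.

    Fits the full regression of the target on the past of target, source
    and conditioning channels (lag order ``p``) and the reduced regression
    omitting the source; returns ``F = ln(sigma_reduced / sigma_full)``
    with its chi-square p-value (``df = p`` excluded coefficients,
    ``scaled_stat = n_obs * F``).
    """
    cond = (conditioning,) if isinstance(conditioning, (int, np.integer)) else tuple(conditioning)
    channels = (target, source) + cond
    if len(set(channels)) != len(channels):
        raise ValueError("target, source and conditioning channels must be distinct")
    full = fit_lag_regression(ts, channels, target, p)
    reduced = fit_lag_regression(ts, (target,) + cond, target, p)
    if full.residual_variance <= 0:
        raise ZeroDivisionError(
            "full-model residual variance is zero; Geweke index undefined"
        )
    F = float(np.log(reduced.residual_variance / full.residual_variance))
    scaled = full.n_obs * F
    df = p
    return GewekeResult(
        F=F,
        sigma_full=full.residual_variance,
        sigma_reduced=reduced.residual_variance,
        df=df,
        scaled_stat=scaled,
        p_value=float(stats.chi2.sf(scaled, df)),
    )


def gca_edge_scores(ts: np.ndarray, p: int) -> tuple[np.ndarray, list[GewekeResult]]:
    """Score all six ordered channel pairs of a 3-channel timeseries.

    Edge order is ``(0,1), (0,2), (1,0), (1,2), (2,0), (2,1)`` (source,
    target); each pair conditions on the remaining channel.  The score is
    ``1 - p_value`` so larger means more evidence of causality.
    """
    ts = np.asarray(ts)
    if ts.shape[0] != 3:
        raise ValueError("edge scoring is defined for 3-channel timeseries")
    scores = np.empty(6)
    results = []
    k = 0
    for src in range(3):
        for tgt in range(3):
            if src == tgt:
                continue
            other = 3 - src - tgt
            res = geweke_index(ts, target=tgt, source=src, conditioning=other, p=p)
            scores[k] = 1.0 - res.p_value
            results.append(res)
            k += 1
    return scores, results


def geweke_table(dataset, p: int, csv_path=None) -> list[dict]:
    """One row per (example, ordered pair): F, p_value, df, n_obs.

    Optionally written as CSV to ``csv_path``.
    """
    pairs = [(s, t) for s in range(3) for t in range(3) if s != t]
    rows = []
    for k, ex in enumerate(dataset):
        _, results = gca_edge_scores(ex.timeseries.values, p)
        for (src, tgt), res in zip(pairs, results):
            rows.append(
                {
                    "example": k,
                    "source": src,
                    "target": tgt,
                    "F": res.F,
                    "p_value": res.p_value,
                    "df": res.df,
                    "n_obs": ex.timeseries.n_timepoints - p,
                }
            )
    if csv_path is not None:
        import csv

        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
            writer.writeheader()
            writer.writerows(rows)
    return rows
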