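"""627-dimensional causality feature encoding of a 3-channel timeseries.

Base scores (48): for each effect channel, the in-sample mean squared
error and coefficient of determination of a lag regression under each of
the 7 cause-set scenarios (21 + 21 values), plus 2 conditional Granger
index values per effect (6).  Feature engineering appends the square root
of the absolute value, square and cube of every base score (144) and all
pairwise products within each score family (210 + 210 + 15 = 435), for a
total of 627.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from effconn.geweke import fit_lag_regression, geweke_index

__all__ = [
    "CausalityScenario",
    "FeatureLayout",
    "scenario_list",
    "fit_scenario",
    "conditional_gci",
    "base_scores",
    "encode",
    "N_BASE",
    "N_POWERS",
    "N_PRODUCTS",
    "N_TOTAL",
]

N_SCENARIOS_PER_EFFECT = 7
N_MSE = 21
N_R2 = 21
N_GCI = 6
N_BASE = N_MSE + N_R2 + N_GCI  # 48
N_POWERS = 3 * N_BASE  # 144
N_PRODUCTS = (N_MSE * (N_MSE - 1)) // 2 + (N_R2 * (N_R2 - 1)) // 2 + (N_GCI * (N_GCI - 1)) // 2
N_TOTAL = N_BASE + N_POWERS + N_PRODUCTS  # 627

#: Cap applied to the conditional Granger index when a residual variance
#: degenerates to zero.
GCI_CAP = 1e6


@dataclass(frozen=True)
class CausalityScenario:
    """A candidate explanation: ``causes`` jointly regressed onto ``effect``."""

    effect: int
    causes: tuple[int, ...]


def scenario_list(M: int = 3) -> list[CausalityScenario]:
    """The 21 cause-set scenarios, effect-major.

    For each effect ``e`` with remaining channels ``o1 < o2`` the cause
    sets follow the canonical table order: ``{e}, {o1}, {o2}, {e,o1},
    {e,o2}, {o1,o2}, {e,o1,o2}``.
    """
    if M != 3:
        raise NotImplementedError("the scenario table is defined for M = 3")
    scenarios = []
    for e in range(3):
        o1, o2 = sorted(set(range(3)) - {e})
        for causes in (
            (e,),
            (o1,),
            (o2,),
            (e, o1),
            (e, o2),
            (o1, o2),
            (e, o1, o2),
        ):
            scenarios.append(CausalityScenario(effect=e, causes=causes))
    return scenarios


def fit_scenario(
    ts: np.ndarray, scenario: CausalityScenario, p: int
) -> tuple[float, float]:
    """In-sample (mse, R^2) of regressing the effect on its causes' past.

    The timeseries is mean-centered per channel; no intercept.  A
    rank-deficient design falls back to the minimum-norm solution.
    """
    fit = fit_lag_regression(ts, scenario.causes, scenario.effect, p)
    ts = np.asarray(ts, dtype=np.float64)
    y = ts[scenario.effect, p:] - ts[scenario.effect].mean()
    tss = float(y @ y / len(y))
    mse = fit.residual_variance
    r2 = 1.0 - mse / tss if tss > 0 else 0.0
    return mse, r2


def conditional_gci(
    ts: np.ndarray, effect: int, source: int, conditioning: int, p: int
) -> float:
    """Conditional Granger index of ``source -> effect`` given ``conditioning``.

    Identical estimator to the Geweke module's ``F`` statistic (shared
    code path); capped when the full model interpolates exactly.
    """
    try:
        return geweke_index(ts, effect, source, conditioning, p).F
    except ZeroDivisionError:
        return GCI_CAP


def base_scores(ts: np.ndarray, p: int) -> np.ndarray:
    """The 48 base feature values: 21 mse, 21 R^2, 6 gci, effect-major.

    Channels are z-scored per example first, so the mse family is
    dimensionless and feature vectors are comparable across generators
    with different signal units (R^2 and gci are scale-invariant already).
    """
    ts = np.asarray(ts, dtype=np.float64)
    if ts.shape[0] != 3:
        raise ValueError("feature encoding is defined for 3-channel timeseries")
    sd = ts.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    ts = (ts - ts.mean(axis=1, keepdims=True)) / sd
    scenarios = scenario_list()
    mse_vals = np.empty(N_MSE)
    r2_vals = np.empty(N_R2)
    for k, sc in enumerate(scenarios):
        mse_vals[k], r2_vals[k] = fit_scenario(ts, sc, p)
    gci_vals = np.empty(N_GCI)
    k = 0
    for e in range(3):
        o1, o2 = sorted(set(range(3)) - {e})
        gci_vals[k] = conditional_gci(ts, e, o1, o2, p)
        gci_vals[k + 1] = conditional_gci(ts, e, o2, o1, p)
        k += 2
    return np.concatenate([mse_vals, r2_vals, gci_vals])


def encode(ts: np.ndarray, p: int) -> np.ndarray:
    """Full 627-dimensional feature vector of one 3-channel timeseries."""
    base = base_scores(ts, p)
    powers = np.concatenate([np.sqrt(np.abs(base)), base**2, base**3])
    fams = [base[:N_MSE], base[N_MSE : N_MSE + N_R2], base[N_MSE + N_R2 :]]
    products = np.concatenate(
        [
            np.array([a * b for a, b in itertools.combinations(fam, 2)])
            for fam in fams
        ]
    )
    vec = np.concatenate([base, powers, products])
    assert vec.shape == (N_TOTAL,)
    return vec


@dataclass(frozen=True)
class FeatureLayout:
    """Named index map: feature position -> (family, description)."""

    names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.names)


def feature_layout() -> FeatureLayout:
    """Human-readable names for all 627 positions, in encoding order."""
    scenarios = scenario_list()
    base_names: list[str] = []
    for fam in ("mse", "r2"):
        base_names += [
            f"{fam}[effect={sc.effect},causes={sc.causes}]" for sc in scenarios
        ]
    for e in range(3):
        o1, o2 = sorted(set(range(3)) - {e})
        base_names += [f"gci[{o1}->{e}|{o2}]", f"gci[{o2}->{e}|{o1}]"]
    power_names = [f"sqrt_abs({n})" for n in base_names]
    power_names += [f"square({n})" for n in base_names]
    power_names += [f"cube({n})" for n in base_names]
    fam_slices = {
        "mse": base_names[:N_MSE],
        "r2": base_names[N_MSE : N_MSE + N_R2],
        "gci": base_names[N_MSE + N_R2 :],
    }
    product_names = [
        f"product({a},{b})"
        for fam in ("mse", "r2", "gci")
        for a, b in itertools.combinations(fam_slices[fam], 2)
    ]
    return FeatureLayout(names=tuple(base_names + power_names + product_names))


def encode_dataset(dataset, p: int):
    """Encode every example of a dataset; returns a featurized copy."""
    rows = np.empty((len(dataset), N_TOTAL))
    for k, ex in enumerate(dataset):
        rows[k] = encode(ex.timeseries.values, p)
    return dataset.with_features(rows, p)
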