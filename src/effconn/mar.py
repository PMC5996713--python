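"""Multivariate autoregressive signal/noise mixture generator.

Each example is ``X = (1 - gamma) * Xs + gamma * Xn`` where both components
follow stationary order-``p`` autoregressions with iid standard-normal
innovations: the signal process ``Xs`` has lag matrices supported on the
generating causal configuration (plus own-past diagonals), the noise
process ``Xn`` has diagonal lag matrices.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from effconn.dataset import Dataset, Example, Timeseries
from effconn.graphs import CausalConfiguration, DagCatalog

__all__ = [
    "MarParameters",
    "MarCoefficients",
    "MarGenerationError",
    "sample_coefficients",
    "mar_generate",
    "generate_mar_dataset",
    "companion_spectral_radius",
    "simulate_var",
]


class MarGenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class MarParameters:
    """Generation knobs for the MAR mixture.

    Nonzero signal coefficients are drawn uniformly from
    ``[coeff_noise_low, coeff_noise_high]`` with magnitudes below
    ``coeff_min_magnitude`` redrawn; noise-model diagonals are uniform on
    ``[-an_scale, an_scale]``.  Draws whose companion matrix exceeds
    ``stability_margin`` in spectral radius are rejected up to
    ``max_rejections``; with ``stabilize`` set (the default), a
    still-unstable draw is made stationary exactly by damping lag-``tau``
    matrices with ``s**tau``, which rescales every companion eigenvalue
    by ``s``.
    """

    p: int = 10
    gamma: float = 0.25
    coeff_noise_low: float = -0.6
    coeff_noise_high: float = 0.6
    coeff_min_magnitude: float = 0.1
    an_scale: float = 0.5
    stability_margin: float = 0.95
    max_rejections: int = 50
    stabilize: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.gamma <= 1:
            raise ValueError("gamma must lie in [0, 1]")
        if self.p < 1:
            raise ValueError("model order p must be >= 1")
        if not 0 < self.stability_margin < 1:
            raise ValueError("stability_margin must lie in (0, 1)")
        if self.coeff_noise_low > self.coeff_noise_high:
            raise ValueError("coefficient bounds out of order")


@dataclass(frozen=True)
class MarCoefficients:
    """Per-lag coefficient matrices for the signal and noise processes.

    ``As[tau][i, j]`` weights the influence of channel ``i`` at ``t - tau - 1``
    on channel ``j`` at ``t``; nonzero only where the configuration has
    ``a_ij = 1`` or ``i == j``.  Every ``An[tau]`` is diagonal.
    """

    As: np.ndarray  # (p, M, M)
    An: np.ndarray  # (p, M, M)

    @property
    def p(self) -> int:
        return self.As.shape[0]

    @property
    def M(self) -> int:
        return self.As.shape[1]


def companion_spectral_radius(coeffs: np.ndarray) -> float:
    """Spectral radius of the companion matrix of lag matrices ``(p, M, M)``.

    The process ``x_t = sum_tau coeffs[tau].T @ x_{t-tau-1} + e_t`` is
    stationary iff this is < 1.
    """
    p, M, _ = coeffs.shape
    companion = np.zeros((M * p, M * p))
    for tau in range(p):
        companion[:M, tau * M : (tau + 1) * M] = coeffs[tau].T
    if p > 1:
        companion[M:, : M * (p - 1)] = np.eye(M * (p - 1))
    return float(np.abs(np.linalg.eigvals(companion)).max())


def _stabilize(coeffs: np.ndarray, target_radius: float) -> np.ndarray:
    """Damp lag-``tau`` matrices by ``s**tau`` so the radius becomes ``target``."""
    r = companion_spectral_radius(coeffs)
    if r <= target_radius:
        return coeffs
    s = target_radius / r
    out = coeffs.copy()
    for tau in range(coeffs.shape[0]):
        out[tau] *= s ** (tau + 1)
    return out


def _draw_signal(
    config: CausalConfiguration, params: MarParameters, rng: np.random.Generator
) -> np.ndarray:
    M = config.M
    support = config.A.astype(bool) | np.eye(M, dtype=bool)
    As = np.zeros((params.p, M, M))
    for tau in range(params.p):
        for i in range(M):
            for j in range(M):
                if support[i, j]:
                    v = 0.0
                    while abs(v) < params.coeff_min_magnitude:
                        v = rng.uniform(params.coeff_noise_low, params.coeff_noise_high)
                    As[tau, i, j] = v
    return As


def sample_coefficients(
    config: CausalConfiguration,
    params: MarParameters = MarParameters(),
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> MarCoefficients:
    """Draw stationary signal and noise coefficient matrices for ``config``."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    def draw_until_stationary(draw) -> np.ndarray:
        last = None
        for _ in range(params.max_rejections):
            last = draw()
            if companion_spectral_radius(last) <= params.stability_margin:
                return last
        if params.stabilize:
            return _stabilize(last, params.stability_margin)
        raise MarGenerationError(
            f"no stationary coefficient draw in {params.max_rejections} attempts "
            "(enable stabilize= to damp the final draw)"
        )

    As = draw_until_stationary(lambda: _draw_signal(config, params, rng))

    M = config.M

    def draw_noise() -> np.ndarray:
        An = np.zeros((params.p, M, M))
        idx = np.arange(M)
        for tau in range(params.p):
            An[tau, idx, idx] = rng.uniform(-params.an_scale, params.an_scale, size=M)
        return An

    An = draw_until_stationary(draw_noise)
    return MarCoefficients(As=As, An=An)


def simulate_var(
    coeffs: np.ndarray,
    N: int,
    rng: np.random.Generator,
    burn_in: int,
) -> np.ndarray:
    """Simulate ``x_t = sum_tau coeffs[tau].T x_{t-tau-1} + e_t`` -> (M, N)."""
    p, M, _ = coeffs.shape
    total = N + burn_in + p
    x = np.zeros((total, M))
    eps = rng.standard_normal((total, M))
    At = coeffs.transpose(0, 2, 1)  # At[tau] maps x_{t-tau-1} -> x_t
    for t in range(p, total):
        acc = eps[t].copy()
        for tau in range(p):
            acc += At[tau] @ x[t - tau - 1]
        x[t] = acc
    out = x[p + burn_in :].T
    if not np.isfinite(out).all():
        raise MarGenerationError("non-finite values in simulated autoregression")
    return out


def mar_generate(
    config: CausalConfiguration,
    params: MarParameters = MarParameters(),
    N: int = 6000,
    seed: int | np.random.SeedSequence = 0,
    coeffs: MarCoefficients | None = None,
    return_components: bool = False,
):
    """Generate one mixed MAR timeseries of shape ``(M, N)``.

    Simulates the signal and noise recursions with independent innovations,
    discards a burn-in of ``10 * p`` steps, and mixes the retained parts as
    ``(1 - gamma) * Xs + gamma * Xn``.
    """
    if N <= params.p:
        raise ValueError(f"need N > p, got N={N}, p={params.p}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_coef, ss_s, ss_n = ss.spawn(3)
    if coeffs is None:
        coeffs = sample_coefficients(config, params, np.random.default_rng(ss_coef))
    burn_in = 10 * params.p
    xs = simulate_var(coeffs.As, N, np.random.default_rng(ss_s), burn_in)
    xn = simulate_var(coeffs.An, N, np.random.default_rng(ss_n), burn_in)
    x = (1.0 - params.gamma) * xs + params.gamma * xn
    names = tuple("XYZW"[c] if c < 4 else f"C{c}" for c in range(config.M))
    ts = Timeseries(values=x, sampling_interval=1.0, channel_names=names)
    if return_components:
        return ts, coeffs, xs, xn
    return ts, coeffs


def generate_mar_dataset(
    catalog: DagCatalog,
    n_per_config: int,
    params: MarParameters = MarParameters(),
    N: int = 6000,
    seed: int = 0,
) -> Dataset:
    """Balanced MAR dataset with fresh coefficients per example."""
    if n_per_config < 1:
        raise ValueError("n_per_config must be >= 1")
    examples = []
    for config in catalog:
        for rep in range(n_per_config):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(config.class_index, rep))
            ts, coeffs = mar_generate(config, params, N, seed=ss)
            meta = {
                "generator": "MAR",
                "master_seed": int(seed),
                "class_index": int(config.class_index),
                "replicate": int(rep),
                "signal_radius": companion_spectral_radius(coeffs.As),
                "noise_radius": companion_spectral_radius(coeffs.An),
            }
            examples.append(Example(ts, config, meta))
    metadata = {
        "generator": "MAR",
        "master_seed": int(seed),
        "n_per_config": int(n_per_config),
        "N": int(N),
        "params": dataclasses.asdict(params),
        "catalog_ordering": catalog.ordering_rule,
    }
    return Dataset(examples, "MAR", catalog, metadata)
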