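"""Simulation of hierarchical survival data with a discrete shared frailty.

Event times are generated by inverse-transform sampling: with survival
``S(t | w, x) = exp(-Lambda0(t) w e^{x'beta})`` and U ~ Uniform(0,1),
``T* = Lambda0^{-1}( -log U / (w e^{x'beta}) )``.  The default cumulative
baseline is the Weibull-type curve ``Lambda0^{-1}(s) = 0.01 * s^1.9``, i.e.
``Lambda0(t) = (100 t)^{1/1.9}``, and the default study design is J = 100
groups of n_j = 50 subjects, one standard-normal covariate with log-hazard
ratio 0.4, and no censoring.  The true latent labels are returned alongside
the dataset so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import brentq

from .data_model import SurvivalDataset, ValidationError

__all__ = ["SimulationConfig", "simulate_dataset", "scenario_grid"]


@dataclass
class SimulationConfig:
    """Generating truth for one simulated dataset.

    ``baseline_c`` and ``baseline_d`` parameterize the inverse cumulative
    baseline ``Lambda0^{-1}(s) = c * s^d``; ``w`` holds the frailty support
    points (ratios to the first entry are what estimation can recover);
    ``censoring`` is ``None`` (all events observed), ``("administrative",
    tau)`` (censor at fixed time tau) or ``("exponential", fraction)``
    (exponential censoring with rate tuned to a target censoring fraction).
    ``round_times`` optionally rounds times to that many decimals to create
    ties.
    """

    J: int = 100
    n_j: Union[int, Sequence[int]] = 50
    K: int = 2
    pi: Sequence[float] = (0.5, 0.5)
    w: Sequence[float] = (1.0, 1.55)
    beta: Sequence[float] = (0.4,)
    baseline_c: float = 0.01
    baseline_d: float = 1.9
    covariates: Union[str, Callable] = "normal"  # "normal", "bernoulli:<p>", callable
    censoring: Optional[Tuple[str, float]] = None
    round_times: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        w = np.asarray(self.w, dtype=float)
        if pi.shape != (self.K,) or w.shape != (self.K,):
            raise ValidationError("pi and w must have length K")
        if abs(pi.sum() - 1.0) > 1e-10 or np.any(pi < 0):
            raise ValidationError("pi must be a probability vector")
        if np.any(w <= 0) or self.baseline_c <= 0 or self.baseline_d <= 0:
            raise ValidationError("w and baseline parameters must be positive")
        nj = np.asarray(self.n_j)
        if np.any(nj < 1) or self.J < 1:
            raise ValidationError("J and every n_j must be >= 1")

    @property
    def group_sizes(self) -> np.ndarray:
        nj = np.asarray(self.n_j, dtype=int)
        if nj.ndim == 0:
            return np.full(self.J, int(nj))
        if nj.shape != (self.J,):
            raise ValidationError("vector n_j must have length J")
        return nj

    def inverse_cumhaz(self, s: np.ndarray) -> np.ndarray:
        return self.baseline_c * np.asarray(s, dtype=float) ** self.baseline_d

    def cumhaz(self, t: np.ndarray) -> np.ndarray:
        return (np.asarray(t, dtype=float) / self.baseline_c) ** (1.0 / self.baseline_d)

    def to_flat(self) -> dict:
        """Flat key=value representation for config echo files."""
        out = {}
        for key, val in self.__dict__.items():
            if isinstance(val, (tuple, list, np.ndarray)):
                out[key] = ",".join(f"{v:.10g}" for v in np.asarray(val, float).ravel())
            else:
                out[key] = val
        return out


def _draw_covariates(config: SimulationConfig, n: int, rng: np.random.Generator):
    spec = config.covariates
    if callable(spec):
        X = np.asarray(spec(n, rng), dtype=float)
        return X.reshape(n, -1)
    if spec == "normal":
        return rng.standard_normal((n, len(np.atleast_1d(config.beta))))
    if isinstance(spec, str) and spec.startswith("bernoulli"):
        prob = float(spec.split(":", 1)[1]) if ":" in spec else 0.5
        return rng.binomial(1, prob, size=(n, len(np.atleast_1d(config.beta)))).astype(float)
    raise ValidationError(f"unknown covariate spec {spec!r}")


def _apply_censoring(
    config: SimulationConfig, t_star: np.ndarray, rng: np.random.Generator
):
    if config.censoring is None:
        return t_star, np.ones(t_star.size, dtype=int)
    kind, value = config.censoring
    if kind == "administrative":
        c = np.full(t_star.size, float(value))
    elif kind == "exponential":
        target = float(value)
        if not 0 < target < 1:
            raise ValidationError("target censoring fraction must be in (0, 1)")
        # E[P(C < t*)] = mean(1 - exp(-r t*)) is increasing in the rate r
        def frac(log_r):
            return np.mean(1.0 - np.exp(-np.exp(log_r) * t_star)) - target

        log_rate = brentq(frac, -30, 30)
        c = rng.exponential(1.0 / np.exp(log_rate), size=t_star.size)
    else:
        raise ValidationError(f"unknown censoring spec {config.censoring!r}")
    status = (t_star <= c).astype(int)
    return np.minimum(t_star, c), status


def simulate_dataset(
    config: SimulationConfig,
) -> Tuple[SurvivalDataset, np.ndarray]:
    """Generate one dataset and its true group-level latent labels.

    Fully reproducible from ``config.seed``: the same config yields a
    bit-identical dataset.
    """
    rng = np.random.default_rng(config.seed)
    pi = np.asarray(config.pi, dtype=float)
    w = np.asarray(config.w, dtype=float)
    beta = np.asarray(config.beta, dtype=float).reshape(-1)
    if np.any(pi == 0):
        import warnings

        warnings.warn("some pi_k = 0: those populations are never drawn", stacklevel=2)
    sizes = config.group_sizes
    n = int(sizes.sum())
    labels = rng.choice(config.K, size=config.J, p=pi)
    group_idx = np.repeat(np.arange(config.J), sizes)
    X = _draw_covariates(config, n, rng)
    eta = X @ beta if beta.size else np.zeros(n)
    u = rng.uniform(size=n)
    t_star = config.inverse_cumhaz(-np.log(u) / (w[labels][group_idx] * np.exp(eta)))
    time, status = _apply_censoring(config, t_star, rng)
    if config.round_times is not None:
        time = np.round(time, config.round_times)
        time = np.maximum(time, 10.0 ** (-config.round_times))  # keep times positive
    data = SurvivalDataset(
        time=time,
        status=status,
        covariates=X,
        group_idx=group_idx,
        group_labels=np.arange(config.J),
    )
    return data, labels


# ---------------------------------------------------------------------------
# Canonical simulation scenarios
# ---------------------------------------------------------------------------

_SCENARIO_IV = {
    1: ((1.0,), (1.0,)),
    2: ((0.4, 0.6), (1.0, 1.5)),
    3: ((0.2, 0.3, 0.5), (1.0, 1.5, 2.5)),
    4: ((0.15, 0.25, 0.3, 0.3), (1.0, 1.5, 2.5, 4.0)),
}


def scenario_grid(name: str) -> list:
    """Configurations for the four canonical simulation studies.

    (i)   K=2, w2/w1 = 1.55, pi_1 in {0.1, ..., 0.9}, J=100, n_j=50;
    (ii)  as (i) with n_j = 35;
    (iii) K=2, pi = (0.3, 0.7), w2/w1 in {1.14, 1.29, 1.43, 1.57, 1.71, 2, 3};
    (iv)  K in {1..4} with matched pi and w/w1 grids.
    """
    base = SimulationConfig()
    if name == "i":
        return [
            replace(base, pi=(round(p1, 1), round(1 - p1, 1)))
            for p1 in np.arange(0.1, 0.95, 0.1)
        ]
    if name == "ii":
        return [replace(cfg, n_j=35) for cfg in scenario_grid("i")]
    if name == "iii":
        return [
            replace(base, pi=(0.3, 0.7), w=(1.0, r))
            for r in (1.14, 1.29, 1.43, 1.57, 1.71, 2.0, 3.0)
        ]
    if name == "iv":
        return [
            replace(base, K=k, pi=pi, w=w) for k, (pi, w) in sorted(_SCENARIO_IV.items())
        ]
    raise ValidationError(f"unknown scenario {name!r}; choose one of i, ii, iii, iv")
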