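"""Tailored EM algorithm for the discrete-frailty Cox model.

One EM iteration, starting from the current posterior membership matrix
``alpha`` (E-step output), performs

1. ``pi`` update: column means of ``alpha`` (Lagrange-multiplier solution of
   the constrained mixing-proportion maximization);
2. ``w`` update: closed-form ratio of weighted event totals to weighted
   cumulative-hazard exposure, at the current baseline and beta;
3. ``beta`` update: Newton maximization of the profile partial
   log-likelihood, a Cox partial likelihood with known per-subject offset
   ``sum_k alpha[group, k] * w_k`` (Breslow tie handling);
4. baseline update: weighted Breslow estimator with the same offsets at the
   new beta — the conditional maximizer profiled out in step 3;
5. E-step at the new parameters.

Steps 2-4 jointly never decrease the expected complete-data objective, so the
observable log-likelihood is non-decreasing across iterations (generalized
EM).  The w are left unconstrained during iteration — the scale is shared
with the baseline and only ratios are identified — and normalized ratios
``w / min(w)`` are reported post hoc.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from scipy.special import logsumexp

from .data_model import (
    EventTable,
    FitResult,
    FrailtyParams,
    MembershipPosterior,
    StepBaseline,
    SurvivalDataset,
    ValidationError,
    build_event_table,
)
from .likelihoods import observable_loglik

__all__ = [
    "EMControl",
    "MonotoneLikelihoodWarning",
    "OptimizerError",
    "e_step",
    "m_step_pi",
    "m_step_w",
    "breslow_baseline",
    "profile_partial_loglik",
    "maximize_beta",
    "fit_em",
]

logger = logging.getLogger("frailtymix")

_DEGENERATE_MASS = 1e-8


class MonotoneLikelihoodWarning(UserWarning):
    """The partial likelihood is monotone in beta (estimate diverges)."""


class OptimizerError(RuntimeError):
    """Newton maximization of the profile partial likelihood failed."""


@dataclass
class EMControl:
    """Tuning knobs for :func:`fit_em`.

    ``tol_loglik`` and ``tol_params`` must *both* be met for convergence: the
    observable log-likelihood can plateau while (w, baseline) still drift
    along their shared scale direction, so a parameter-change criterion is
    required as well.
    """

    max_iter: int = 200
    tol_loglik: float = 1e-6
    tol_params: float = 1e-5
    n_restarts: int = 5
    seed: Optional[int] = None
    inner_mstep_cycles: int = 1
    init: str = "random"  # "random" or "na_quantile"

    def __post_init__(self) -> None:
        if self.max_iter < 1 or self.n_restarts < 1:
            raise ValidationError("max_iter and n_restarts must be >= 1")
        if self.tol_loglik <= 0 or self.tol_params <= 0:
            raise ValidationError("tolerances must be positive")


# ---------------------------------------------------------------------------
# E-step
# ---------------------------------------------------------------------------


def _group_exposure(
    data: SurvivalDataset, baseline: StepBaseline, beta: np.ndarray
) -> np.ndarray:
    """A_j = sum_i Lambda0(t_ij) exp(X_ij' beta), the unit-frailty exposure."""
    eta = data.covariates @ beta if data.p else np.zeros(data.n)
    lam = baseline.cumhaz(data.time)
    return np.bincount(data.group_idx, weights=lam * np.exp(eta), minlength=data.J)


def e_step(data: SurvivalDataset, params: FrailtyParams) -> MembershipPosterior:
    """Closed-form posterior membership probabilities (Bayes' theorem).

    ``alpha[j, k]`` is proportional to ``pi_k * w_k**D_j * exp(-w_k A_j)``
    with ``A_j`` the group's unit-frailty cumulative-hazard exposure; rows
    are normalized in log space for stability.
    """
    if np.any(params.w <= 0):
        raise ValidationError("frailty support points must be positive")
    A = _group_exposure(data, params.baseline, params.beta)
    D = data.D_j
    with np.errstate(divide="ignore"):
        log_num = (
            np.log(params.pi)[None, :]
            + D[:, None] * np.log(params.w)[None, :]
            - A[:, None] * params.w[None, :]
        )
    alpha = np.exp(log_num - logsumexp(log_num, axis=1, keepdims=True))
    return MembershipPosterior(alpha)


# ---------------------------------------------------------------------------
# M-step pieces
# ---------------------------------------------------------------------------


def m_step_pi(alpha: MembershipPosterior) -> np.ndarray:
    """Mixing-proportion update: column means of alpha."""
    if alpha.alpha.size == 0:
        raise ValidationError("empty membership matrix")
    return alpha.alpha.mean(axis=0)


def m_step_w(
    data: SurvivalDataset,
    alpha: MembershipPosterior,
    baseline: StepBaseline,
    beta: np.ndarray,
) -> np.ndarray:
    """Closed-form frailty update at the current baseline and beta.

    ``w_k = (sum_j alpha_jk D_j) / (sum_j alpha_jk A_j)`` — weighted events
    over weighted exposure for each latent population.
    """
    A = _group_exposure(data, baseline, beta)
    num = alpha.alpha.T @ data.D_j.astype(float)
    den = alpha.alpha.T @ A
    if np.any(den <= 0):
        raise ValidationError(
            "degenerate latent population: zero weighted exposure in the w update"
        )
    return num / den


def _breslow_denominators(
    data: SurvivalDataset,
    event_table: EventTable,
    offset: np.ndarray,
    beta: np.ndarray,
) -> np.ndarray:
    """Risk-set denominators ``sum_{rs in R(t_m)} offset_s exp(X_rs' beta)``."""
    eta = data.covariates @ beta if data.p else np.zeros(data.n)
    r = offset * np.exp(eta - eta.max())
    rs = r[event_table.order]
    suffix = np.cumsum(rs[::-1])[::-1]
    return suffix[event_table.risk_start] * np.exp(eta.max())


def breslow_baseline(
    event_table: EventTable,
    data: SurvivalDataset,
    alpha: MembershipPosterior,
    w: np.ndarray,
    beta: np.ndarray,
) -> StepBaseline:
    """Weighted Breslow estimator of the cumulative baseline hazard.

    Jump at each distinct event time t_m is ``d_m`` divided by the risk-set
    sum of ``(sum_k alpha_sk w_k) exp(X_rs' beta)``, i.e. each subject is
    weighted by its own group's expected frailty.
    """
    offset = (alpha.alpha @ w)[data.group_idx]
    den = _breslow_denominators(data, event_table, offset, beta)
    return StepBaseline(event_table.distinct_event_times, event_table.tie_counts / den)


# ---------------------------------------------------------------------------
# Profile partial likelihood in beta
# ---------------------------------------------------------------------------


def profile_partial_loglik(
    beta: np.ndarray,
    data: SurvivalDataset,
    event_table: EventTable,
    offset: np.ndarray,
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Cox partial log-likelihood with known multiplicative offsets.

    Returns ``(value, gradient, hessian)``.  Breslow tie handling: the value
    is ``sum_events [X'beta] - sum_m d_m log S0(t_m)`` where ``S0`` sums
    ``offset * exp(X'beta)`` over the risk set.  The offset of a subject is
    its group's expected frailty ``sum_k alpha_sk w_k``; with unit offsets
    this is exactly the standard Cox partial log-likelihood.
    """
    beta = np.asarray(beta, dtype=float).reshape(-1)
    offset = np.asarray(offset, dtype=float)
    if np.any(offset <= 0):
        raise ValidationError("offsets must be positive")
    p = data.p
    eta = data.covariates @ beta if p else np.zeros(data.n)
    shift = eta.max()
    r = offset * np.exp(eta - shift)
    order = event_table.order
    rs = r[order]
    Xs = data.covariates[order]
    d = event_table.tie_counts.astype(float)
    start = event_table.risk_start

    S0 = np.cumsum(rs[::-1])[::-1][start]
    log_S0 = np.log(S0) + shift

    events = data.status == 1
    value = float(eta[events].sum() - d @ log_S0)
    if p == 0:
        return value, np.zeros(0), np.zeros((0, 0))

    S1 = np.cumsum((rs[:, None] * Xs)[::-1], axis=0)[::-1][start]
    S2 = np.cumsum((rs[:, None, None] * Xs[:, :, None] * Xs[:, None, :])[::-1], axis=0)[
        ::-1
    ][start]
    Xbar = S1 / S0[:, None]
    grad = data.covariates[events].sum(axis=0) - d @ Xbar
    hess = -np.einsum("m,mab->ab", d, S2 / S0[:, None, None]) + np.einsum(
        "m,ma,mb->ab", d, Xbar, Xbar
    )
    return value, grad, hess


def _warn_if_diverging(beta: np.ndarray, bound: float = 10.0) -> None:
    if np.linalg.norm(beta) > bound:
        warnings.warn(
            "beta estimate very large: the partial likelihood appears monotone "
            "(e.g. a covariate level with no events)",
            MonotoneLikelihoodWarning,
            stacklevel=3,
        )


def maximize_beta(
    data: SurvivalDataset,
    event_table: EventTable,
    offset: np.ndarray,
    beta_init: np.ndarray,
    grad_tol: float = 1e-8,
    max_newton: int = 50,
) -> np.ndarray:
    """Newton maximization (with step halving) of the profile partial likelihood."""
    beta = np.asarray(beta_init, dtype=float).reshape(-1)
    if data.p == 0:
        return beta
    value, grad, hess = profile_partial_loglik(beta, data, event_table, offset)
    if not np.isfinite(value):
        raise OptimizerError("profile partial likelihood not finite at beta_init")
    for _ in range(max_newton):
        if np.max(np.abs(grad)) < grad_tol:
            _warn_if_diverging(beta)
            return beta
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            step = None
        if step is None or grad @ step <= 0:
            # fall back to a scaled ascent step
            step = grad / max(np.max(np.abs(np.diag(hess))), 1.0)
        pred = float(grad @ step)
        if pred < 1e-9:
            # predicted gain below the float resolution of the objective:
            # take the pure Newton step (locally contracting) and stop
            beta = beta + step
            _, grad, _ = profile_partial_loglik(beta, data, event_table, offset)
            _warn_if_diverging(beta)
            return beta
        # step halving: accept only (numerically) non-decreasing moves
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            v, g, h = profile_partial_loglik(cand, data, event_table, offset)
            if np.isfinite(v) and v >= value - 5e-9:
                break
            scale *= 0.5
        else:
            raise OptimizerError("step halving failed to find an ascent step")
        beta, value, grad, hess = cand, v, g, h
        if np.linalg.norm(beta) > 50:
            _warn_if_diverging(beta)
            return beta
    raise OptimizerError(
        f"Newton did not converge in {max_newton} steps (|grad|={np.max(np.abs(grad)):.2e})"
    )


# ---------------------------------------------------------------------------
# Full EM
# ---------------------------------------------------------------------------


def _initial_alpha_random(J: int, K: int, rng: np.random.Generator) -> np.ndarray:
    labels = rng.integers(0, K, size=J)
    alpha = np.zeros((J, K))
    alpha[np.arange(J), labels] = 1.0
    return alpha


def _initial_alpha_quantile(data: SurvivalDataset, K: int) -> np.ndarray:
    """Deterministic start: K quantile blocks of per-group Nelson-Aalen
    cumulative hazard evaluated at the median follow-up time."""
    t_med = float(np.median(data.time))
    na = np.zeros(data.J)
    for j in range(data.J):
        sel = data.group_idx == j
        tj, dj = data.time[sel], data.status[sel]
        ev = np.unique(tj[dj == 1])
        ev = ev[ev <= t_med]
        for t in ev:
            na[j] += (dj[tj == t] == 1).sum() / (tj >= t).sum()
    ranks = np.argsort(np.argsort(na, kind="stable"), kind="stable")
    labels = np.minimum((ranks * K) // data.J, K - 1)
    alpha = np.zeros((data.J, K))
    alpha[np.arange(data.J), labels] = 1.0
    return alpha


def _em_single(
    data: SurvivalDataset,
    event_table: EventTable,
    K: int,
    alpha0: np.ndarray,
    control: EMControl,
) -> dict:
    alpha = MembershipPosterior(alpha0)
    beta = np.zeros(data.p)
    w = np.ones(K)
    baseline = breslow_baseline(event_table, data, alpha, w, beta)
    ll_prev = -np.inf
    theta_prev = None
    ll_path = []
    converged = False
    degenerate = False
    n_iter = 0
    for it in range(1, control.max_iter + 1):
        n_iter = it
        pi = m_step_pi(alpha)
        for _ in range(control.inner_mstep_cycles):
            mass = alpha.alpha.sum(axis=0)
            if np.any(mass < _DEGENERATE_MASS):
                degenerate = True
                # freeze w for empty populations; update the rest
                try:
                    w_new = m_step_w(data, alpha, baseline, beta)
                except ValidationError:
                    w_new = w.copy()
                keep = mass >= _DEGENERATE_MASS
                w = np.where(keep, w_new, w)
            else:
                w = m_step_w(data, alpha, baseline, beta)
            offset = (alpha.alpha @ w)[data.group_idx]
            beta = maximize_beta(data, event_table, offset, beta)
            baseline = breslow_baseline(event_table, data, alpha, w, beta)
        params = FrailtyParams(pi=pi, w=w, beta=beta, baseline=baseline)
        ll = observable_loglik(data, params)
        ll_path.append(ll)
        theta = np.concatenate([pi, w, beta])
        if theta_prev is not None:
            if (
                abs(ll - ll_prev) < control.tol_loglik
                and np.max(np.abs(theta - theta_prev)) < control.tol_params
            ):
                converged = True
                break
        ll_prev, theta_prev = ll, theta
        alpha = e_step(data, params)
    # final E-step so alpha is consistent with the returned parameters
    alpha = e_step(data, params)
    if np.any(alpha.alpha.sum(axis=0) < _DEGENERATE_MASS):
        degenerate = True
    return {
        "params": params,
        "alpha": alpha,
        "loglik": ll,
        "n_iter": n_iter,
        "converged": converged,
        "degenerate": degenerate,
        "ll_path": np.asarray(ll_path),
    }


def fit_em(
    data: SurvivalDataset,
    K: int,
    control: Optional[EMControl] = None,
    init: Optional[Union[FrailtyParams, np.ndarray, MembershipPosterior]] = None,
) -> FitResult:
    """Fit the discrete-frailty Cox model with K latent populations by EM.

    Runs ``control.n_restarts`` random hard-assignment initializations (plus
    the supplied ``init``, if any) and returns the restart with the highest
    observable log-likelihood.  Populations in the result are relabeled in
    ascending order of the frailty support points and ``frailty_ratios``
    reports ``w / min(w)``.
    """
    control = control or EMControl()
    if K < 1:
        raise ValidationError("K must be >= 1")
    if K > data.J:
        raise ValidationError(f"K={K} exceeds the number of groups J={data.J}")
    event_table = build_event_table(data)

    starts = []
    if init is not None:
        if isinstance(init, FrailtyParams):
            starts.append(e_step(data, init).alpha)
        elif isinstance(init, MembershipPosterior):
            starts.append(init.alpha)
        else:
            starts.append(MembershipPosterior(np.asarray(init, dtype=float)).alpha)
    if K == 1:
        starts = [np.ones((data.J, 1))]
    elif not starts:
        if control.init == "na_quantile":
            starts.append(_initial_alpha_quantile(data, K))
        seq = np.random.SeedSequence(control.seed)
        n_random = max(control.n_restarts - len(starts), 0)
        for child in seq.spawn(n_random):
            starts.append(_initial_alpha_random(data.J, K, np.random.default_rng(child)))

    best = None
    restart_lls = []
    for i, alpha0 in enumerate(starts):
        run = _em_single(data, event_table, K, alpha0, control)
        restart_lls.append(run["loglik"])
        logger.debug(
            "restart %d: loglik=%.6f iters=%d converged=%s degenerate=%s",
            i, run["loglik"], run["n_iter"], run["converged"], run["degenerate"],
        )
        if best is None or run["loglik"] > best["loglik"]:
            best = run

    params, alpha = best["params"], best["alpha"]
    order = np.argsort(params.w, kind="stable")
    params = FrailtyParams(
        pi=params.pi[order], w=params.w[order], beta=params.beta,
        baseline=params.baseline,
    )
    alpha = MembershipPosterior(alpha.alpha[:, order])
    return FitResult(
        params=params,
        alpha=alpha,
        loglik=best["loglik"],
        n_iter=best["n_iter"],
        converged=best["converged"],
        frailty_ratios=params.w / params.w.min(),
        assignments=np.argmax(alpha.alpha, axis=1),
        degenerate=best["degenerate"],
        loglik_path=best["ll_path"],
        restart_logliks=np.asarray(restart_lls),
    )
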