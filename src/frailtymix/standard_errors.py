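"""Observed-information standard errors for the discrete-frailty Cox model.

Three estimators of the observed information matrix are provided, all over
the same free-parameter vector

    theta_free = (pi_1..pi_{K-1}, w_1..w_K, beta_1..beta_p, lam_1..lam_M)

with ``pi_K = 1 - sum`` and ``lam_m`` the baseline jump heights:

* ``information_exact``  — analytic negative Hessian of the observable
  (marginal) log-likelihood, assembled blockwise;
* ``information_louis``  — per-group Louis decomposition
  ``I^j = E[B_j] - E[S_j S_j'] + S*_j S*_j'`` with the expectation over the
  latent memberships taken under the posterior alpha;
* ``information_numeric`` — central finite differences of the observable
  log-likelihood with one step of Richardson extrapolation.

The joint matrix has one flat direction (multiplying all w by c and the
baseline by 1/c leaves the likelihood unchanged); before inversion
:func:`se_report` removes it either by fixing the total cumulative baseline
at its fitted value (default) or by fixing w_1.  Variances of the reported
frailty ratios ``w_k / w_1`` come from the second-order Taylor (delta-method)
formula in :func:`ratio_variance`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .data_model import (
    BaselineInconsistencyError,
    FitResult,
    FrailtyParams,
    MembershipPosterior,
    SurvivalDataset,
    ValidationError,
    build_event_table,
)
from .em_core import e_step

__all__ = [
    "SEReport",
    "information_exact",
    "information_louis",
    "information_numeric",
    "ratio_variance",
    "se_report",
]


# ---------------------------------------------------------------------------
# Free-parameter bookkeeping and shared sufficient pieces
# ---------------------------------------------------------------------------


class _FreeIndex:
    """Coordinate layout of the free-parameter vector."""

    def __init__(self, K: int, p: int, M: int):
        self.K, self.p, self.M = K, p, M
        self.n_pi = K - 1
        self.pi = slice(0, self.n_pi)
        self.w = slice(self.n_pi, self.n_pi + K)
        self.beta = slice(self.n_pi + K, self.n_pi + K + p)
        self.lam = slice(self.n_pi + K + p, self.n_pi + K + p + M)
        self.dim = self.n_pi + K + p + M

    def pack(self, params: FrailtyParams) -> np.ndarray:
        return np.concatenate(
            [params.pi[:-1], params.w, params.beta, params.baseline.jumps]
        )


class _Pieces:
    """Per-group sufficient statistics entering all information formulas."""

    def __init__(self, data: SurvivalDataset, params: FrailtyParams):
        et = build_event_table(data)
        times = et.distinct_event_times
        if not np.array_equal(times, params.baseline.times):
            raise BaselineInconsistencyError(
                "baseline jump times must coincide with the data's distinct event times"
            )
        J, p, M = data.J, data.p, times.size
        self.idx = _FreeIndex(params.K, p, M)
        self.et = et
        eta = data.covariates @ params.beta if p else np.zeros(data.n)
        exp_eta = np.exp(eta)
        Lam = params.baseline.cumhaz(data.time)
        g = data.group_idx
        X = data.covariates

        self.D = data.D_j.astype(float)
        self.d = et.tie_counts.astype(float)
        self.A = np.bincount(g, weights=Lam * exp_eta, minlength=J)
        self.a = np.zeros((J, p))
        self.C = np.zeros((J, p, p))
        self.b = np.zeros((J, p))
        wgt = Lam * exp_eta
        for q in range(p):
            self.a[:, q] = np.bincount(g, weights=wgt * X[:, q], minlength=J)
            self.b[:, q] = np.bincount(g, weights=data.status * X[:, q], minlength=J)
            for r in range(q, p):
                self.C[:, q, r] = np.bincount(
                    g, weights=wgt * X[:, q] * X[:, r], minlength=J
                )
                self.C[:, r, q] = self.C[:, q, r]

        # events of group j at distinct time m
        ev = data.status == 1
        m_of_event = np.searchsorted(times, data.time[ev])
        self.d_jm = np.zeros((J, M))
        np.add.at(self.d_jm, (g[ev], m_of_event), 1.0)

        # R[j, m]  = sum_{i in j: t_i >= t_m} exp(eta_i)
        # RX[j, m] = same weighted by X (per covariate)
        c_i = np.searchsorted(times, data.time, side="right")
        G = np.zeros((J, M + 1))
        np.add.at(G, (g, c_i), exp_eta)
        self.R = G[:, 1:][:, ::-1].cumsum(axis=1)[:, ::-1]
        self.RX = np.zeros((J, M, p))
        for q in range(p):
            Gq = np.zeros((J, M + 1))
            np.add.at(Gq, (g, c_i), exp_eta * X[:, q])
            self.RX[:, :, q] = Gq[:, 1:][:, ::-1].cumsum(axis=1)[:, ::-1]


def _u_matrix(pieces: _Pieces, params: FrailtyParams) -> np.ndarray:
    """First derivatives u[j, k, :] of h_jk = log pi_k + D_j log w_k - w_k A_j
    with respect to the free parameters."""
    idx = pieces.idx
    J, K = pieces.A.shape[0], params.K
    U = np.zeros((J, K, idx.dim))
    for k in range(K):
        if k < K - 1:
            U[:, k, idx.pi.start + k] = 1.0 / params.pi[k]
        else:
            U[:, k, idx.pi] = -1.0 / params.pi[-1] if K > 1 else 0.0
        U[:, k, idx.w.start + k] = pieces.D / params.w[k] - pieces.A
        if idx.p:
            U[:, k, idx.beta] = -params.w[k] * pieces.a
        U[:, k, idx.lam] = -params.w[k] * pieces.R
    return U


def information_exact(data: SurvivalDataset, params: FrailtyParams) -> np.ndarray:
    """Analytic observed information: negative Hessian of the observable
    log-likelihood over the free parameters, assembled blockwise."""
    pieces = _Pieces(data, params)
    idx = pieces.idx
    K = params.K
    alpha = e_step(data, params).alpha
    U = _u_matrix(pieces, params)

    d = idx.dim
    hess = np.zeros((d, d))

    # structured sum over j, k of alpha_jk * (second derivatives of h_jk)
    if K > 1:
        colsum = alpha.sum(axis=0)
        hess[idx.pi, idx.pi] -= np.diag(colsum[:-1] / params.pi[:-1] ** 2)
        hess[idx.pi, idx.pi] -= colsum[-1] / params.pi[-1] ** 2
    aw = alpha @ params.w  # expected frailty per group
    for k in range(K):
        wk = idx.w.start + k
        hess[wk, wk] -= alpha[:, k] @ pieces.D / params.w[k] ** 2
        if idx.p:
            hess[wk, idx.beta] -= alpha[:, k] @ pieces.a
        hess[wk, idx.lam] -= alpha[:, k] @ pieces.R
    if idx.p:
        hess[idx.beta, idx.beta] -= np.einsum("j,jab->ab", aw, pieces.C)
        hess[idx.beta, idx.lam] -= np.einsum("j,jma->am", aw, pieces.RX)
    # mirror the upper blocks filled above
    hess = np.tril(hess.T, -1) + hess

    # curvature of the within-group log mixture: sum alpha (u u') - g g'
    Uf = U.reshape(-1, d)
    af = alpha.reshape(-1)
    hess += (Uf * af[:, None]).T @ Uf
    G = np.einsum("jk,jkd->jd", alpha, U)
    hess -= G.T @ G

    # event terms sum_m d_m log(lam_m)
    lam_diag = np.arange(idx.lam.start, idx.lam.stop)
    hess[lam_diag, lam_diag] -= pieces.d / params.baseline.jumps ** 2

    info = -hess
    return (info + info.T) / 2.0


def information_louis(
    data: SurvivalDataset,
    params: FrailtyParams,
    alpha: Optional[MembershipPosterior] = None,
) -> np.ndarray:
    """Louis observed information, summed over per-group contributions
    ``E[B_j] - E[S_j S_j'] + S*_j S*_j'``.

    ``S_j`` and ``B_j`` are the complete-data score and negative second
    derivative of group j given membership k; the expectation over the
    latent membership uses alpha; ``S*_j = E[S_j | Y]`` is the observable
    score contribution of the group (Fisher's identity).
    """
    pieces = _Pieces(data, params)
    idx = pieces.idx
    K = params.K
    if alpha is None:
        alpha = e_step(data, params)
    al = alpha.alpha
    U = _u_matrix(pieces, params)
    d = idx.dim
    J = data.J
    lam = params.baseline.jumps
    info = np.zeros((d, d))
    for j in range(J):
        # complete-data event terms shared across k
        c_j = np.zeros(d)
        if idx.p:
            c_j[idx.beta] = pieces.b[j]
        c_j[idx.lam] = pieces.d_jm[j] / lam

        EB = np.zeros((d, d))
        ESS = np.zeros((d, d))
        s_star = np.zeros(d)
        for k in range(K):
            a_jk = al[j, k]
            # B_j(k): negative Hessian of the complete-data log-lik for group j
            B = np.zeros((d, d))
            if K > 1:
                if k < K - 1:
                    B[idx.pi.start + k, idx.pi.start + k] = 1.0 / params.pi[k] ** 2
                else:
                    B[idx.pi, idx.pi] = 1.0 / params.pi[-1] ** 2
            wk = idx.w.start + k
            B[wk, wk] = pieces.D[j] / params.w[k] ** 2
            if idx.p:
                B[wk, idx.beta] = pieces.a[j]
                B[idx.beta, wk] = pieces.a[j]
                B[np.ix_(range(idx.beta.start, idx.beta.stop),
                         range(idx.beta.start, idx.beta.stop))] = params.w[k] * pieces.C[j]
                B[idx.beta, idx.lam] = params.w[k] * pieces.RX[j].T
                B[np.ix_(range(idx.lam.start, idx.lam.stop),
                         range(idx.beta.start, idx.beta.stop))] = params.w[k] * pieces.RX[j]
            B[wk, idx.lam] = pieces.R[j]
            B[idx.lam, wk] = pieces.R[j]
            lam_diag = np.arange(idx.lam.start, idx.lam.stop)
            B[lam_diag, lam_diag] += pieces.d_jm[j] / lam ** 2

            S = U[j, k] + c_j
            EB += a_jk * B
            ESS += a_jk * np.outer(S, S)
            s_star += a_jk * S
        info += EB - ESS + np.outer(s_star, s_star)
    return (info + info.T) / 2.0


# ---------------------------------------------------------------------------
# Numerical information
# ---------------------------------------------------------------------------


def _loglik_free(x: np.ndarray, data: SurvivalDataset, idx: _FreeIndex, c_i, bX) -> float:
    """Observable log-likelihood as a plain function of the free vector.

    Tolerates infeasible points (returns -inf/nan) so finite-difference steps
    near the boundary can be detected and reduced.
    """
    K = idx.K
    pi = np.empty(K)
    pi[: K - 1] = x[idx.pi]
    pi[K - 1] = 1.0 - pi[: K - 1].sum()
    w = x[idx.w]
    beta = x[idx.beta]
    lam = x[idx.lam]
    if np.any(lam <= 0) or np.any(w <= 0) or np.any(pi < 0):
        return -np.inf
    eta = data.covariates @ beta if idx.p else np.zeros(data.n)
    cum = np.concatenate([[0.0], np.cumsum(lam)])
    Lam_i = cum[c_i]
    A = np.bincount(data.group_idx, weights=Lam_i * np.exp(eta), minlength=data.J)
    D = data.D_j
    from scipy.special import logsumexp

    with np.errstate(divide="ignore"):
        log_mix = np.log(pi)[None, :] + D[:, None] * np.log(w)[None, :] - A[:, None] * w[None, :]
    ev = data.status == 1
    m_of_event = c_i[ev] - 1
    return float(
        np.log(lam[m_of_event]).sum()
        + (bX @ beta if idx.p else 0.0)
        + logsumexp(log_mix, axis=1).sum()
    )


def _fd_hessian(f, x: np.ndarray, h: np.ndarray) -> np.ndarray:
    d = x.size
    f0 = f(x)
    if not np.isfinite(f0):
        raise ValidationError("objective not finite at the expansion point")
    H = np.empty((d, d))
    e = np.eye(d)
    fp = np.empty(d)
    fm = np.empty(d)
    for i in range(d):
        fp[i] = f(x + h[i] * e[i])
        fm[i] = f(x - h[i] * e[i])
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(d):
        for j in range(i + 1, d):
            fpp = f(x + h[i] * e[i] + h[j] * e[j])
            fmm = f(x - h[i] * e[i] - h[j] * e[j])
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm) / (
                2 * h[i] * h[j]
            )
    return H


def information_numeric(
    data: SurvivalDataset,
    params: FrailtyParams,
    rel_step: float = 1e-3,
    max_free_params: int = 500,
) -> np.ndarray:
    """Finite-difference observed information with Richardson extrapolation.

    Central second differences at steps ``h`` and ``h/2`` are combined as
    ``(4 H_{h/2} - H_h) / 3``; steps are scaled to parameter magnitude and
    halved (up to 6 times) if an evaluation lands outside the feasible
    region.  Cost grows quadratically in the number of free parameters, so
    requests beyond ``max_free_params`` are declined.
    """
    pieces_idx = _FreeIndex(params.K, params.p, params.baseline.times.size)
    if pieces_idx.dim > max_free_params:
        raise ValidationError(
            f"numerical information declined: {pieces_idx.dim} free parameters "
            f"exceed the threshold {max_free_params} (the finite-difference "
            "Hessian needs O(d^2) likelihood evaluations); use the exact or "
            "Louis method instead"
        )
    et_times = params.baseline.times
    if not np.array_equal(np.unique(data.time[data.status == 1]), et_times):
        raise BaselineInconsistencyError(
            "baseline jump times must coincide with the data's distinct event times"
        )
    c_i = np.searchsorted(et_times, data.time, side="right")
    bX = data.covariates[data.status == 1].sum(axis=0) if data.p else np.zeros(0)
    x0 = pieces_idx.pack(params)

    def f(x):
        return _loglik_free(x, data, pieces_idx, c_i, bX)

    h = rel_step * np.maximum(np.abs(x0), 1e-3)
    for _ in range(6):
        try:
            H1 = _fd_hessian(f, x0, h)
            H2 = _fd_hessian(f, x0, h / 2)
            if np.all(np.isfinite(H1)) and np.all(np.isfinite(H2)):
                break
        except FloatingPointError:
            pass
        h = h / 2
    else:
        raise ValidationError(
            "finite-difference Hessian not estimable: evaluations remain "
            "non-finite near the parameter boundary"
        )
    H = (4.0 * H2 - H1) / 3.0
    info = -(H + H.T) / 2.0
    return info


# ---------------------------------------------------------------------------
# Delta-method ratio variance and the report
# ---------------------------------------------------------------------------


def ratio_variance(mu1, muk, var1, vark, cov) -> float:
    """Taylor (delta-method) variance of the ratio ``w_k / w_1``::

        Var(wk/w1) = (muk/mu1)^2 [ var1/mu1^2 + vark/muk^2 - 2 cov/(mu1 muk) ]

    Negative values arising from inconsistent inputs are clipped to zero.
    """
    if mu1 == 0:
        raise ValidationError("mu1 must be nonzero")
    out = (muk / mu1) ** 2 * (
        var1 / mu1 ** 2 + vark / muk ** 2 - 2.0 * cov / (mu1 * muk)
    )
    if out < 0:
        warnings.warn("negative delta-method variance clipped to 0", stacklevel=2)
        out = 0.0
    return float(out)


@dataclass
class SEReport:
    """Standard errors for the reported parameters of one fit.

    ``parameters``/``estimates``/``se`` cover pi_1..pi_{K-1}, the frailty
    ratios w_k/w_1 (k >= 2) and beta; ``cov_free`` is the covariance matrix
    of the underlying free parameters (pi_1..pi_{K-1}, w_1..w_K, beta) after
    removing the scale direction; ``diagnostics`` records the constraint
    used, conditioning and rank-deficiency flags.
    """

    method: str
    parameters: List[str]
    estimates: np.ndarray
    se: np.ndarray
    cov_free: np.ndarray
    diagnostics: Dict[str, object] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "parameter": self.parameters,
                "estimate": self.estimates,
                "se": self.se,
                "method": self.method,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def se_report(
    data: SurvivalDataset,
    fit: FitResult,
    method: str = "exact",
    constraint: str = "total_baseline",
    numeric_max_params: int = 500,
) -> SEReport:
    """Invert an observed-information estimate and report standard errors.

    The flat scale direction (w * c against baseline / c) is removed before
    inversion: ``constraint="total_baseline"`` re-expresses the last baseline
    jump as (fitted total) minus the others; ``constraint="fix_w1"`` treats
    w_1 as fixed.  Frailty-ratio standard errors use :func:`ratio_variance`.
    If the constrained information is still not positive definite a
    pseudo-inverse is used and flagged.
    """
    params = fit.params
    K, p = params.K, params.p
    idx = _FreeIndex(K, p, params.baseline.times.size)
    if method == "exact":
        info = information_exact(data, params)
    elif method == "louis":
        info = information_louis(data, params, fit.alpha)
    elif method == "numeric":
        info = information_numeric(data, params, max_free_params=numeric_max_params)
    else:
        raise ValidationError(f"unknown SE method {method!r}")

    n_report = idx.n_pi + K + p  # pi, w, beta coordinates (always leading)
    diagnostics: Dict[str, object] = {"constraint": constraint, "rank_deficient": False}

    if constraint == "fix_w1":
        w1 = idx.w.start
        keep = np.ones(idx.dim, dtype=bool)
        keep[w1] = False
        I_red = info[np.ix_(keep, keep)]
        # original reported coords, shifted by the deleted w1 column
        orig = np.array([i for i in range(n_report) if i != w1])
        cov_small = _solve_columns(I_red, orig - (orig > w1), diagnostics)
        cov = np.zeros((n_report, n_report))
        cov[np.ix_(orig, orig)] = cov_small
    elif constraint == "total_baseline":
        c = idx.dim - 1  # last baseline jump re-expressed via the fitted total
        A = info[:c, :c]
        u = info[:c, c]
        v = np.zeros(c)
        v[idx.lam.start : c] = 1.0
        I_red = A - np.outer(u, v) - np.outer(v, u) + info[c, c] * np.outer(v, v)
        cov = _solve_columns(I_red, np.arange(n_report), diagnostics)
    else:
        raise ValidationError(f"unknown constraint {constraint!r}")

    cov = (cov + cov.T) / 2.0
    names: List[str] = []
    est: List[float] = []
    ses: List[float] = []
    for k in range(idx.n_pi):
        names.append(f"pi_{k + 1}")
        est.append(params.pi[k])
        ses.append(float(np.sqrt(max(cov[k, k], 0.0))))
    iw = idx.n_pi
    for k in range(1, K):
        names.append(f"w{k + 1}/w1")
        est.append(params.w[k] / params.w[0])
        var = ratio_variance(
            params.w[0], params.w[k], cov[iw, iw], cov[iw + k, iw + k], cov[iw, iw + k]
        )
        ses.append(float(np.sqrt(var)))
    ib = idx.n_pi + K
    cov_names = [f"pi_{k + 1}" for k in range(idx.n_pi)]
    cov_names += [f"w{k + 1}" for k in range(K)]
    for q in range(p):
        names.append(f"beta_{data.covariate_names[q]}")
        est.append(params.beta[q])
        ses.append(float(np.sqrt(max(cov[ib + q, ib + q], 0.0))))
        cov_names.append(f"beta_{data.covariate_names[q]}")
    diagnostics["cov_parameter_order"] = cov_names
    return SEReport(
        method=method,
        parameters=names,
        estimates=np.asarray(est),
        se=np.asarray(ses),
        cov_free=cov,
        diagnostics=diagnostics,
    )


def _solve_columns(I_red: np.ndarray, cols: np.ndarray, diagnostics: dict) -> np.ndarray:
    """Covariance sub-block: columns of the inverse of the reduced information."""
    E = np.zeros((I_red.shape[0], cols.size))
    E[cols, np.arange(cols.size)] = 1.0
    try:
        factor = cho_factor(I_red)
        X = cho_solve(factor, E)
    except np.linalg.LinAlgError:
        warnings.warn(
            "constrained information not positive definite; using a pseudo-inverse",
            stacklevel=2,
        )
        diagnostics["rank_deficient"] = True
        X = np.linalg.pinv(I_red) @ E
    if I_red.shape[0] <= 600:
        diagnostics["condition_number"] = float(np.linalg.cond(I_red))
    return X[cols]
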