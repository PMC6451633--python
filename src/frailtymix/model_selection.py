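"""Selection of the number of latent populations and group assignment.

The number of support points K cannot be chosen by likelihood maximization
alone (the likelihood is non-decreasing in richer mixtures up to local-optima
noise), so the model is refit over a grid of K and compared by AIC/BIC, or K
is pruned iteratively by an empty-cluster rule: fit with a generous K, drop
populations to which no group is assigned, refit, repeat.

The effective parameter count used by the criteria is ``p + 2(K - 1)`` by
default — (K-1) free mixing proportions and (K-1) identifiable frailty
ratios; one w is absorbed by the scale of the non-parametric baseline, and
baseline jumps are excluded as in Cox partial-likelihood practice.  The BIC
sample size defaults to the number of groups J, the sampling unit of the
latent structure; both choices are switchable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .data_model import FitResult, MembershipPosterior, SurvivalDataset, ValidationError
from .em_core import EMControl, fit_em

__all__ = ["SelectionTable", "fit_over_K", "select_K", "select_K_laird", "assign_groups"]

logger = logging.getLogger("frailtymix")

_EMPTY_MASS = 1e-8


@dataclass
class SelectionTable:
    """One row per candidate K: log-likelihood, parameter count, AIC, BIC."""

    K: np.ndarray
    loglik: np.ndarray
    n_params: np.ndarray
    aic: np.ndarray
    bic: np.ndarray
    degenerate: np.ndarray
    failed: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "K": self.K,
                "loglik": self.loglik,
                "n_params": self.n_params,
                "AIC": self.aic,
                "BIC": self.bic,
                "degenerate": self.degenerate,
                "failed": self.failed,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def _count_params(K: int, p: int, scheme: str) -> int:
    if scheme == "ratios":
        return p + 2 * (K - 1)
    if scheme == "full":
        return p + 2 * K - 1
    raise ValidationError(f"unknown parameter-count scheme {scheme!r}")


def fit_over_K(
    data: SurvivalDataset,
    K_min: int,
    K_max: int,
    control: Optional[EMControl] = None,
    param_count: str = "ratios",
    bic_n: str = "groups",
) -> Tuple[SelectionTable, Dict[int, FitResult]]:
    """Fit the model for each K in [K_min, K_max] and tabulate AIC/BIC.

    A K whose every restart fails is flagged in the table and skipped by
    :func:`select_K`.
    """
    if not (1 <= K_min <= K_max <= data.J):
        raise ValidationError("need 1 <= K_min <= K_max <= J")
    control = control or EMControl()
    N = data.J if bic_n == "groups" else data.n
    Ks = list(range(K_min, K_max + 1))
    fits: Dict[int, FitResult] = {}
    rows = {k: [] for k in ("loglik", "n_params", "aic", "bic", "degenerate", "failed")}
    for K in Ks:
        q = _count_params(K, data.p, param_count)
        try:
            fit = fit_em(data, K, control)
        except Exception as exc:  # noqa: BLE001 - selection proceeds over the rest
            logger.warning("fit at K=%d failed: %s", K, exc)
            rows["loglik"].append(np.nan)
            rows["n_params"].append(q)
            rows["aic"].append(np.nan)
            rows["bic"].append(np.nan)
            rows["degenerate"].append(False)
            rows["failed"].append(True)
            continue
        fits[K] = fit
        rows["loglik"].append(fit.loglik)
        rows["n_params"].append(q)
        rows["aic"].append(2 * q - 2 * fit.loglik)
        rows["bic"].append(q * np.log(N) - 2 * fit.loglik)
        rows["degenerate"].append(fit.degenerate)
        rows["failed"].append(False)
    table = SelectionTable(
        K=np.asarray(Ks),
        loglik=np.asarray(rows["loglik"]),
        n_params=np.asarray(rows["n_params"]),
        aic=np.asarray(rows["aic"]),
        bic=np.asarray(rows["bic"]),
        degenerate=np.asarray(rows["degenerate"]),
        failed=np.asarray(rows["failed"]),
    )
    return table, fits


def select_K(table: SelectionTable, criterion: str = "bic") -> int:
    """Smallest K minimizing the chosen criterion (ties favour smaller K)."""
    crit = {"aic": table.aic, "bic": table.bic}.get(criterion.lower())
    if crit is None:
        raise ValidationError(f"criterion must be 'aic' or 'bic', got {criterion!r}")
    valid = ~table.failed & np.isfinite(crit)
    if not np.any(valid):
        raise ValidationError("no successful fits to select from")
    best = np.min(crit[valid])
    hit = np.flatnonzero(np.isclose(crit[valid], best))[0]
    return int(table.K[valid][hit])


def select_K_laird(
    data: SurvivalDataset,
    K_max: int,
    control: Optional[EMControl] = None,
) -> Tuple[int, FitResult]:
    """Empty-cluster pruning: fit at K_max, keep populations that attract at
    least one assigned group (and non-negligible posterior mass), refit at
    that count, and iterate until the count is stable.

    On oscillation between two values the smaller is returned (flagged in the
    log).
    """
    control = control or EMControl()
    K = int(K_max)
    if K < 1:
        raise ValidationError("K_max must be >= 1")
    seen = []
    fit = fit_em(data, K, control)
    while True:
        seen.append(K)
        labels = np.argmax(fit.alpha.alpha, axis=1)
        mass = fit.alpha.alpha.sum(axis=0)
        occupied = np.unique(labels)  # populations with >= 1 assigned group
        keep = np.zeros(fit.K, dtype=bool)
        keep[occupied] = True
        keep &= mass >= _EMPTY_MASS
        K_new = int(keep.sum())
        if K_new == K:
            return K, fit
        if K_new in seen:
            K_final = min(K_new, K)
            logger.warning(
                "empty-cluster pruning oscillates between %d and %d; returning %d",
                K, K_new, K_final,
            )
            fit = fit_em(data, K_final, control)
            return K_final, fit
        K = K_new
        fit = fit_em(data, K, control)


def assign_groups(
    alpha: MembershipPosterior, threshold: float = 0.6
) -> Tuple[np.ndarray, np.ndarray]:
    """Hard assignment label_j = argmax_k alpha_jk with uncertainty flags.

    Groups whose maximal membership probability is below ``threshold`` are
    flagged as uncertain; exact ties resolve to the lower-index population
    and are flagged.
    """
    a = alpha.alpha
    labels = np.argmax(a, axis=1)
    best = a[np.arange(a.shape[0]), labels]
    ties = (a >= best[:, None] - 1e-15).sum(axis=1) > 1
    flags = (best < threshold) | ties
    return labels, flags
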