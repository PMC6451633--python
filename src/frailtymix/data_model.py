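"""Core containers for hierarchical time-to-event data and model parameters.

The model addressed by this package is a Cox proportional-hazards model in
which subjects are nested in groups (e.g. patients within healthcare
providers) and each group carries a shared multiplicative frailty drawn from
a *discrete* distribution with K support points ``w_1..w_K`` and mixing
proportions ``pi_1..pi_K``.  Conditional on group j belonging to latent
population k, subject i in group j has hazard::

    lambda(t | X_ij, k) = lambda0(t) * w_k * exp(X_ij' beta)

with a non-parametric (step-function) baseline ``Lambda0``.  This module
defines the observable-data container, the parameter container, the posterior
membership matrix, the event/risk-set table used by the Breslow-type
estimators, and the fit-result record shared by the estimation modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FormatError",
    "ModelUndefinedError",
    "BaselineInconsistencyError",
    "SurvivalDataset",
    "StepBaseline",
    "FrailtyParams",
    "MembershipPosterior",
    "EventTable",
    "FitResult",
    "load_dataset",
    "build_event_table",
]

_SIMPLEX_TOL = 1e-10


class ValidationError(ValueError):
    """Input data violate a structural requirement of the model."""


class FormatError(ValueError):
    """A delimited input file does not have the expected layout."""


class ModelUndefinedError(ValueError):
    """The model is undefined for these data (e.g. no observed events)."""


class BaselineInconsistencyError(ValueError):
    """The baseline step function lacks a jump at an observed event time."""


# ---------------------------------------------------------------------------
# Observable data
# ---------------------------------------------------------------------------


@dataclass
class SurvivalDataset:
    """Observable hierarchical survival data.

    One entry per subject: follow-up time ``t_ij = min(T*_ij, C_ij)``, event
    indicator ``delta_ij`` (1 = event, 0 = censored), covariate vector
    ``X_ij`` and the index of the group the subject belongs to.  Groups are
    indexed contiguously ``0..J-1`` internally; the original labels are kept
    in ``group_labels`` for reporting.
    """

    time: np.ndarray
    status: np.ndarray
    covariates: np.ndarray
    group_idx: np.ndarray
    group_labels: np.ndarray
    covariate_names: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.status = np.asarray(self.status)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != self.time.shape[0]:
            self.covariates = self.covariates.T
        if self.covariates.size == 0:
            self.covariates = self.covariates.reshape(self.time.shape[0], 0)
        self.group_idx = np.asarray(self.group_idx, dtype=np.intp)
        self.group_labels = np.asarray(self.group_labels)
        if not self.covariate_names:
            self.covariate_names = [f"x{i + 1}" for i in range(self.p)]
        self.validate()

    # -- shape properties ---------------------------------------------------

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def J(self) -> int:
        return self.group_labels.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_j(self) -> np.ndarray:
        """Per-group subject counts."""
        return np.bincount(self.group_idx, minlength=self.J)

    @property
    def D_j(self) -> np.ndarray:
        """Per-group event totals ``D_j = sum_i delta_ij``."""
        return np.bincount(self.group_idx, weights=self.status, minlength=self.J).astype(int)

    # -- validation ---------------------------------------------------------

    def validate(self) -> "SurvivalDataset":
        if self.time.ndim != 1:
            raise ValidationError("time must be a 1-d array")
        if np.any(~np.isfinite(self.time)) or np.any(self.time < 0):
            bad = int(np.flatnonzero(~np.isfinite(self.time) | (self.time < 0))[0])
            raise ValidationError(f"negative or non-finite time at row {bad}")
        bad_status = ~np.isin(self.status, (0, 1))
        if np.any(bad_status):
            bad = int(np.flatnonzero(bad_status)[0])
            raise ValidationError(
                f"status must be 0 or 1; found {self.status[bad]!r} at row {bad}"
            )
        self.status = self.status.astype(int)
        if self.group_idx.min(initial=0) < 0 or (
            self.n > 0 and self.group_idx.max() >= self.J
        ):
            raise ValidationError("group_idx out of range for group_labels")
        if np.any(self.n_j < 1):
            empty = int(np.flatnonzero(self.n_j < 1)[0])
            raise ValidationError(f"group {self.group_labels[empty]!r} has no subjects")
        if self.status.sum() < 1:
            raise ModelUndefinedError("no events observed; the model is undefined")
        if np.any(~np.isfinite(self.covariates)):
            raise ValidationError("covariate matrix contains missing/non-finite entries")
        self.constant_covariates = np.flatnonzero(self.covariates.std(axis=0) == 0)
        if self.constant_covariates.size:
            names = [self.covariate_names[i] for i in self.constant_covariates]
            warnings.warn(f"covariate(s) {names} have zero variance", stacklevel=2)
        return self

    # -- construction / IO --------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        group_col: str = "group",
        time_col: str = "time",
        status_col: str = "status",
        covariate_cols: Optional[Sequence[str]] = None,
    ) -> "SurvivalDataset":
        for col in (group_col, time_col, status_col):
            if col not in df.columns:
                raise FormatError(f"required column {col!r} not found")
        if covariate_cols is None:
            covariate_cols = [
                c for c in df.columns if c not in (group_col, time_col, status_col)
            ]
        missing = [c for c in covariate_cols if c not in df.columns]
        if missing:
            raise FormatError(f"covariate column(s) {missing} not found")
        labels, idx = np.unique(df[group_col].to_numpy(), return_inverse=True)
        status_raw = df[status_col].to_numpy()
        return cls(
            time=df[time_col].to_numpy(dtype=float),
            status=status_raw,
            covariates=df[covariate_cols].to_numpy(dtype=float).reshape(len(df), -1),
            group_idx=idx,
            group_labels=labels,
            covariate_names=list(covariate_cols),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "group": self.group_labels[self.group_idx],
                "time": self.time,
                "status": self.status,
            }
        )
        for i, name in enumerate(self.covariate_names):
            df[name] = self.covariates[:, i]
        return df

    def to_csv(self, path, sep: str = ",") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index=False, float_format="%.10g")


def load_dataset(
    path,
    column_map: Optional[Mapping[str, object]] = None,
    delimiter: str = ",",
) -> SurvivalDataset:
    """Read a delimited file with header into a validated :class:`SurvivalDataset`.

    ``column_map`` may remap the roles ``group``, ``time``, ``status`` and
    ``covariates`` (a list of column names) onto the file's column names;
    unmapped remaining columns are treated as covariates.
    """
    column_map = dict(column_map or {})
    try:
        df = pd.read_csv(path, sep=delimiter)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not parse {path!r}: {exc}") from exc
    return SurvivalDataset.from_dataframe(
        df,
        group_col=column_map.get("group", "group"),
        time_col=column_map.get("time", "time"),
        status_col=column_map.get("status", "status"),
        covariate_cols=column_map.get("covariates"),
    )


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class StepBaseline:
    """Non-decreasing step estimate of the cumulative baseline hazard.

    Jumps of height ``jumps[m] > 0`` sit at the sorted distinct event times
    ``times[m]``; ``Lambda0(0) = 0`` and evaluation is right-continuous.  The
    jump height at an event time is the non-parametric analogue of
    ``lambda0(t) dt`` and is what the likelihood modules use for
    ``log lambda0(t_ij)``.
    """

    times: np.ndarray
    jumps: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.jumps = np.asarray(self.jumps, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.jumps.shape:
            raise ValidationError("baseline times and jumps must be matching 1-d arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("baseline times must be strictly increasing")
        if np.any(self.times <= 0):
            raise ValidationError("baseline jump times must be positive")
        if np.any(self.jumps <= 0):
            raise ValidationError("baseline jumps must be positive")
        self._cum = np.cumsum(self.jumps)

    def cumhaz(self, t) -> np.ndarray:
        """Cumulative baseline ``Lambda0(t)`` (right-continuous step)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        return np.where(idx > 0, self._cum[np.maximum(idx - 1, 0)], 0.0)

    __call__ = cumhaz

    def jump_at(self, t) -> np.ndarray:
        """Jump height at exact time(s) ``t``; error if no jump sits there."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t)
        ok = (idx < self.times.size) & np.isclose(
            self.times[np.minimum(idx, self.times.size - 1)], t, rtol=0, atol=0
        )
        if not np.all(ok):
            missing = np.atleast_1d(t)[np.atleast_1d(~ok)][:3]
            raise BaselineInconsistencyError(
                f"no baseline jump at event time(s) {missing.tolist()}"
            )
        return self.jumps[idx]

    @property
    def total(self) -> float:
        """``Lambda0`` at the largest event time."""
        return float(self._cum[-1]) if self.jumps.size else 0.0

    def scaled(self, c: float) -> "StepBaseline":
        return StepBaseline(self.times.copy(), self.jumps * c)


@dataclass
class FrailtyParams:
    """Full parameter vector theta = (pi, w, Lambda0, beta) for a given K."""

    pi: np.ndarray
    w: np.ndarray
    beta: np.ndarray
    baseline: StepBaseline

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float).reshape(-1)
        self.validate()

    @property
    def K(self) -> int:
        return self.pi.shape[0]

    @property
    def p(self) -> int:
        return self.beta.shape[0]

    def validate(self) -> "FrailtyParams":
        if self.pi.shape != self.w.shape or self.pi.ndim != 1:
            raise ValidationError("pi and w must be 1-d vectors of equal length K")
        if abs(self.pi.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValidationError(f"pi must sum to 1 (got {self.pi.sum()!r})")
        if np.any(self.pi < 0):
            raise ValidationError("pi must be non-negative")
        if np.any(self.w <= 0):
            raise ValidationError("frailty support points w must be positive")
        return self


@dataclass
class MembershipPosterior:
    """Posterior membership matrix ``alpha[j, k] = P(group j in population k | Y)``."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        self.validate()

    @property
    def J(self) -> int:
        return self.alpha.shape[0]

    @property
    def K(self) -> int:
        return self.alpha.shape[1]

    def validate(self) -> "MembershipPosterior":
        if np.any(self.alpha < -_SIMPLEX_TOL) or np.any(self.alpha > 1 + _SIMPLEX_TOL):
            raise ValidationError("alpha entries must lie in [0, 1]")
        if np.any(np.abs(self.alpha.sum(axis=1) - 1.0) > 1e-8):
            raise ValidationError("alpha rows must sum to 1")
        return self


# ---------------------------------------------------------------------------
# Event table
# ---------------------------------------------------------------------------


@dataclass
class EventTable:
    """Distinct event times, tie counts and risk sets for Breslow-type sums.

    ``risk_start[m]`` is the position in ``order`` (subjects sorted by
    ascending follow-up time) where the risk set at ``distinct_event_times[m]``
    begins; the risk set is the suffix ``order[risk_start[m]:]``, i.e. all
    subjects with observed time >= that event time (subjects censored exactly
    at an event time are at risk there).
    """

    distinct_event_times: np.ndarray
    tie_counts: np.ndarray
    group_event_totals: np.ndarray
    order: np.ndarray
    risk_start: np.ndarray

    @property
    def n_times(self) -> int:
        return self.distinct_event_times.shape[0]

    @property
    def risk_sets(self) -> list:
        """Explicit risk sets as arrays of original subject indices.

        Materializes one array per distinct event time; intended for
        inspection and small-data checks, not for the vectorized estimators.
        """
        return [self.order[s:] for s in self.risk_start]

    @property
    def risk_sizes(self) -> np.ndarray:
        return self.order.shape[0] - self.risk_start


def build_event_table(data: SurvivalDataset) -> EventTable:
    """Tabulate distinct event times, tie counts d_fg and risk sets R(t_fg)."""
    events = data.status == 1
    if not np.any(events):
        raise ModelUndefinedError("cannot build an event table without events")
    times, d = np.unique(data.time[events], return_counts=True)
    order = np.argsort(data.time, kind="stable")
    risk_start = np.searchsorted(data.time[order], times, side="left")
    return EventTable(
        distinct_event_times=times,
        tie_counts=d,
        group_event_totals=data.D_j,
        order=order,
        risk_start=risk_start,
    )


# ---------------------------------------------------------------------------
# Fit result
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Converged EM output for a fixed number of latent populations K.

    ``frailty_ratios = w / min(w)`` is the post-hoc normalization that makes
    the frailties interpretable as hazard ratios relative to the lowest-risk
    population (the raw w are only identified jointly with the baseline
    scale).  Populations are relabeled in ascending-w order.
    """

    params: FrailtyParams
    alpha: MembershipPosterior
    loglik: float
    n_iter: int
    converged: bool
    frailty_ratios: np.ndarray
    assignments: np.ndarray
    degenerate: bool = False
    loglik_path: Optional[np.ndarray] = None
    restart_logliks: Optional[np.ndarray] = None
    se: Optional[object] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.loglik):
            raise ValidationError("fit log-likelihood is not finite")
        if abs(float(np.min(self.frailty_ratios)) - 1.0) > 1e-12:
            raise ValidationError("frailty_ratios must have minimum exactly 1")

    @property
    def K(self) -> int:
        return self.params.K
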