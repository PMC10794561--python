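"""Survival-analysis kernels: Cox proportional hazards, AUC with DeLong CI,
Kaplan-Meier curves and quantile incidence.

The Cox model maximizes the Breslow partial likelihood by Newton-Raphson.
With day-resolution follow-up times ties are common; Breslow's approximation
treats all events at a tied time as sharing the same risk set. Standard
errors come from the inverse observed information at the maximum, Wald
confidence intervals are ``coef +/- 1.96*se`` on the log-hazard scale, and
hazard ratios are exponentiated only for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoxPH",
    "CoxFit",
    "CoxError",
    "SeparationError",
    "fit_cox",
    "AucResult",
    "auc",
    "km_curve",
    "QuantileIncidence",
    "quantile_incidence",
]

Z975 = 1.959963984540054


class CoxError(ValueError):
    """Invalid input or failed fit for the Cox model."""


class SeparationError(CoxError):
    """Monotone partial likelihood (complete separation) for a covariate."""


@dataclass
class CoxFit:
    """Fitted Cox proportional-hazards model (log-hazard scale).

    ``conf_int`` holds the Wald 95% interval for the coefficients; apply
    ``np.exp`` to get hazard-ratio bounds.
    """

    params: np.ndarray
    bse: np.ndarray
    conf_int: np.ndarray  # (p, 2) on the log scale
    pvalues: np.ndarray
    converged: bool
    n: int
    n_events: int
    loglik: float
    names: list[str]
    ties: str = "breslow"
    ridge: float = 0.0
    # Breslow baseline cumulative hazard evaluated at covariates == 0
    baseline_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    baseline_cumhaz: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    def predict_lp(self, X) -> np.ndarray:
        """Linear predictor ``X @ params``."""
        return np.asarray(X, dtype=float) @ self.params

    def cumulative_hazard_at(self, t: float) -> float:
        """Baseline cumulative hazard H0(t) (right-continuous step)."""
        idx = np.searchsorted(self.baseline_times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.baseline_cumhaz[idx])

    def predict_risk(self, X, t: float) -> np.ndarray:
        """Absolute event risk 1 - exp(-H0(t) * exp(lp)) by time ``t``."""
        h0 = self.cumulative_hazard_at(t)
        return 1.0 - np.exp(-h0 * np.exp(self.predict_lp(X)))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "HR": self.hazard_ratios,
                "se": self.bse,
                "HR lower 95%": np.exp(self.conf_int[:, 0]),
                "HR upper 95%": np.exp(self.conf_int[:, 1]),
                "p": self.pvalues,
            },
            index=self.names,
        )


class CoxPH:
    """Cox proportional-hazards model for right-censored data.

    Parameters
    ----------
    times : array-like
        Positive follow-up times.
    events : array-like
        Event indicators (1 event, 0 censored).
    X : array-like or DataFrame
        Covariate matrix, one column per covariate.
    names : sequence of str, optional
        Covariate names (taken from DataFrame columns when available).
    ridge : float
        Ridge term added to the observed information matrix each Newton
        step. Used to stabilize near-collinear designs; 0 disables it.
    """

    def __init__(self, times, events, X, names: Sequence[str] | None = None,
                 ridge: float = 0.0):
        if isinstance(X, pd.DataFrame):
            if names is None:
                names = [str(c) for c in X.columns]
            X = X.to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(times)) > 1:
            X = X.T
        self.times = np.asarray(times, dtype=float)
        self.events = np.asarray(events).astype(int)
        self.X = X
        self.names = list(names) if names is not None else [
            f"x{j}" for j in range(X.shape[1])
        ]
        self.ridge = float(ridge)
        self._validate()

    def _validate(self) -> None:
        n, p = self.X.shape
        if len(self.times) != n or len(self.events) != n:
            raise CoxError("times, events and X must have equal length")
        if np.any(~np.isfinite(self.times)) or np.any(self.times <= 0):
            raise CoxError("all follow-up times must be positive and finite")
        if self.events.sum() < 1:
            raise CoxError("at least one event is required")
        if np.any(~np.isfinite(self.X)):
            raise CoxError("covariates contain non-finite values")
        sds = self.X.std(axis=0)
        for j, sd in enumerate(sds):
            if sd == 0:
                raise CoxError(f"constant covariate: {self.names[j]}")

    # ---- Breslow partial likelihood machinery -------------------------

    def _prepare(self):
        # Sort descending by time so risk sets are cumulative prefixes.
        order = np.argsort(-self.times, kind="stable")
        t = self.times[order]
        d = self.events[order]
        x = self.Xs[order]
        # Event-time groups (unique event times, ascending within the
        # descending layout they appear as contiguous runs).
        return t, d, x

    def _loglik_grad_info(self, beta, t, d, x):
        n, p = x.shape
        eta = x @ beta
        eta = np.clip(eta, -700, 700)
        w = np.exp(eta)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w[:, None] * x, axis=0)
        s2 = np.cumsum(w[:, None, None] * (x[:, :, None] * x[:, None, :]),
                       axis=0)
        # For each subject i (descending time), the risk set of its time is
        # all subjects with time >= t_i == prefix ending at the last index
        # sharing that time.
        # last index of each tied block:
        last = np.concatenate([np.nonzero(np.diff(t))[0], [n - 1]])
        block_of = np.repeat(np.arange(len(last)),
                             np.diff(np.concatenate([[-1], last])))
        ridx = last[block_of]  # per-subject index into cumsums
        ev = d.astype(bool)
        r = ridx[ev]
        S0 = s0[r]
        S1 = s1[r]
        S2 = s2[r]
        ll = float(eta[ev].sum() - np.log(S0).sum())
        mean = S1 / S0[:, None]
        grad = x[ev].sum(axis=0) - mean.sum(axis=0)
        info = (S2 / S0[:, None, None]).sum(axis=0) - np.einsum(
            "ij,ik->jk", mean, mean)
        return ll, grad, info

    def fit(self, max_iter: int = 50, tol: float = 1e-8) -> CoxFit:
        """Newton-Raphson maximization of the Breslow partial likelihood.

        Convergence when the information-scaled step has max-norm < ``tol``.
        Raises :class:`SeparationError` when a coefficient diverges
        (monotone likelihood).
        """
        n, p = self.X.shape
        # Standardize internally: scale-free convergence and divergence
        # thresholds; transformed back at the end.
        self._mu = self.X.mean(axis=0)
        self._sd = self.X.std(axis=0)
        self.Xs = (self.X - self._mu) / self._sd
        t, d, x = self._prepare()
        beta = np.zeros(p)
        converged = False
        I = np.eye(p)

        def _solve(info, grad):
            if self.ridge > 0:
                # collinear-fallback path: spectral truncation of the
                # information keeps the Newton step minimum-norm in
                # (near-)unidentified directions, which a small absolute
                # ridge alone cannot stabilize
                return np.linalg.pinv(info, rcond=max(self.ridge, 1e-9),
                                      hermitian=True) @ grad
            try:
                return np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as exc:
                if np.max(np.abs(beta)) > 2.0:
                    # information vanished while a coefficient drifted out:
                    # monotone likelihood, not collinearity
                    j = int(np.argmax(np.abs(beta)))
                    raise SeparationError(
                        f"monotone partial likelihood: coefficient for "
                        f"'{self.names[j]}' diverges (complete separation)"
                    ) from exc
                raise CoxError(
                    "singular information matrix; covariates may be "
                    "collinear (consider ridge > 0)"
                ) from exc

        for _ in range(max_iter):
            ll, grad, info = self._loglik_grad_info(beta, t, d, x)
            step = _solve(info, grad)
            # step halving if the likelihood does not improve
            shrink = 1.0
            while shrink > 1e-10:
                cand = beta + shrink * step
                ll_new, _, _ = self._loglik_grad_info(cand, t, d, x)
                if ll_new >= ll - 1e-12:
                    break
                shrink /= 2.0
            beta = beta + shrink * step
            if np.max(np.abs(beta)) > 15.0:
                j = int(np.argmax(np.abs(beta)))
                raise SeparationError(
                    f"monotone partial likelihood: coefficient for "
                    f"'{self.names[j]}' diverges (complete separation)"
                )
            if np.max(np.abs(shrink * step)) < tol:
                converged = True
                break
        ll, grad, info = self._loglik_grad_info(beta, t, d, x)
        if self.ridge > 0:
            cov = np.linalg.pinv(info, rcond=max(self.ridge, 1e-9),
                                 hermitian=True)
        else:
            cov = np.linalg.inv(info)
        # back-transform to the raw covariate scale
        params = beta / self._sd
        bse = np.sqrt(np.diag(cov)) / self._sd
        ci = np.column_stack([params - Z975 * bse, params + Z975 * bse])
        z = params / bse
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        fit = CoxFit(
            params=params,
            bse=bse,
            conf_int=ci,
            pvalues=pvals,
            converged=converged,
            n=n,
            n_events=int(self.events.sum()),
            loglik=ll,
            names=list(self.names),
            ridge=self.ridge,
        )
        self._breslow_baseline(fit)
        return fit

    def _breslow_baseline(self, fit: CoxFit) -> None:
        """Breslow estimator of the baseline cumulative hazard at X = 0."""
        eta = np.clip(self.X @ fit.params, -700, 700)
        w = np.exp(eta)
        order = np.argsort(self.times, kind="stable")
        t = self.times[order]
        d = self.events[order]
        ww = w[order]
        # risk-set sums: total minus prefix of those already failed/censored
        tot = ww.sum()
        before = np.concatenate([[0.0], np.cumsum(ww)[:-1]])
        # subjects with identical times are in the same risk set: recompute
        # "before" at the first index of each tied block
        firsts = np.concatenate([[0], np.nonzero(np.diff(t))[0] + 1])
        block_of = np.searchsorted(firsts, np.arange(len(t)), side="right") - 1
        atrisk = tot - before[firsts[block_of]]
        ev_times, inv = np.unique(t[d == 1], return_inverse=True)
        dN = np.bincount(inv)
        # risk-set sum at each event time
        pos = np.searchsorted(t, ev_times, side="left")
        risk = atrisk[pos]
        fit.baseline_times = ev_times
        fit.baseline_cumhaz = np.cumsum(dN / risk)


def fit_cox(times, events, X, names: Sequence[str] | None = None,
            ridge: float = 0.0, **fit_kw) -> CoxFit:
    """Convenience wrapper: build a :class:`CoxPH` model and fit it."""
    return CoxPH(times, events, X, names=names, ridge=ridge).fit(**fit_kw)


# ---------------------------------------------------------------------------
# AUC (Mann-Whitney) with DeLong confidence interval


@dataclass
class AucResult:
    auc: float
    ci: tuple[float, float]
    se: float
    n_cases: int
    n_controls: int
    method: str = "delong"


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def auc(scores, labels, ci_method: str = "delong", n_boot: int = 2000,
        seed: int = 0) -> AucResult:
    """Area under the ROC curve with a 95% confidence interval.

    AUC is the Mann-Whitney probability that a random case outscores a
    random control, ties counting one half. The default CI uses DeLong's
    asymptotic variance from the structural components of the U-statistic;
    ``ci_method="bootstrap"`` resamples cases and controls (seeded).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    m, n = len(cases), len(controls)
    if m == 0 or n == 0:
        raise ValueError("AUC undefined: one class is empty")
    all_r = _midranks(np.concatenate([cases, controls]))
    case_r = _midranks(cases)
    ctrl_r = _midranks(controls)
    theta = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    if ci_method == "delong":
        v10 = (all_r[:m] - case_r) / n          # per-case components
        v01 = 1.0 - (all_r[m:] - ctrl_r) / m    # per-control components
        var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
            np.var(v01, ddof=1) / n if n > 1 else 0.0)
        se = float(np.sqrt(var))
        lo, hi = theta - Z975 * se, theta + Z975 * se
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            cs = rng.choice(cases, m, replace=True)
            ct = rng.choice(controls, n, replace=True)
            r = _midranks(np.concatenate([cs, ct]))
            reps[b] = (r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        se = float(reps.std(ddof=1))
        lo, hi = np.percentile(reps, [2.5, 97.5])
    else:
        raise ValueError(f"unknown ci_method: {ci_method!r}")
    return AucResult(
        auc=float(theta),
        ci=(float(max(0.0, lo)), float(min(1.0, hi))),
        se=se,
        n_cases=m,
        n_controls=n,
        method=ci_method,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier


def km_curve(times, events):
    """Product-limit survival curve.

    Returns ``(times, survival)`` arrays describing the right-continuous
    step function, starting at S(0) = 1. Wraps lifelines'
    ``KaplanMeierFitter``.
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    if np.any(times <= 0):
        raise ValueError("all times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, np.asarray(events).astype(int))
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Quantile incidence


@dataclass
class QuantileIncidence:
    """Event rate per score quantile, ordered bottom to top."""

    rates: np.ndarray
    counts: np.ndarray
    events: np.ndarray
    fold_ratio: float  # rate(top) / rate(bottom); inf if bottom rate is 0

    @property
    def q(self) -> int:
        return len(self.rates)


def quantile_incidence(scores, events, q: int = 10) -> QuantileIncidence:
    """Cumulative event rate within ``q`` equal-size score bins.

    Ties are broken by stable input order; bin sizes differ by at most one.
    The fold ratio contrasts the top and bottom bins and is reported as
    ``inf`` when the bottom bin has no events.
    """
    scores = np.asarray(scores, dtype=float)
    events = np.asarray(events).astype(int)
    if q < 2:
        raise ValueError("q must be at least 2")
    n = len(scores)
    if n < q:
        raise ValueError(f"need at least q={q} observations, got {n}")
    order = np.argsort(scores, kind="stable")
    bins = np.array_split(order, q)  # ascending score: bins[0] = bottom
    counts = np.array([len(b) for b in bins])
    ev = np.array([events[b].sum() for b in bins])
    rates = ev / counts
    bottom, top = rates[0], rates[-1]
    fold = float("inf") if bottom == 0 else float(top / bottom)
    return QuantileIncidence(rates=rates, counts=counts, events=ev,
                             fold_ratio=fold)
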