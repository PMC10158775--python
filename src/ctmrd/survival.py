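"""Survival analytics written from first principles.

Kaplan–Meier product-limit estimation, the k-group log-rank test, and Cox
proportional-hazards regression by Newton–Raphson on the partial likelihood
with Efron's tie correction.  These are deliberately self-contained: the
estimators are the quantity of interest here, and the implementations are
cross-checked against independent references in the test suite.

Conventions
-----------
* Censored subjects at time t contribute to the risk set of events at t
  (ties between a censoring and an event: the event is counted first).
* The log-rank statistic uses the (k-1)-dimensional O−E vector with its
  hypergeometric covariance; p is the chi-square upper tail with k−1 df.
* Cox hazard-ratio CIs are Wald on the log scale (95% by default), and the
  ``univariate_first`` selection mode fits each covariate alone and carries
  only those with two-sided p < 0.05 into the multivariate model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm


# ---------------------------------------------------------------------------
# Kaplan–Meier


@dataclass
class KMCurve:
    """A right-continuous, non-increasing step function with S(0) = 1."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def evaluate(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def median(self) -> Optional[float]:
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if below.size else None


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Product-limit estimator: S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("km_estimate: empty input")
    if np.any(times < 0):
        raise ValueError("km_estimate: negative times")

    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    event_times = np.unique(times[events])
    n = times.size
    surv = []
    at_risk = []
    d_out = []
    s = 1.0
    for t in event_times:
        n_i = int(np.sum(times >= t))
        d_i = int(np.sum((times == t) & events))
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        d_out.append(d_i)
    return KMCurve(
        times=event_times,
        survival=np.asarray(surv),
        n_at_risk=np.asarray(at_risk),
        n_events=np.asarray(d_out),
    )


# ---------------------------------------------------------------------------
# log-rank


def logrank_test(groups: Sequence[tuple[Sequence[float], Sequence[bool]]]) -> tuple[float, float]:
    """k-sample log-rank test; ``groups`` is a list of (times, events).

    Returns (chi2, p).  The statistic is (O−E)' V⁻¹ (O−E) over the first
    k−1 groups, with the usual hypergeometric variance at each distinct
    event time.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("logrank_test needs at least two groups")
    times = [np.asarray(t, dtype=float) for t, _ in groups]
    events = [np.asarray(e, dtype=bool) for _, e in groups]
    for t in times:
        if t.size == 0:
            raise ValueError("logrank_test: empty group")

    all_event_times = np.unique(np.concatenate([t[e] for t, e in zip(times, events)]))
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in all_event_times:
        n_j = np.array([np.sum(tj >= t) for tj in times], dtype=float)
        d_j = np.array(
            [np.sum((tj == t) & ej) for tj, ej in zip(times, events)], dtype=float
        )
        n = n_j.sum()
        d = d_j.sum()
        if n <= 0 or d <= 0:
            continue
        O += d_j
        E += d * n_j / n
        if n > 1:
            c = d * (n - d) / (n - 1.0)
            p_j = n_j / n
            V += c * (np.diag(p_j) - np.outer(p_j, p_j))

    z = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    if not np.any(z) or not np.any(Vsub):
        return 0.0, 1.0
    chi2 = float(z @ np.linalg.pinv(Vsub) @ z)
    chi2 = max(chi2, 0.0)
    p = float(chi2_dist.sf(chi2, df=k - 1))
    return chi2, p


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass
class CoxCovariateResult:
    name: str
    coef: float
    hazard_ratio: float
    se: float
    ci95_lo: float
    ci95_hi: float
    wald_p: float


@dataclass
class CoxFit:
    covariates: list[CoxCovariateResult]
    log_likelihood: float
    n: int
    n_events: int
    separation_flagged: bool = False
    #: names screened out in univariate_first selection (p >= threshold)
    excluded: list[str] = field(default_factory=list)

    def __getitem__(self, name: str) -> CoxCovariateResult:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(name)


def _cox_loglik(beta, X, times, events):
    """Efron partial log-likelihood, gradient and information matrix."""
    n, p = X.shape
    eta = X @ beta
    theta = np.exp(eta)
    order = np.argsort(-times, kind="stable")  # descending time
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))

    # running sums over the risk set (subjects with time >= current t)
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    idx = order
    while i < n:
        t = times[idx[i]]
        j = i
        tied = []
        while j < n and times[idx[j]] == t:
            m = idx[j]
            s0 += theta[m]
            s1 += theta[m] * X[m]
            s2 += theta[m] * np.outer(X[m], X[m])
            if events[m]:
                tied.append(m)
            j += 1
        d = len(tied)
        if d > 0:
            t0 = sum(theta[m] for m in tied)
            t1 = np.sum([theta[m] * X[m] for m in tied], axis=0)
            t2 = np.sum([theta[m] * np.outer(X[m], X[m]) for m in tied], axis=0)
            xsum = np.sum([X[m] for m in tied], axis=0)
            ll += float(np.sum(eta[tied]))
            for r in range(d):
                f = r / d
                z0 = s0 - f * t0
                z1 = s1 - f * t1
                z2 = s2 - f * t2
                ll -= np.log(z0)
                grad_term = z1 / z0
                grad -= grad_term
                info += z2 / z0 - np.outer(grad_term, grad_term)
            grad += xsum
        i = j
    return ll, grad, info


def _newton_cox(X, times, events, max_iter=60, tol=1e-10):
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _cox_loglik(beta, X, times, events)
    trace = [ll]
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < 1e-9:
            return beta, ll, grad, info, trace
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(info) @ grad
        # step-halving to guarantee ascent
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, grad_new, info_new = _cox_loglik(cand, X, times, events)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-10 * (abs(ll) + 1.0):
                break
            factor /= 2.0
        else:
            raise ConvergenceError("Cox Newton step failed to increase likelihood", trace)
        beta, ll_prev = cand, ll
        ll, grad, info = ll_new, grad_new, info_new
        trace.append(ll)
        if abs(ll - ll_prev) < tol and np.max(np.abs(grad)) < 1e-6:
            return beta, ll, grad, info, trace
    if np.max(np.abs(grad)) < 1e-4:  # flat enough to accept
        return beta, ll, grad, info, trace
    raise ConvergenceError(
        f"Cox model did not converge in {max_iter} iterations", trace
    )


def cox_fit(
    X,
    times,
    events,
    names: Optional[Sequence[str]] = None,
    selection: str = "none",
    screen_p: float = 0.05,
) -> CoxFit:
    """Fit a Cox proportional-hazards model.

    Parameters
    ----------
    X : (n, p) array of covariates (binary or numeric, as coded upstream)
    times, events : survival outcome
    selection : "none" fits all covariates jointly; "univariate_first" fits
        each alone and keeps only those with Wald p < ``screen_p`` for the
        joint model.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(times)) == X.shape[1]:
        X = X.T
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    n, p = X.shape
    names = list(names) if names is not None else [f"x{i}" for i in range(p)]

    excluded: list[str] = []
    keep = list(range(p))
    if selection == "univariate_first":
        keep = []
        for j in range(p):
            uni = cox_fit(X[:, [j]], times, events, names=[names[j]])
            if uni.covariates[0].wald_p < screen_p:
                keep.append(j)
            else:
                excluded.append(names[j])
        if not keep:
            return CoxFit(covariates=[], log_likelihood=0.0, n=n,
                          n_events=int(events.sum()), excluded=excluded)
        X = X[:, keep]
        names = [names[j] for j in keep]

    beta, ll, grad, info, trace = _newton_cox(X, times, events)
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    separation = bool(np.any(np.abs(beta) > 10) or np.any(se > 10))
    z975 = norm.ppf(0.975)
    results = []
    for j, name in enumerate(names):
        b, s = float(beta[j]), float(se[j])
        zval = b / s if s > 0 else np.inf * np.sign(b)
        results.append(
            CoxCovariateResult(
                name=name,
                coef=b,
                hazard_ratio=float(np.exp(min(b, 700.0))),
                se=s,
                ci95_lo=float(np.exp(max(b - z975 * s, -700.0))),
                ci95_hi=float(np.exp(min(b + z975 * s, 700.0))),
                wald_p=float(2 * norm.sf(abs(zval))),
            )
        )
    return CoxFit(
        covariates=results,
        log_likelihood=float(ll),
        n=n,
        n_events=int(events.sum()),
        separation_flagged=separation,
        excluded=excluded,
    )


def cox_score_test(X, times, events) -> float:
    """Score (Rao) chi-square statistic at beta = 0.

    For a single binary covariate with no tied event times this equals the
    two-group log-rank chi-square.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    _, grad, info = _cox_loglik(np.zeros(X.shape[1]), X, times, events)
    return float(grad @ np.linalg.pinv(info) @ grad)
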