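"""Self-contained time-to-event statistics.

Implements the three tools the stratification pipeline needs — the
Kaplan–Meier product-limit estimator, the k-group log-rank test and Cox
proportional-hazards regression — directly on numpy arrays, so the cutoff
search can evaluate thousands of candidate splits without framework
overhead and every numerical convention (tie handling, risk-set rules,
convergence) is explicit and testable.

Conventions
-----------
* Subjects censored at an event time remain in the risk set at that time.
* Cox ties: Breslow by default, Efron as an option.
* Cox confidence intervals are Wald: exp(coef +/- z * SE).
* Non-convergence and suspected monotone likelihood (separation) are
  reported on the fit object, never silently ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


def _validate_times_events(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.ndim != 1 or times.shape != events.shape:
        raise ValueError("times and events must be 1D arrays of equal length")
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times < 0) or np.any(~np.isfinite(times)):
        raise ValueError("times must be finite and non-negative")
    if not np.all(np.isin(events, (0, 1))):
        raise ValueError("events must be 0/1")
    return times, events.astype(int)


def as_survival_arrays(y) -> tuple[np.ndarray, np.ndarray]:
    """Coerce a survival target into (times, events).

    Accepts a (times, events) tuple/list, an (n, 2) array with columns
    (time, event), a structured array with time/event-like fields, or a
    DataFrame with time/event columns.
    """
    if isinstance(y, tuple) or (isinstance(y, list) and len(y) == 2):
        times, events = y
        return _validate_times_events(times, events)
    if hasattr(y, "dtype") and getattr(y.dtype, "names", None):
        names = y.dtype.names
        tname = next(n for n in names if "time" in n.lower() or n.lower() in ("t", "futime"))
        ename = next(n for n in names if n != tname)
        # scikit-survival convention lists the event field first
        if np.issubdtype(y.dtype[tname], np.bool_):
            tname, ename = ename, tname
        return _validate_times_events(y[tname], y[ename].astype(int))
    if hasattr(y, "columns"):
        cols = list(y.columns)
        tcol = next(c for c in cols if "time" in c.lower())
        ecol = next(c for c in cols if "event" in c.lower())
        return _validate_times_events(y[tcol].to_numpy(), y[ecol].to_numpy())
    arr = np.asarray(y, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return _validate_times_events(arr[:, 0], arr[:, 1])
    raise ValueError("cannot interpret survival target; pass (times, events)")


@dataclass
class KMCurve:
    """Kaplan–Meier survival curve over the distinct event times."""

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) at each event time
    at_risk: np.ndarray        # n at risk just before each event time
    n_events: np.ndarray       # events at each event time
    censor_times: np.ndarray   # times of censored observations

    def survival_at(self, t: float | np.ndarray) -> np.ndarray | float:
        """Step-function value S(t); S = 1 before the first event."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        s = np.concatenate([[1.0], self.survival])[idx]
        return float(s) if s.ndim == 0 else s

    @property
    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5; nan if never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if below.size else float("nan")


def km_estimate(times, events) -> KMCurve:
    """Product-limit estimate of the survival function.

    S(t) = prod_{t_k <= t} (1 - d_k / n_k) over distinct event times t_k,
    with d_k events and n_k subjects at risk just before t_k.
    """
    times, events = _validate_times_events(times, events)
    order = np.argsort(times, kind="stable")
    t_sorted, e_sorted = times[order], events[order]
    event_times = np.unique(t_sorted[e_sorted == 1])
    # n at risk just before t_k: all subjects with observed time >= t_k
    n_at_risk = t_sorted.size - np.searchsorted(t_sorted, event_times, side="left")
    d = np.array(
        [np.sum((t_sorted == t) & (e_sorted == 1)) for t in event_times], dtype=int
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - d / n_at_risk)
    return KMCurve(
        times=event_times,
        survival=surv,
        at_risk=n_at_risk,
        n_events=d,
        censor_times=np.sort(times[events == 0]),
    )


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray
    group_labels: np.ndarray


def logrank_test(times, events, group) -> LogRankResult:
    """k-group log-rank test (observed-minus-expected over pooled event times).

    Chi-square statistic with df = k - 1; the variance uses the standard
    hypergeometric form with the multiplicity correction (n-d)/(n-1) for
    tied events.
    """
    times, events = _validate_times_events(times, events)
    group = np.asarray(group)
    if group.shape != times.shape:
        raise ValueError("group must align with times")
    labels, gidx = np.unique(group, return_inverse=True)
    k = labels.size
    if k < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(gidx, minlength=k)
    if np.any(counts == 0):
        raise ValueError("every group needs at least one subject")

    event_times = np.unique(times[events == 1])
    m = event_times.size
    # n_jk: group-j subjects at risk at t_k; d_jk: group-j events at t_k
    n_jk = np.empty((k, m))
    d_jk = np.zeros((k, m))
    for j in range(k):
        tj = np.sort(times[gidx == j])
        n_jk[j] = tj.size - np.searchsorted(tj, event_times, side="left")
        tj_ev = times[(gidx == j) & (events == 1)]
        if tj_ev.size:
            pos = np.searchsorted(event_times, tj_ev)
            np.add.at(d_jk[j], pos, 1.0)
    n_k = n_jk.sum(axis=0)
    d_k = d_jk.sum(axis=0)

    observed = d_jk.sum(axis=1)
    expected = (d_k * n_jk / n_k).sum(axis=1)

    # covariance of (O - E) restricted to the first k-1 groups
    with np.errstate(divide="ignore", invalid="ignore"):
        tie_factor = np.where(n_k > 1, (n_k - d_k) / (n_k - 1), 0.0)
    w = d_k * tie_factor
    P = n_jk / n_k  # (k, m) proportions at risk
    # V_ab = sum_k w_k (delta_ab P_a - P_a P_b)
    V = np.zeros((k - 1, k - 1))
    for a in range(k - 1):
        for b in range(k - 1):
            V[a, b] = np.sum(w * ((P[a] if a == b else 0.0) - P[a] * P[b]))

    oe = (observed - expected)[: k - 1]
    if m == 0 or not np.any(np.abs(oe) > 0):
        chi2 = 0.0
    else:
        try:
            chi2 = float(oe @ np.linalg.solve(V, oe))
        except np.linalg.LinAlgError:
            chi2 = float(oe @ np.linalg.pinv(V) @ oe)
    chi2 = max(chi2, 0.0)
    df = k - 1
    return LogRankResult(
        statistic=chi2,
        df=df,
        p_value=float(stats.chi2.sf(chi2, df)),
        observed=observed,
        expected=expected,
        group_labels=labels,
    )


@dataclass
class CoxFit:
    """Fitted Cox proportional-hazards model (partial likelihood)."""

    coef: np.ndarray
    se: np.ndarray
    hazard_ratio: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    z: np.ndarray
    p_value: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool
    ties: str
    covariate_names: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> "pd.DataFrame":  # noqa: F821 - lazy import
        import pandas as pd

        names = self.covariate_names or [f"x{i}" for i in range(self.coef.size)]
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "HR": self.hazard_ratio,
                "HR 95% CI lower": self.ci_lower,
                "HR 95% CI upper": self.ci_upper,
                "z": self.z,
                "p": self.p_value,
            },
            index=names,
        )


def _cox_loglik_grad_hess(
    beta: np.ndarray,
    X: np.ndarray,
    order: np.ndarray,
    tie_starts: np.ndarray,
    tie_counts: np.ndarray,
    event_rows: list[np.ndarray],
    ties: str,
):
    """Partial log-likelihood, score and Hessian under Breslow or Efron ties.

    ``order`` sorts subjects by descending time so risk sets are cumulative
    prefixes; ``event_rows[k]`` holds the (sorted-order) indices of events
    at the k-th distinct event time.
    """
    Xs = X[order]
    eta = Xs @ beta
    eta -= eta.max()  # guard exp overflow; constant shift cancels in ratios
    theta = np.exp(eta)
    # cumulative risk-set sums in sorted (descending-time) order
    S0_cum = np.cumsum(theta)
    S1_cum = np.cumsum(theta[:, None] * Xs, axis=0)
    S2_cum = np.cumsum(theta[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)

    p = X.shape[1]
    loglik = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    for k, rows in enumerate(event_rows):
        d = rows.size
        last = tie_starts[k] + tie_counts[k] - 1  # end of risk-set prefix
        S0 = S0_cum[last]
        S1 = S1_cum[last]
        S2 = S2_cum[last]
        x_sum = Xs[rows].sum(axis=0)
        eta_sum = eta[rows].sum()
        if ties == "breslow" or d == 1:
            loglik += eta_sum - d * np.log(S0)
            score += x_sum - d * S1 / S0
            info += d * (S2 / S0 - np.outer(S1, S1) / S0**2)
        else:  # efron
            th_d = theta[rows].sum()
            S1_d = (theta[rows, None] * Xs[rows]).sum(axis=0)
            S2_d = (theta[rows, None, None] * (Xs[rows, :, None] * Xs[rows, None, :])).sum(axis=0)
            loglik += eta_sum
            for ell in range(d):
                f = ell / d
                S0e = S0 - f * th_d
                S1e = S1 - f * S1_d
                S2e = S2 - f * S2_d
                loglik -= np.log(S0e)
                score -= S1e / S0e
                info += S2e / S0e - np.outer(S1e, S1e) / S0e**2
            score += x_sum
    return loglik, score, info


def cox_fit(
    times,
    events,
    covariates,
    ties: str = "breslow",
    covariate_names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-9,
    alpha: float = 0.05,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton–Raphson.

    Parameters
    ----------
    times, events : arrays (n,)
        Observed time and event indicator (1 = event, 0 = censored).
    covariates : array (n, p) or (n,)
        Covariate matrix; constant columns are rejected.
    ties : {"breslow", "efron"}
        Tied-event handling in the partial likelihood.
    tol : float
        Convergence on the relative change of the partial log-likelihood.

    Returns a :class:`CoxFit` with Wald confidence intervals
    exp(coef +/- z_{1-alpha/2} * SE).  Non-convergence sets
    ``converged=False``; a singular information matrix raises; suspected
    monotone likelihood (separation) appends a warning.
    """
    times, events = _validate_times_events(times, events)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n != times.size:
        raise ValueError("covariates must have one row per subject")
    if n <= p:
        raise ValueError(f"need n > p covariates (n={n}, p={p})")
    if events.sum() == 0:
        raise ValueError("no events observed; partial likelihood undefined")
    if np.any(X.std(axis=0) == 0):
        bad = np.nonzero(X.std(axis=0) == 0)[0].tolist()
        raise ValueError(f"constant covariate column(s) {bad}")
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")

    # center columns for numerical stability (coefficients are unaffected)
    x_mean = X.mean(axis=0)
    Xc = X - x_mean

    order = np.argsort(-times, kind="stable")  # descending time
    t_sorted = times[order]
    e_sorted = events[order]
    # group tied times: prefix of sorted order covers the risk set at each time
    uniq, tie_starts, tie_counts = np.unique(
        -t_sorted, return_index=True, return_counts=True
    )
    event_rows = []
    keep_starts, keep_counts = [], []
    for start, count in zip(tie_starts, tie_counts):
        rows = np.arange(start, start + count)
        ev = rows[e_sorted[rows] == 1]
        if ev.size:
            event_rows.append(ev)
            keep_starts.append(start)
            keep_counts.append(count)
    tie_starts = np.array(keep_starts)
    tie_counts = np.array(keep_counts)

    beta = np.zeros(p)
    loglik, score, info = _cox_loglik_grad_hess(
        beta, Xc, order, tie_starts, tie_counts, event_rows, ties
    )
    converged = False
    n_iter = 0
    fit_warnings: list[str] = []
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular information matrix (collinear covariates?)"
            ) from exc
        # step-halving on overshoot
        new_loglik = -np.inf
        for _ in range(30):
            candidate = beta + step
            new_loglik, new_score, new_info = _cox_loglik_grad_hess(
                candidate, Xc, order, tie_starts, tie_counts, event_rows, ties
            )
            if np.isfinite(new_loglik) and new_loglik >= loglik - 1e-12:
                break
            step /= 2.0
        rel_change = abs(new_loglik - loglik) / max(abs(loglik), 1.0)
        beta, loglik, score, info = candidate, new_loglik, new_score, new_info
        if rel_change < tol:
            converged = True
            break
    if not converged:
        fit_warnings.append(f"did not converge in {max_iter} iterations")
    if np.any(np.abs(beta) > 15):
        fit_warnings.append(
            "suspected monotone likelihood / separation: |coef| > 15"
        )

    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular information matrix at optimum") from exc
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    zcrit = stats.norm.ppf(1 - alpha / 2)
    with np.errstate(divide="ignore", over="ignore"):
        zstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        hr, lo, hi = np.exp(beta), np.exp(beta - zcrit * se), np.exp(beta + zcrit * se)
    return CoxFit(
        coef=beta,
        se=se,
        hazard_ratio=hr,
        ci_lower=lo,
        ci_upper=hi,
        z=zstat,
        p_value=2 * stats.norm.sf(np.abs(zstat)),
        log_likelihood=float(loglik),
        n_iter=n_iter,
        converged=converged,
        ties=ties,
        covariate_names=list(covariate_names or []),
        warnings=fit_warnings,
    )
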