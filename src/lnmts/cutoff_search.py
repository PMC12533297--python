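"""Survival-optimal dichotomization of a continuous biomarker.

The cutpoint for a feature (tLNV or tLND) is chosen by the maximally
selected log-rank procedure: the two-group log-rank statistic is evaluated
at every distinct observed feature value whose induced split ("at or
above" vs "below") leaves at least a configurable fraction of patients on
each side, and the value maximizing the statistic is returned (ties broken
toward the smaller cutoff).  The full candidate grid is retained for
audit.

Because the maximal statistic is selected over many candidate splits, its
nominal chi-square p-value is optimistic; :func:`permutation_pvalue`
provides an honest selection-adjusted p-value by re-running the search on
label-permuted data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .survival import as_survival_arrays, _validate_times_events


@dataclass
class CutoffResult:
    """Learned threshold plus the evidence behind it."""

    feature_name: str
    cutoff: float
    statistic: float
    endpoint: str
    grid: pd.DataFrame  # columns: value, statistic, n_below, n_above
    permutation_p: float | None = None


def _candidate_grid_stats(
    values: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    min_group_frac: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Two-group log-rank chi-square at every admissible candidate cutoff.

    Vectorized over candidates: with R the (event-time x subject) at-risk
    indicator, E the event indicator and F the (subject x candidate)
    "at or above" indicator, the per-candidate risk-set and event counts
    of the upper group are the matrix products R @ F and E @ F.

    Returns (candidates, chi2, n_below, n_above).
    """
    n = values.size
    candidates = np.unique(values)
    n_above = (values[:, None] >= candidates[None, :]).sum(axis=0)
    n_below = n - n_above
    min_size = min_group_frac * n
    admissible = (n_above >= min_size) & (n_below >= min_size)
    candidates = candidates[admissible]
    if candidates.size == 0:
        raise ValueError(
            f"no admissible candidate cutoff (n={n}, min_group_frac={min_group_frac})"
        )

    event_times = np.unique(times[events == 1])
    R = (times[None, :] >= event_times[:, None]).astype(float)
    E = ((times[None, :] == event_times[:, None]) & (events[None, :] == 1)).astype(float)
    F = (values[:, None] >= candidates[None, :]).astype(float)

    n_k = R.sum(axis=1)            # total at risk at each event time
    d_k = E.sum(axis=1)            # total events at each event time
    n1 = R @ F                     # (m, J) upper-group at risk
    d1 = E @ F                     # (m, J) upper-group events

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = n1 / n_k[:, None]
        tie = np.where(n_k > 1, (n_k - d_k) / (n_k - 1), 0.0)
        oe = (d1 - d_k[:, None] * frac).sum(axis=0)
        var = (d_k * tie)[:, None] * frac * (1.0 - frac)
        var = var.sum(axis=0)
        chi2 = np.where(var > 0, oe**2 / var, 0.0)
    return candidates, chi2, n - F.sum(axis=0).astype(int), F.sum(axis=0).astype(int)


def find_optimal_cutoff(
    values,
    times,
    events,
    min_group_frac: float = 0.10,
    endpoint: str = "os",
    feature_name: str = "feature",
) -> CutoffResult:
    """Maximally selected log-rank cutoff for one continuous feature.

    Requires at least 20 subjects, at least one event and at least two
    distinct feature values.  The returned cutoff is an observed feature
    value; patients with feature >= cutoff form the upper group.
    """
    values = np.asarray(values, dtype=float)
    times, events = _validate_times_events(times, events)
    if values.shape != times.shape:
        raise ValueError("values must align with times")
    if values.size < 20:
        raise ValueError(f"need n >= 20 subjects, got {values.size}")
    if not np.all(np.isfinite(values)):
        raise ValueError("feature values must be finite")
    if events.sum() < 1:
        raise ValueError("need at least one event")
    if np.unique(values).size < 2:
        raise ValueError("feature must take at least two distinct values")

    candidates, chi2, n_below, n_above = _candidate_grid_stats(
        values, times, events, min_group_frac
    )
    best = int(np.argmax(chi2))  # first max -> smallest cutoff on ties
    grid = pd.DataFrame(
        {"value": candidates, "statistic": chi2, "n_below": n_below, "n_above": n_above}
    )
    return CutoffResult(
        feature_name=feature_name,
        cutoff=float(candidates[best]),
        statistic=float(chi2[best]),
        endpoint=endpoint,
        grid=grid,
    )


def permutation_pvalue(
    values,
    times,
    events,
    n_perm: int = 200,
    seed: int = 0,
    min_group_frac: float = 0.10,
) -> float:
    """Selection-adjusted p-value for the maximal log-rank statistic.

    Permutes the feature values against the (time, event) pairs, re-runs
    the full cutoff search each time, and reports the add-one-corrected
    fraction of permuted maxima at or above the observed maximum:
    p = (1 + #{perm >= obs}) / (n_perm + 1), hence p in [1/(n_perm+1), 1].
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    values = np.asarray(values, dtype=float)
    times, events = _validate_times_events(times, events)
    _, chi2, _, _ = _candidate_grid_stats(values, times, events, min_group_frac)
    observed = chi2.max()
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(values.size)
        _, chi2_p, _, _ = _candidate_grid_stats(
            values[perm], times, events, min_group_frac
        )
        if chi2_p.max() >= observed:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


class MaximallySelectedCutoff(BaseEstimator):
    """Estimator wrapper around the maximally selected log-rank search.

    Parameters
    ----------
    min_group_frac : float
        Minimum fraction of subjects each side of a candidate split must
        retain (guards against extreme, unstable cutoffs).
    endpoint : str
        Label recorded on the result ("os" or "dfs"); the caller supplies
        the matching times/events.
    n_permutations : int
        If > 0, a permutation p-value is computed during fit.
    random_state : int
        Seed for the permutation test.

    Attributes
    ----------
    cutoff_ : float
        Learned threshold (an observed feature value; upper side inclusive).
    statistic_ : float
        Two-group log-rank chi-square at the learned threshold.
    result_ : CutoffResult
        Full result including the candidate-grid audit trail.
    """

    def __init__(
        self,
        min_group_frac: float = 0.10,
        endpoint: str = "os",
        n_permutations: int = 0,
        random_state: int = 0,
    ):
        self.min_group_frac = min_group_frac
        self.endpoint = endpoint
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, X, y) -> "MaximallySelectedCutoff":
        x = np.asarray(X, dtype=float).squeeze()
        if x.ndim != 1:
            raise ValueError("MaximallySelectedCutoff handles a single feature")
        times, events = as_survival_arrays(y)
        result = find_optimal_cutoff(
            x, times, events, min_group_frac=self.min_group_frac, endpoint=self.endpoint
        )
        if self.n_permutations > 0:
            result.permutation_p = permutation_pvalue(
                x,
                times,
                events,
                n_perm=self.n_permutations,
                seed=self.random_state,
                min_group_frac=self.min_group_frac,
            )
        self.result_ = result
        self.cutoff_ = result.cutoff
        self.statistic_ = result.statistic
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        """Dichotomize: 1 for feature >= cutoff_, else 0."""
        check_is_fitted(self, "cutoff_")
        x = np.asarray(X, dtype=float).squeeze()
        return (x >= self.cutoff_).astype(int).reshape(-1, 1)
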