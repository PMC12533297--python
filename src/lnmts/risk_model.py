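"""Three-tier prognostic risk subtypes from dichotomized imaging features.

Patients are classified on the 2x2 grid of dichotomized total lymph-node
volume (tLNV) and total drainage distance (tLND):

======== ========= =========
         D-tLND    N-tLND
======== ========= =========
L-tLNV   LRS       MRS
S-tLNV   MRS       HRS
======== ========= =========

i.e. large total volume *and* distant total drainage are jointly favorable
(low-risk subtype), both small/near is high-risk, and the mixed cells are
moderate-risk.  Boundary convention: the favorable side is inclusive —
a feature exactly at its cutoff counts as L-tLNV / D-tLND.  This applies
everywhere (classification, cutoff transfer, reports) and is printed in
every report header.

The published cutoff pair (71.5 mm^3 for tLNV, 140.5 mm for tLND) is
shipped as the named configuration ``paper-2025`` for apply-only runs; it
is a transferred constant, not re-derived here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .cutoff_search import CutoffResult, MaximallySelectedCutoff
from .survival import CoxFit, KMCurve, as_survival_arrays, cox_fit, km_estimate, logrank_test

SUBTYPES = ("LRS", "MRS", "HRS")
FIVE_YEAR_DAYS = 1826.0
BOUNDARY_NOTE = "boundary convention: tLNV >= cutoff -> L-tLNV, tLND >= cutoff -> D-tLND (favorable side inclusive)"

#: published cutoffs (mm^3, mm), transferred for apply-only use
NAMED_CUTOFFS = {"paper-2025": {"tlnv": 71.5, "tlnd": 140.5}}


def component_labels(tlnv: float, tlnd: float, cutoff_tlnv: float, cutoff_tlnd: float) -> tuple[str, str]:
    """Dichotomized component labels (S/L-tLNV, N/D-tLND) for one patient."""
    for name, value in (("tLNV", tlnv), ("tLND", tlnd)):
        if value is None or not np.isfinite(value):
            raise ValueError(f"missing or non-finite {name}; no imputation is performed")
    v = "L-tLNV" if tlnv >= cutoff_tlnv else "S-tLNV"
    d = "D-tLND" if tlnd >= cutoff_tlnd else "N-tLND"
    return v, d


def classify(tlnv: float, tlnd: float, cutoff_tlnv: float, cutoff_tlnd: float) -> str:
    """Risk subtype for one patient: LRS, MRS or HRS (see module docs)."""
    v, d = component_labels(tlnv, tlnd, cutoff_tlnv, cutoff_tlnd)
    if v == "L-tLNV" and d == "D-tLND":
        return "LRS"
    if v == "S-tLNV" and d == "N-tLND":
        return "HRS"
    return "MRS"


class RiskStratifier(BaseEstimator, ClassifierMixin):
    """Two-feature, three-tier prognostic risk classifier.

    ``fit`` learns survival-optimal cutoffs for tLNV and tLND on a
    training cohort by maximally selected log-rank (unless explicit
    cutoffs are given, e.g. ``cutoffs="paper-2025"``); ``predict`` maps
    feature pairs to subtypes {LRS, MRS, HRS}.

    Parameters
    ----------
    cutoffs : None, str or dict
        ``None`` — learn both cutoffs during fit; a named configuration
        (``"paper-2025"``); or ``{"tlnv": float, "tlnd": float}``.
    min_group_frac : float
        Candidate-split group-size guard for the cutoff search.
    endpoint : str
        Endpoint label used for the search ("os" by default).

    Attributes
    ----------
    cutoff_tlnv_, cutoff_tlnd_ : float
        Thresholds applied by predict (favorable side inclusive).
    cutoff_results_ : dict[str, CutoffResult]
        Audit trail of the search (empty when cutoffs were supplied).
    """

    def __init__(
        self,
        cutoffs: str | dict[str, float] | None = None,
        min_group_frac: float = 0.10,
        endpoint: str = "os",
    ):
        self.cutoffs = cutoffs
        self.min_group_frac = min_group_frac
        self.endpoint = endpoint

    @staticmethod
    def _feature_arrays(X) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(X, pd.DataFrame):
            missing = {"tlnv", "tlnd"} - set(X.columns)
            if missing:
                raise ValueError(f"feature table lacks column(s) {sorted(missing)}")
            return X["tlnv"].to_numpy(float), X["tlnd"].to_numpy(float)
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("X must be a DataFrame with tlnv/tlnd or an (n, 2) array")
        return arr[:, 0], arr[:, 1]

    def fit(self, X, y=None) -> "RiskStratifier":
        tlnv, tlnd = self._feature_arrays(X)
        self.cutoff_results_: dict[str, CutoffResult] = {}
        if self.cutoffs is not None:
            resolved = (
                NAMED_CUTOFFS[self.cutoffs]
                if isinstance(self.cutoffs, str)
                else dict(self.cutoffs)
            )
            self.cutoff_tlnv_ = float(resolved["tlnv"])
            self.cutoff_tlnd_ = float(resolved["tlnd"])
        else:
            if y is None:
                raise ValueError("survival target y is required to learn cutoffs")
            times, events = as_survival_arrays(y)
            for name, values in (("tlnv", tlnv), ("tlnd", tlnd)):
                selector = MaximallySelectedCutoff(
                    min_group_frac=self.min_group_frac, endpoint=self.endpoint
                ).fit(values, (times, events))
                self.cutoff_results_[name] = selector.result_
                self.cutoff_results_[name].feature_name = name
            self.cutoff_tlnv_ = self.cutoff_results_["tlnv"].cutoff
            self.cutoff_tlnd_ = self.cutoff_results_["tlnd"].cutoff
        self.classes_ = np.array(SUBTYPES)
        self.n_features_in_ = 2
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "cutoff_tlnv_")
        tlnv, tlnd = self._feature_arrays(X)
        return np.array(
            [
                classify(v, d, self.cutoff_tlnv_, self.cutoff_tlnd_)
                for v, d in zip(tlnv, tlnd)
            ]
        )


@dataclass
class StratifiedReport:
    """Per-subtype survival summary of a classified cohort."""

    endpoint: str
    boundary_note: str
    km_curves: dict[str, KMCurve]
    five_year: pd.DataFrame          # subtype, n, events, rate (NaN = not reached)
    logrank_global: dict | None      # statistic, df, p (None if < 2 subtypes)
    logrank_pairwise: pd.DataFrame
    cox_unadjusted: CoxFit | None
    cox_adjusted: CoxFit | None
    absent_subtypes: list[str] = field(default_factory=list)

    def cox_table(self) -> pd.DataFrame:
        frames = []
        if self.cox_unadjusted is not None:
            t = self.cox_unadjusted.summary()
            t.insert(0, "model", "unadjusted")
            frames.append(t)
        if self.cox_adjusted is not None:
            t = self.cox_adjusted.summary()
            t.insert(0, "model", "adjusted")
            frames.append(t)
        return pd.concat(frames) if frames else pd.DataFrame()

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = f"# endpoint: {self.endpoint}\n# {self.boundary_note}\n"
        for name, df in (
            ("five_year", self.five_year),
            ("logrank_pairwise", self.logrank_pairwise),
            ("cox", self.cox_table().reset_index(names="contrast") if not self.cox_table().empty else pd.DataFrame()),
        ):
            path = outdir / f"{self.endpoint}_{name}.csv"
            with open(path, "w") as fh:
                fh.write(header)
                df.to_csv(fh, index=False)
        km_rows = []
        for subtype, curve in self.km_curves.items():
            for t, s, n, d in zip(curve.times, curve.survival, curve.at_risk, curve.n_events):
                km_rows.append(
                    {"subtype": subtype, "time": t, "survival": s, "at_risk": n, "events": d}
                )
        with open(outdir / f"{self.endpoint}_km.csv", "w") as fh:
            fh.write(header)
            pd.DataFrame(km_rows).to_csv(fh, index=False)

    def plot_km(self, path: str | Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4.5))
        for subtype in SUBTYPES:
            if subtype not in self.km_curves:
                continue
            curve = self.km_curves[subtype]
            t = np.concatenate([[0.0], np.repeat(curve.times, 2)])
            s = np.concatenate([[1.0, 1.0], np.repeat(curve.survival, 2)[:-1]])
            ax.plot(t, s, label=subtype, drawstyle="steps-post")
        ax.set_xlabel("time (days)")
        ax.set_ylabel(f"{self.endpoint.upper()} probability")
        ax.set_ylim(0, 1.02)
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _five_year_rate(curve: KMCurve, at_days: float) -> float:
    """KM estimate at ``at_days``; NaN ("not reached") if follow-up is shorter."""
    last_observed = max(
        curve.times.max() if curve.times.size else 0.0,
        curve.censor_times.max() if curve.censor_times.size else 0.0,
    )
    if last_observed < at_days:
        return float("nan")
    return float(curve.survival_at(at_days))


def stratified_report(
    cohort: pd.DataFrame,
    subtype_col: str = "subtype",
    time_col: str = "os_time",
    event_col: str = "os_event",
    endpoint: str = "os",
    covariate_cols: list[str] | None = None,
    at_days: float = FIVE_YEAR_DAYS,
) -> StratifiedReport:
    """Survival summary of a subtype-classified cohort.

    Produces per-subtype Kaplan–Meier curves, 5-year survival rates (KM
    estimate at 1826 days; "not reached" when a group's follow-up ends
    earlier), the global and pairwise log-rank tests over the subtypes
    present, and Cox hazard ratios for MRS vs LRS and HRS vs LRS, with and
    (if ``covariate_cols`` is given) without adjustment.  Absent subtypes
    are reported as absent and their contrasts skipped.
    """
    times = cohort[time_col].to_numpy(float)
    events = cohort[event_col].to_numpy(int)
    subtype = cohort[subtype_col].to_numpy()
    present = [s for s in SUBTYPES if np.any(subtype == s)]
    absent = [s for s in SUBTYPES if s not in present]

    km_curves = {
        s: km_estimate(times[subtype == s], events[subtype == s]) for s in present
    }
    five_year = pd.DataFrame(
        [
            {
                "subtype": s,
                "n": int(np.sum(subtype == s)),
                "events": int(events[subtype == s].sum()),
                f"{endpoint}_rate_{int(at_days)}d": _five_year_rate(km_curves[s], at_days),
            }
            for s in present
        ]
    )

    logrank_global = None
    if len(present) >= 2:
        mask = np.isin(subtype, present)
        res = logrank_test(times[mask], events[mask], subtype[mask])
        logrank_global = {"statistic": res.statistic, "df": res.df, "p": res.p_value}
    pair_rows = []
    for i, a in enumerate(present):
        for b in present[i + 1:]:
            mask = np.isin(subtype, [a, b])
            res = logrank_test(times[mask], events[mask], subtype[mask])
            pair_rows.append(
                {"group_a": a, "group_b": b, "statistic": res.statistic, "p": res.p_value}
            )
    logrank_pairwise = pd.DataFrame(pair_rows)

    cox_unadjusted = cox_adjusted = None
    if "LRS" in present and len(present) >= 2:
        mask = np.isin(subtype, present)
        dummies = []
        names = []
        for s in ("MRS", "HRS"):
            if s in present:
                dummies.append((subtype[mask] == s).astype(float))
                names.append(f"{s} vs LRS")
        X = np.column_stack(dummies)
        try:
            cox_unadjusted = cox_fit(times[mask], events[mask], X, covariate_names=names)
        except (ValueError, np.linalg.LinAlgError):
            cox_unadjusted = None
        if covariate_cols:
            Xadj = np.column_stack(
                [X] + [cohort.loc[mask, c].to_numpy(float) for c in covariate_cols]
            )
            try:
                cox_adjusted = cox_fit(
                    times[mask], events[mask], Xadj,
                    covariate_names=names + list(covariate_cols),
                )
            except (ValueError, np.linalg.LinAlgError):
                cox_adjusted = None

    return StratifiedReport(
        endpoint=endpoint,
        boundary_note=BOUNDARY_NOTE,
        km_curves=km_curves,
        five_year=five_year,
        logrank_global=logrank_global,
        logrank_pairwise=logrank_pairwise,
        cox_unadjusted=cox_unadjusted,
        cox_adjusted=cox_adjusted,
        absent_subtypes=absent,
    )
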