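"""Survival stratification: Kaplan-Meier, log-rank family, hazard ratios.

Disease-free survival (DFS, days from resection to recurrence or censoring)
is compared between prognosis groups with the product-limit estimator and
the weighted observed-minus-expected family of tests: standard log-rank
(Mantel-Cox, unit weights), Gehan-Breslow-Wilcoxon (at-risk weights) and the
log-rank test for trend over ordered groups (scores 1..k, 1 df).  The hazard
ratio is the O/E (Pike) estimator with a log-scale confidence interval,
matching the reporting style of the tests; an adjusted Cox proportional
hazards fit is available as a secondary analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in records.columns:
            raise ValueError(f"survival records need a {col!r} column")
    if (records["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    return records


@dataclass
class KMResult:
    """Product-limit estimate with its at-risk table."""

    table: pd.DataFrame  # index time; columns at_risk, events, censored, survival
    median: float  # earliest time with S(t) <= 0.5; nan if never reached

    def survival_at(self, t: float) -> float:
        prior = self.table.index[self.table.index <= t]
        if len(prior) == 0:
            return 1.0
        return float(self.table.loc[prior[-1], "survival"])


def km_estimate(records: pd.DataFrame) -> KMResult:
    """Kaplan-Meier product-limit estimator with at-risk table and median.

    At tied times events are processed before censorings (standard
    convention).  The median is the earliest time at which the survival
    function falls to 0.5 or below, NaN if it never does.
    """
    records = _validate_records(records)
    if len(records) == 0:
        raise ValueError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], records["event"])
    ev = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index else kmf.event_table
    sf = kmf.survival_function_["KM_estimate"]
    table = pd.DataFrame(
        {
            "at_risk": ev["at_risk"].astype(int),
            "events": ev["observed"].astype(int),
            "censored": ev["censored"].astype(int),
            "survival": sf.reindex(ev.index).to_numpy(),
        }
    )
    median = kmf.median_survival_time_
    median = float(median) if np.isfinite(median) else float("nan")
    return KMResult(table=table, median=median)


# ---------------------------------------------------------------------------
# weighted O-E tests


def _event_grid(groups: dict[str, pd.DataFrame]):
    """Per-event-time at-risk/death counts per group.

    Returns (times, n_gt, d_gt, labels): arrays over distinct event times
    with group-wise numbers at risk and deaths.
    """
    labels = list(groups)
    times_all = []
    for lab in labels:
        rec = _validate_records(groups[lab])
        if len(rec) == 0:
            raise ValueError(f"group {lab!r} has no subjects")
        times_all.append(rec)
    event_times = np.unique(
        np.concatenate(
            [r.loc[r["event"] == 1, "time"].to_numpy(float) for r in times_all]
        )
    )
    k = len(labels)
    n_gt = np.zeros((k, len(event_times)))
    d_gt = np.zeros((k, len(event_times)))
    for g, rec in enumerate(times_all):
        t = rec["time"].to_numpy(float)
        e = rec["event"].to_numpy(int)
        for j, et in enumerate(event_times):
            n_gt[g, j] = (t >= et).sum()
            d_gt[g, j] = ((t == et) & (e == 1)).sum()
    return event_times, n_gt, d_gt, labels


def _oe_vectors(n_gt: np.ndarray, d_gt: np.ndarray, weights: np.ndarray):
    """Weighted O-E vector and covariance over event times."""
    k, m = n_gt.shape
    n_t = n_gt.sum(axis=0)
    d_t = d_gt.sum(axis=0)
    z = np.zeros(k)
    V = np.zeros((k, k))
    for j in range(m):
        n, d, w = n_t[j], d_t[j], weights[j]
        if n <= 0 or d == 0:
            continue
        e = n_gt[:, j] * d / n
        z += w * (d_gt[:, j] - e)
        if n > 1:
            # multivariate hypergeometric: Cov(d_g, d_h) =
            # d (n - d) / (n - 1) * (p_g delta_gh - p_g p_h)
            c = d * (n - d) / (n - 1)
            p = n_gt[:, j] / n
            V += w**2 * c * (np.diag(p) - np.outer(p, p))
    return z, V


def logrank_family(
    groups: dict[str, pd.DataFrame], weights: str = "logrank"
) -> dict:
    """Weighted log-rank comparison of k survival groups.

    ``weights`` is one of ``'logrank'`` (unit weights, Mantel-Cox),
    ``'gehan_breslow_wilcoxon'`` (weight = total number at risk) or
    ``'trend'`` (unit weights with ordered group scores 1..k, 1 df; group
    order follows the mapping order).  Returns chi2, df, p, and the per-group
    observed and expected event counts (unweighted).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    times, n_gt, d_gt, labels = _event_grid(groups)
    n_t = n_gt.sum(axis=0)
    if weights == "gehan_breslow_wilcoxon":
        w = n_t.astype(float)
    elif weights in ("logrank", "trend"):
        w = np.ones_like(n_t, dtype=float)
    else:
        raise ValueError(f"unknown weights {weights!r}")
    z, V = _oe_vectors(n_gt, d_gt, w)
    zu, _ = _oe_vectors(n_gt, d_gt, np.ones_like(w))
    d_t = d_gt.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = np.nansum(
            np.where(n_t > 0, n_gt * d_t / n_t, 0.0), axis=1
        )
    observed = d_gt.sum(axis=1)

    k = len(labels)
    if weights == "trend":
        scores = np.arange(1, k + 1, dtype=float)
        num = float(scores @ z) ** 2
        den = float(scores @ V @ scores)
        chi2 = num / den if den > 0 else 0.0
        df = 1
    else:
        zz = z[: k - 1]
        VV = V[: k - 1, : k - 1]
        try:
            chi2 = float(zz @ np.linalg.solve(VV, zz))
        except np.linalg.LinAlgError:
            chi2 = float(zz @ np.linalg.pinv(VV) @ zz)
        df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    assert abs(zu.sum()) < 1e-8, "O-E must sum to zero across groups"
    return {
        "chi2": chi2,
        "df": df,
        "p": p,
        "observed": dict(zip(labels, observed)),
        "expected": dict(zip(labels, expected)),
    }


def hazard_ratio(
    groups: dict[str, pd.DataFrame], conf: float = 0.95, method: str = "cox"
) -> dict:
    """Hazard ratio of the first group relative to the second.

    ``method='cox'`` (default) fits a one-covariate Cox proportional-hazards
    model by Newton-Raphson partial likelihood, which is close to unbiased
    even for large effects.  ``method='pike'`` returns the O/E estimator
    HR = (O1/E1)/(O2/E2) with SE(log HR) = sqrt(1/E1 + 1/E2), the form often
    reported alongside Mantel-Cox tests; note it is pulled toward 1 when the
    true hazard ratio is far from 1.  The CI is on the log scale either way.
    A group with zero events yields an undefined HR, flagged rather than
    raised.
    """
    if len(groups) != 2:
        raise ValueError("hazard_ratio takes exactly two groups")
    labels = list(groups)
    res = logrank_family(groups, weights="logrank")
    o1, o2 = (res["observed"][lab] for lab in labels)
    undefined = {
        "hr": float("nan"), "ci": (float("nan"), float("nan")),
        "defined": False, "reference": labels[1], "method": method,
    }
    if o1 == 0 or o2 == 0:
        return undefined
    zq = stats.norm.ppf(0.5 + conf / 2)
    if method == "pike":
        e1, e2 = (res["expected"][lab] for lab in labels)
        hr = (o1 / e1) / (o2 / e2)
        se = np.sqrt(1 / e1 + 1 / e2)
    elif method == "cox":
        df = pd.concat(
            [
                groups[labels[0]][["time", "event"]].assign(_g=1),
                groups[labels[1]][["time", "event"]].assign(_g=0),
            ],
            ignore_index=True,
        )
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        hr = float(np.exp(cph.params_["_g"]))
        se = float(cph.standard_errors_["_g"])
    else:
        raise ValueError(f"unknown method {method!r}")
    ci = (float(hr * np.exp(-zq * se)), float(hr * np.exp(zq * se)))
    return {
        "hr": float(hr), "ci": ci, "defined": True,
        "reference": labels[1], "method": method,
    }


# ---------------------------------------------------------------------------
# stratifications


@dataclass
class StratifiedCohort:
    """Ordered disjoint survival groups with their comparison statistics."""

    groups: dict[str, pd.DataFrame]
    order: list[str]
    medians: dict[str, float] = field(default_factory=dict)
    tests: dict = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)

    def group_sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.groups.items()}

    def group_fractions(self) -> dict[str, float]:
        n = sum(len(v) for v in self.groups.values())
        return {k: len(v) / n for k, v in self.groups.items()}


def _join(scores: pd.Series, records: pd.DataFrame) -> pd.DataFrame:
    missing = scores.index.difference(records.index)
    if len(missing) > 0:
        raise ValueError(f"patients without survival records: {list(missing)}")
    return records.loc[scores.index]


def median_split_stratify(
    scores: pd.Series, records: pd.DataFrame, cohort_median: float | None = None
) -> StratifiedCohort:
    """Two-group stratification at the cohort-median Prognosis Score.

    Patients above the median form the good-prognosis group.  Runs log-rank,
    Gehan-Breslow-Wilcoxon and the Pike hazard ratio (poor relative to good,
    so HR > 1 means worse outcome in the poor group) and reports per-group
    median DFS; with fewer than two patients in a group the tests are
    refused with a warning.
    """
    from .array import classify_patients

    records = _join(scores, records)
    calls = classify_patients(scores, cohort_median)
    groups = {
        "good": records.loc[calls.index[calls["call"] == "good"]],
        "poor": records.loc[calls.index[calls["call"] == "poor"]],
    }
    strat = StratifiedCohort(groups=groups, order=["good", "poor"])
    for lab, rec in groups.items():
        strat.medians[lab] = km_estimate(rec).median if len(rec) else float("nan")
    if min(len(g) for g in groups.values()) < 2:
        warnings.warn("a group has fewer than 2 patients; tests refused",
                      stacklevel=2)
        strat.tests = {}
        return strat
    strat.tests = {
        "logrank": logrank_family(groups, "logrank"),
        "gehan_breslow_wilcoxon": logrank_family(groups, "gehan_breslow_wilcoxon"),
        "hazard_ratio": hazard_ratio({"poor": groups["poor"], "good": groups["good"]}),
    }
    return strat


COMBINED_ORDER = [
    "good_hnf1b_pos", "good_hnf1b_neg", "poor_hnf1b_pos", "poor_hnf1b_neg"
]


def combined_stratify(
    scores: pd.Series,
    hnf1b_nuclear: pd.Series,
    records: pd.DataFrame,
    cohort_median: float | None = None,
) -> StratifiedCohort:
    """Four-group stratification: Prognosis Score split x HNF1b nuclear status.

    Group order (best to worst expected outcome): good score + HNF1b
    nuclear-positive, good + negative, poor + positive, poor + negative.
    Patients missing either marker are excluded and reported.  Runs the
    log-rank test and the test for trend over the ordered groups; the trend
    test refuses (with a warning) when any group is empty.
    """
    have = scores.dropna().index.intersection(hnf1b_nuclear.dropna().index)
    excluded = sorted(
        set(scores.index).union(hnf1b_nuclear.index).difference(have)
    )
    scores = scores.loc[have]
    records = _join(scores, records)
    from .array import classify_patients

    calls = classify_patients(scores, cohort_median)
    labels = pd.Series(index=have, dtype=object)
    for pid in have:
        call = calls.loc[pid, "call"]
        pos = bool(hnf1b_nuclear.loc[pid])
        labels[pid] = f"{call}_hnf1b_{'pos' if pos else 'neg'}"
    groups = {
        lab: records.loc[labels.index[labels == lab]] for lab in COMBINED_ORDER
    }
    strat = StratifiedCohort(
        groups=groups, order=list(COMBINED_ORDER), excluded=list(excluded)
    )
    for lab, rec in groups.items():
        strat.medians[lab] = km_estimate(rec).median if len(rec) else float("nan")
    nonempty = {k: v for k, v in groups.items() if len(v) > 0}
    if len(nonempty) < 2 or any(len(v) == 0 for v in groups.values()):
        warnings.warn("empty stratum; trend test refused", stacklevel=2)
        strat.tests = (
            {"logrank": logrank_family(nonempty)} if len(nonempty) >= 2 else {}
        )
        return strat
    strat.tests = {
        "logrank": logrank_family(groups, "logrank"),
        "trend": logrank_family(groups, "trend"),
    }
    return strat


def cox_adjusted(
    records: pd.DataFrame, group_col: str, covariates: list[str]
) -> pd.DataFrame:
    """Secondary Cox proportional-hazards fit adjusting for covariates.

    Returns the coefficient table (log HR, se, p) from a Newton-Raphson
    partial-likelihood fit.
    """
    df = records[["time", "event", group_col, *covariates]].copy()
    if df[group_col].dtype == object:
        df[group_col] = (df[group_col] == df[group_col].unique()[0]).astype(int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return cph.summary
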