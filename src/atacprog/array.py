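"""ATAC-array scoring: two-channel normalization and the Prognosis Score.

The array tiles differential-accessibility signature regions with probes in
four classes: RED (regions open in recurrent/poor-prognosis tumors), BLUE
(open in non-recurrent/good-prognosis tumors), GREEN (positive controls,
open in all tumors) and BLACK (aCGH backbone negative controls).  A sample's
ATAC library is hybridized in the Cy5 channel against reference genomic DNA
in Cy3; per-probe intensities are normalized as cy5/cy3 and each class is
summarized by its median.  The Prognosis Score is

    blue_score = BLUE / (CTRL - CGH)

with CTRL the GREEN median and CGH the BLACK median; patients scoring above
the cohort median carry the good-prognosis signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

PROBE_CLASSES = ("RED", "BLUE", "GREEN", "BLACK")


def validate_probes(probes: pd.DataFrame) -> pd.DataFrame:
    """Check probe table columns and class labels; returns the table."""
    required = {"probe_id", "klass"}
    missing = required - set(probes.columns)
    if missing:
        raise ValueError(f"probe table missing columns: {sorted(missing)}")
    bad = set(probes["klass"]) - set(PROBE_CLASSES)
    if bad:
        raise ValueError(f"unknown probe classes: {sorted(bad)}")
    return probes


def probe_bookkeeping(probes: pd.DataFrame) -> dict:
    """Per-class probe and region counts; signature regions = RED + BLUE."""
    validate_probes(probes)
    out = {"probes": probes["klass"].value_counts().to_dict()}
    if "region_id" in probes.columns:
        regions = probes.groupby("klass")["region_id"].nunique().to_dict()
        out["regions"] = regions
        out["signature_regions"] = regions.get("RED", 0) + regions.get("BLUE", 0)
    return out


def design_probes(
    regions: pd.DataFrame,
    probes_per_region: int = 5,
    probe_length: int = 60,
) -> pd.DataFrame:
    """Tile each region with evenly spaced fixed-length probes (plumbing).

    ``regions`` needs columns ``region_id, chrom, start, end, klass``.
    Regions shorter than ``probe_length`` get a single centered probe clipped
    to the region.
    """
    rows = []
    for r in regions.itertuples(index=False):
        span = r.end - r.start
        k = max(1, probes_per_region)
        for j in range(k):
            if span <= probe_length:
                s, e = r.start, r.end
            else:
                offset = round(j * (span - probe_length) / max(1, k - 1))
                s = r.start + offset
                e = s + probe_length
            rows.append(
                (f"{r.region_id}_p{j}", r.chrom, s, e, r.klass, r.region_id)
            )
    return pd.DataFrame(
        rows, columns=["probe_id", "chrom", "start", "end", "klass", "region_id"]
    )


def normalize_scan(scan: pd.DataFrame, scale: str = "linear") -> pd.Series:
    """Per-probe normalized intensity cy5/cy3 (or its log2).

    The Cy3 reference channel controls hybridization efficiency per probe.
    Probes with cy3 <= 0 are dropped with a warning reporting the count;
    cy5 must be positive for the log2 scale.
    """
    bad = scan["cy3"] <= 0
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} probe(s) with nonpositive cy3",
            stacklevel=2,
        )
        scan = scan[~bad]
    ratio = scan["cy5"].to_numpy(float) / scan["cy3"].to_numpy(float)
    if scale == "linear":
        vals = ratio
    elif scale == "log2":
        if (ratio <= 0).any():
            raise ValueError("nonpositive ratio; cannot take log2")
        vals = np.log2(ratio)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return pd.Series(vals, index=scan["probe_id"].to_numpy(), name="normalized")


@dataclass
class ClassMedians:
    """Median normalized intensity per probe class."""

    ctrl: float  # GREEN median (positive control)
    cgh: float  # BLACK median (aCGH backbone, negative control)
    blue: float
    red: float


def class_medians(normalized: pd.Series, probes: pd.DataFrame) -> ClassMedians:
    """Median normalized intensity per class (even n: mean of central pair)."""
    validate_probes(probes)
    klass = probes.set_index("probe_id")["klass"]
    common = normalized.index.intersection(klass.index)
    meds = {}
    for c in PROBE_CLASSES:
        vals = normalized[common[klass[common] == c]]
        if len(vals) == 0:
            raise ValueError(f"no probes with intensities in class {c}")
        meds[c] = float(np.median(vals))
    return ClassMedians(
        ctrl=meds["GREEN"], cgh=meds["BLACK"], blue=meds["BLUE"], red=meds["RED"]
    )


@dataclass
class PrognosisScore:
    """Control-normalized class-median ratios for one array."""

    blue_score: float  # BLUE / (CTRL - CGH)
    red_score: float  # RED / (CTRL - CGH)
    diff_score: float  # (BLUE - RED) / (CTRL - CGH)


def prognosis_score(m: ClassMedians) -> PrognosisScore:
    """Prognosis Score variants from the class medians.

    Requires CTRL > CGH: a positive-control median at or below the negative
    control marks an invalid array.
    """
    denom = m.ctrl - m.cgh
    if denom <= 0:
        raise ValueError(
            f"positive-control failure: CTRL ({m.ctrl}) <= CGH ({m.cgh})"
        )
    return PrognosisScore(
        blue_score=m.blue / denom,
        red_score=m.red / denom,
        diff_score=(m.blue - m.red) / denom,
    )


def classify_patients(
    scores: pd.Series, cohort_median: float | None = None
) -> pd.DataFrame:
    """Median-split prognosis calls from blue scores.

    Score above the (cohort or supplied) median -> ``good``, below ->
    ``poor``; a score exactly at the median is assigned ``good`` and
    flagged as a tie.  If all scores are identical every call is flagged
    indeterminate.
    """
    if cohort_median is None:
        if len(scores) < 2:
            raise ValueError("need >= 2 patients or an external median")
        cohort_median = float(np.median(scores))
    out = pd.DataFrame(index=scores.index)
    out["score"] = scores
    out["call"] = np.where(scores >= cohort_median, "good", "poor")
    out["tie"] = scores == cohort_median
    if scores.nunique() == 1:
        out["call"] = "indeterminate"
        out["tie"] = True
    return out


def red_blue_ttest_call(
    normalized: pd.Series, probes: pd.DataFrame, alpha: float = 0.05
) -> tuple[str, float]:
    """Welch t-test sample call from RED vs BLUE log-ratio distributions.

    Calls ``good`` (blue) if the BLUE median exceeds the RED median with
    Welch p < alpha on the log2 ratios, ``poor`` (red) for the converse, and
    ``indeterminate`` otherwise.  If both classes are constant the call is
    made on exact median (in)equality with p of 0 or 1.
    """
    validate_probes(probes)
    klass = probes.set_index("probe_id")["klass"]
    common = normalized.index.intersection(klass.index)
    red = normalized[common[klass[common] == "RED"]].to_numpy(float)
    blue = normalized[common[klass[common] == "BLUE"]].to_numpy(float)
    if len(red) < 2 or len(blue) < 2:
        raise ValueError("need >= 2 probes in each of RED and BLUE")
    if (red <= 0).any() or (blue <= 0).any():
        raise ValueError("nonpositive normalized intensity; cannot take log")
    lred, lblue = np.log2(red), np.log2(blue)
    red_med, blue_med = np.median(lred), np.median(lblue)
    if np.ptp(lred) == 0 and np.ptp(lblue) == 0:
        if blue_med == red_med:
            return "indeterminate", 1.0
        p = 0.0
    else:
        p = float(stats.ttest_ind(lblue, lred, equal_var=False).pvalue)
    if p < alpha and blue_med > red_med:
        return "good", p
    if p < alpha and red_med > blue_med:
        return "poor", p
    return "indeterminate", p


def correlate_with_atacseq(
    array_values: pd.Series, seq_values: pd.Series, conf: float = 0.95
) -> dict:
    """Spearman correlation of region-level array vs sequencing signal.

    Inputs are paired per-region values (array value = median over the
    region's probes, sequencing value = normalized read count).  Returns the
    rank correlation with mid-rank ties, a Fisher-z confidence interval and
    the two-sided p value.
    """
    joined = pd.concat(
        [array_values.rename("array"), seq_values.rename("seq")], axis=1
    ).dropna()
    n = len(joined)
    if n < 3:
        raise ValueError("need at least 3 paired regions")
    rho, p = stats.spearmanr(joined["array"], joined["seq"])
    if n > 3 and abs(rho) < 1:
        z = np.arctanh(rho)
        se = 1.0 / np.sqrt(n - 3)
        zq = stats.norm.ppf(0.5 + conf / 2)
        ci = (float(np.tanh(z - zq * se)), float(np.tanh(z + zq * se)))
    else:
        ci = (float(rho), float(rho))
    return {"rho": float(rho), "ci": ci, "p": float(p), "n": n}


class PrognosisScorer(BaseEstimator, TransformerMixin):
    """Transformer turning per-patient array scans into prognosis scores.

    ``fit`` stores the probe table; ``transform`` takes a mapping of patient
    id to scan table (``probe_id, cy5, cy3``) and returns one row per patient
    with the three score variants, the Welch RED/BLUE t-test call and its p.

    Parameters
    ----------
    scale : {'linear', 'log2'}, default 'linear'
        Scale on which class medians are taken (scores use the same scale).
    """

    def __init__(self, scale: str = "linear"):
        self.scale = scale

    def fit(self, probes: pd.DataFrame, y=None) -> "PrognosisScorer":
        self.probes_ = validate_probes(probes)
        return self

    def transform(self, scans: dict[str, pd.DataFrame]) -> pd.DataFrame:
        rows = []
        for patient, scan in scans.items():
            normalized = normalize_scan(scan, scale=self.scale)
            m = class_medians(normalized, self.probes_)
            s = prognosis_score(m)
            if self.scale == "linear":
                call, p = red_blue_ttest_call(normalized, self.probes_)
            else:
                call, p = red_blue_ttest_call(
                    pd.Series(
                        np.power(2.0, normalized.to_numpy()),
                        index=normalized.index,
                    ),
                    self.probes_,
                )
            rows.append(
                (patient, s.blue_score, s.red_score, s.diff_score, call, p)
            )
        return pd.DataFrame(
            rows,
            columns=[
                "patient", "blue_score", "red_score", "diff_score",
                "ttest_call", "ttest_p",
            ],
        ).set_index("patient")


def score_arrays(
    scans: dict[str, pd.DataFrame], probes: pd.DataFrame, scale: str = "linear"
) -> pd.DataFrame:
    """Score every patient's scan; thin wrapper over :class:`PrognosisScorer`."""
    return PrognosisScorer(scale=scale).fit(probes).transform(scans)
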