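"""Differential chromatin accessibility over a peak atlas.

Fragments are counted into disjoint atlas peaks by midpoint, counts are
normalized by median-of-ratios size factors, and a per-peak negative-binomial
GLM (log link, offset = log size factor) tests the recurrent vs non-recurrent
group contrast while adjusting for nuclear read depth (log scale) and margin
status.  The differential signature is called at strict |log2FC| and BH-FDR
thresholds, and concordance with expression changes is assessed by
Kolmogorov-Smirnov comparison of nearest-gene log fold changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .atlas import PeakAtlas, PeakInterval

LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# fragment handling


def tn5_shift(fragments: pd.DataFrame) -> pd.DataFrame:
    """Shift fragment intervals for the Tn5 insertion offset.

    Plus-strand fragments are shifted by +4 bp and minus-strand fragments by
    -5 bp; the whole interval moves so lengths are preserved.  ``fragments``
    must have columns ``chrom, start, end, strand``.
    """
    if "strand" not in fragments.columns:
        raise ValueError("fragments must carry a 'strand' column")
    if len(fragments) == 0:
        return fragments.copy()
    strand = fragments["strand"]
    bad = ~strand.isin(["+", "-"])
    if bad.any():
        raise ValueError(f"invalid strand values: {strand[bad].unique()!r}")
    shift = np.where(strand == "+", 4, -5)
    out = fragments.copy()
    out["start"] = fragments["start"] + shift
    out["end"] = fragments["end"] + shift
    return out


def count_fragments(fragments: pd.DataFrame, atlas: PeakAtlas) -> pd.DataFrame:
    """Count fragments into atlas peaks by fragment midpoint.

    Each fragment is assigned to the unique atlas peak containing its
    midpoint (the atlas is disjoint, so assignment is unambiguous); fragments
    whose midpoint falls outside every peak are not counted.  ``fragments``
    needs columns ``chrom, start, end, sample``.  Returns a peak x sample
    integer count matrix indexed by ``chrom:start-end`` peak ids, including
    all-zero rows for peaks without fragments.
    """
    ivs = atlas.intervals
    if sorted(ivs) != list(ivs):
        warnings.warn("atlas intervals were not sorted; sorting", stacklevel=2)
        ivs = sorted(ivs)
    starts_by_chrom: dict[str, np.ndarray] = {}
    ends_by_chrom: dict[str, np.ndarray] = {}
    offset_by_chrom: dict[str, int] = {}
    pos = 0
    for iv in ivs:
        if iv.chrom not in offset_by_chrom:
            offset_by_chrom[iv.chrom] = pos
            starts_by_chrom[iv.chrom] = []
            ends_by_chrom[iv.chrom] = []
        starts_by_chrom[iv.chrom].append(iv.start)
        ends_by_chrom[iv.chrom].append(iv.end)
        pos += 1
    for c in starts_by_chrom:
        starts_by_chrom[c] = np.asarray(starts_by_chrom[c])
        ends_by_chrom[c] = np.asarray(ends_by_chrom[c])

    samples = sorted(fragments["sample"].unique()) if len(fragments) else []
    counts = np.zeros((len(ivs), len(samples)), dtype=np.int64)
    sample_idx = {s: j for j, s in enumerate(samples)}
    for chrom, sub in fragments.groupby("chrom"):
        if chrom not in starts_by_chrom:
            continue
        starts = starts_by_chrom[chrom]
        ends = ends_by_chrom[chrom]
        off = offset_by_chrom[chrom]
        mids = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2).astype(int)
        j = np.searchsorted(starts, mids, side="right") - 1
        ok = (j >= 0) & (mids < ends[np.clip(j, 0, len(ends) - 1)])
        cols = sub["sample"].map(sample_idx).to_numpy()
        np.add.at(counts, (j[ok] + off, cols[ok]), 1)
    peak_ids = [iv.peak_id for iv in ivs]
    return pd.DataFrame(counts, index=peak_ids, columns=samples)


# ---------------------------------------------------------------------------
# normalization


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each peak with nonzero counts in every sample, the ratio of each
    sample's count to the peak's geometric mean is formed; the size factor is
    the per-sample median of these ratios.  If no peak is nonzero everywhere,
    falls back to total-count scaling (factors proportional to column sums,
    normalized to geometric mean 1) with a warning.
    """
    mat = counts.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        warnings.warn(
            "no peak with nonzero counts in all samples; "
            "falling back to total-count scaling",
            stacklevel=2,
        )
        totals = mat.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("cannot compute size factors: empty sample column")
        f = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(f, index=counts.columns)
    sub = mat[nonzero]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_geo)
    return pd.Series(np.median(ratios, axis=0), index=counts.columns)


def _mom_dispersions(
    counts: np.ndarray, sf: np.ndarray, groups: np.ndarray, floor: float
) -> np.ndarray:
    """Per-peak method-of-moments NB dispersion after removing group means.

    Var = mu + alpha * mu^2 on normalized counts; within-group variances are
    pooled so planted group differences do not inflate the estimate.
    """
    q = counts / sf  # normalized counts, peaks x samples
    n = q.shape[1]
    levels = np.unique(groups)
    ss = np.zeros(q.shape[0])
    dof = 0
    for g in levels:
        sel = groups == g
        if sel.sum() < 2:
            continue
        sub = q[:, sel]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        dof += sel.sum() - 1
    if dof == 0:
        return np.full(q.shape[0], floor)
    v = ss / dof
    mu = q.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - mu) / mu**2
    alpha = np.where(np.isfinite(alpha), alpha, floor)
    return np.maximum(alpha, floor)


# ---------------------------------------------------------------------------
# NB GLM


class NBDifferentialTest(BaseEstimator):
    """Per-peak negative-binomial GLM Wald test of a two-group contrast.

    The model for each peak is NB(mu_s, alpha_p) with
    ``log mu_s = log(size_factor_s) + b0 + b1*group_s + covariates`` where the
    group coding is 1 for the recurrent group.  Dispersion alpha_p is a
    per-peak method-of-moments estimate (pooled within-group variance) with a
    floor; the Wald test is on the group coefficient and
    ``log2FC = b1 / ln 2``.

    Parameters
    ----------
    covariates : tuple of str, default ('log_nuclear_read_depth', 'margin_status')
        Metadata columns entered as additional linear terms.
        ``nuclear_read_depth`` is log-transformed automatically when listed
        as ``log_nuclear_read_depth``.
    dispersion_floor : float, default 1e-8
        Lower bound on the dispersion estimate (Poisson limit).

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per peak: log2fc, se, pvalue, padj, direction, converged.
    size_factors_ : pandas.Series
    dispersions_ : numpy.ndarray
    """

    def __init__(
        self,
        covariates: tuple = ("log_nuclear_read_depth", "margin_status"),
        dispersion_floor: float = 1e-8,
    ):
        self.covariates = covariates
        self.dispersion_floor = dispersion_floor

    def fit(self, counts: pd.DataFrame, metadata: pd.DataFrame) -> "NBDifferentialTest":
        if list(counts.columns) != list(metadata.index):
            metadata = metadata.loc[counts.columns]
        groups = metadata["group"].to_numpy()
        bad = ~np.isin(groups, ["recurrent", "non_recurrent"])
        if bad.any():
            raise ValueError(f"unknown group labels: {set(groups[bad])}")
        for g in ("recurrent", "non_recurrent"):
            if (groups == g).sum() < 2:
                raise ValueError(f"need >= 2 samples in group {g!r}")
        sf = size_factors(counts)
        mat = counts.to_numpy(dtype=float)
        gvec = (groups == "recurrent").astype(float)

        cols = [np.ones(len(gvec)), gvec]
        names = ["intercept", "group"]
        for cov in self.covariates:
            if cov == "log_nuclear_read_depth":
                vals = np.log(metadata["nuclear_read_depth"].to_numpy(float))
            else:
                vals = metadata[cov].to_numpy(float)
            cols.append(vals)
            names.append(cov)
        X = np.column_stack(cols)

        alphas = _mom_dispersions(mat, sf.to_numpy(), groups, self.dispersion_floor)
        offset = np.log(sf.to_numpy())

        df_resid = X.shape[0] - X.shape[1]
        rows = []
        for p in range(mat.shape[0]):
            y = mat[p]
            res = self._fit_one(y, X, offset, alphas[p], df_resid)
            rows.append(res)
        out = pd.DataFrame(
            rows, index=counts.index, columns=["log2fc", "se", "pvalue", "converged"]
        )
        out["converged"] = out["converged"].astype(bool)
        ok = out["converged"] & out["pvalue"].notna()
        padj = pd.Series(np.nan, index=out.index)
        if ok.any():
            padj[ok] = multipletests(out.loc[ok, "pvalue"], method="fdr_bh")[1]
        out["padj"] = padj
        out["direction"] = np.where(
            out["log2fc"] > 0, "open_in_recurrent", "open_in_nonrecurrent"
        )
        out.loc[~ok, "direction"] = "NA"
        self.results_ = out
        self.size_factors_ = sf
        self.dispersions_ = alphas
        return self

    @staticmethod
    def _fit_one(y, X, offset, alpha, df_resid):
        # Wald statistic referred to t with residual df: at the small sample
        # sizes of a patient cohort the normal reference is anticonservative.
        if y.sum() == 0:
            return (0.0, np.nan, np.nan, False)
        fam = (
            sm.families.Poisson()
            if alpha <= 1e-8
            else sm.families.NegativeBinomial(alpha=alpha)
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=100)
            if not fit.converged:
                return (np.nan, np.nan, np.nan, False)
            b = fit.params[1]
            se = fit.bse[1]
            z = b / se if se > 0 else np.nan
            if not np.isfinite(z):
                return (b / LN2, np.nan, np.nan, True)
            p = 2 * stats.t.sf(abs(z), df=max(df_resid, 1))
            return (b / LN2, se / LN2, p, True)
        except Exception:
            return (np.nan, np.nan, np.nan, False)


def fit_nb_glm(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    covariates: tuple = ("log_nuclear_read_depth", "margin_status"),
    dispersion_floor: float = 1e-8,
) -> pd.DataFrame:
    """Fit the per-peak NB GLM; returns the per-peak results table."""
    est = NBDifferentialTest(covariates=covariates, dispersion_floor=dispersion_floor)
    return est.fit(counts, metadata).results_


# ---------------------------------------------------------------------------
# signature calling


@dataclass
class Signature:
    """Differential signature: peak ids split by direction of opening."""

    open_in_recurrent: list[str]
    open_in_nonrecurrent: list[str]

    def __len__(self) -> int:
        return len(self.open_in_recurrent) + len(self.open_in_nonrecurrent)

    @property
    def peak_ids(self) -> list[str]:
        return self.open_in_recurrent + self.open_in_nonrecurrent


def call_differential(
    results: pd.DataFrame, lfc_threshold: float = 1.0, fdr: float = 0.001
) -> Signature:
    """Call the differential signature at strict thresholds.

    Keeps peaks with ``|log2FC| > lfc_threshold`` and BH-adjusted
    ``padj < fdr`` (both strict inequalities).  The Benjamini-Hochberg
    adjustment is recomputed here over all tested peaks (every peak with a
    defined raw p-value), so the multiplicity correction always reflects the
    full table passed in.
    """
    if len(results) == 0:
        return Signature([], [])
    ok = results["pvalue"].notna()
    padj = pd.Series(np.nan, index=results.index)
    if ok.any():
        padj[ok] = multipletests(results.loc[ok, "pvalue"], method="fdr_bh")[1]
    hits = results[
        ok
        & (results["log2fc"].abs() > lfc_threshold)
        & (padj < fdr)
    ]
    up = hits.index[hits["log2fc"] > 0].tolist()
    down = hits.index[hits["log2fc"] < 0].tolist()
    return Signature(up, down)


# ---------------------------------------------------------------------------
# expression concordance


def _peak_midpoints(peak_ids) -> pd.DataFrame:
    chroms, mids = [], []
    for pid in peak_ids:
        chrom, rng = pid.split(":")
        s, e = rng.split("-")
        chroms.append(chrom)
        mids.append((int(s) + int(e)) // 2)
    return pd.DataFrame({"chrom": chroms, "mid": mids}, index=peak_ids)


def nearest_gene(peak_ids, gene_annotations: pd.DataFrame) -> pd.Series:
    """Nearest gene per peak by TSS distance from the peak midpoint.

    ``gene_annotations`` needs columns ``gene, chrom, tss``.  Ties are broken
    toward the gene with the smaller TSS coordinate.
    """
    genes = gene_annotations.sort_values(["chrom", "tss", "gene"])
    mids = _peak_midpoints(peak_ids)
    out = {}
    for chrom, sub in mids.groupby("chrom"):
        g = genes[genes["chrom"] == chrom]
        if len(g) == 0:
            continue
        tss = g["tss"].to_numpy()
        names = g["gene"].to_numpy()
        for pid, mid in zip(sub.index, sub["mid"]):
            d = np.abs(tss - mid)
            # ties -> smaller coordinate; tss is sorted so first argmin wins
            out[pid] = names[int(np.argmin(d))]
    return pd.Series(out)


def expression_concordance(
    results: pd.DataFrame,
    signature: Signature,
    expression_lfc: pd.Series,
    gene_annotations: pd.DataFrame,
) -> dict:
    """KS comparison of expression changes near signature vs unchanged peaks.

    Maps every tested peak to its nearest gene, then runs a two-sided
    two-sample Kolmogorov-Smirnov test of the expression log2 fold changes of
    genes nearest to differentially closed peaks (open in non-recurrent)
    against genes nearest to unchanged peaks, and likewise for open peaks.
    Returns ``{'closed': (D, p), 'open': (D, p)}``.
    """
    gene_of = nearest_gene(results.index, gene_annotations)
    if len(gene_of) == 0:
        raise ValueError("no peak could be mapped to a gene")
    sig_ids = set(signature.peak_ids)
    background = [p for p in results.index if p not in sig_ids and p in gene_of]
    bg_genes = gene_of[background].unique()
    bg_lfc = expression_lfc.reindex(bg_genes).dropna().to_numpy()

    out = {}
    for key, ids in (
        ("closed", signature.open_in_nonrecurrent),
        ("open", signature.open_in_recurrent),
    ):
        if len(ids) == 0:
            out[key] = (float("nan"), float("nan"))
            continue
        genes = gene_of.reindex(ids).dropna().unique()
        vals = expression_lfc.reindex(genes).dropna().to_numpy()
        if len(vals) == 0 or len(bg_lfc) == 0:
            raise ValueError(f"no mappable genes for {key} peaks or background")
        stat = stats.ks_2samp(vals, bg_lfc, alternative="two-sided")
        out[key] = (stat.statistic, stat.pvalue)
    return out
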