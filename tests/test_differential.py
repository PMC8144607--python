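"""Fragment counting, normalization, NB GLM testing and signature calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from atacprog import (
    PeakAtlas,
    Signature,
    call_differential,
    count_fragments,
    expression_concordance,
    fit_nb_glm,
    nearest_gene,
    size_factors,
    tn5_shift,
)

from conftest import iv


def frame(rows, columns=("chrom", "start", "end", "strand")):
    return pd.DataFrame(rows, columns=list(columns))


# ---------------------------------------------------------------------------
# Tn5 shift


class TestTn5Shift:
    def test_plus_strand_shifts_interval_by_plus_four(self):
        out = tn5_shift(frame([("chrS", 100, 150, "+")]))
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (104, 154)

    def test_minus_strand_shifts_interval_by_minus_five(self):
        out = tn5_shift(frame([("chrS", 100, 150, "-")]))
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (95, 145)

    def test_lengths_preserved(self):
        df = frame([("chrS", 10, 60, "+"), ("chrS", 30, 130, "-")])
        out = tn5_shift(df)
        assert ((out["end"] - out["start"]) == (df["end"] - df["start"])).all()

    def test_empty_input_passes_through(self):
        assert len(tn5_shift(frame([]))) == 0

    def test_missing_strand_is_an_error(self):
        with pytest.raises(ValueError):
            tn5_shift(pd.DataFrame({"chrom": ["chrS"], "start": [0], "end": [9]}))

    def test_bad_strand_value_is_an_error(self):
        with pytest.raises(ValueError):
            tn5_shift(frame([("chrS", 0, 10, ".")]))


# ---------------------------------------------------------------------------
# counting


class TestCountFragments:
    atlas = PeakAtlas([iv(100, 200), iv(300, 400)])

    def test_midpoint_inside_peak_counts_once(self):
        frags = pd.DataFrame(
            {"chrom": ["chrS"], "start": [150], "end": [170], "sample": ["s1"]}
        )
        counts = count_fragments(frags, self.atlas)
        assert counts.loc["chrS:100-200", "s1"] == 1
        assert counts.loc["chrS:300-400", "s1"] == 0

    def test_fragment_outside_every_peak_is_uncounted(self):
        frags = pd.DataFrame(
            {"chrom": ["chrS"], "start": [210], "end": [280], "sample": ["s1"]}
        )
        assert count_fragments(frags, self.atlas).to_numpy().sum() == 0

    def test_straddling_fragment_assigned_by_midpoint_only(self):
        # midpoint (90+110)//2 = 100 -> inside [100, 200)
        frags = pd.DataFrame(
            {"chrom": ["chrS"], "start": [90], "end": [110], "sample": ["s1"]}
        )
        assert count_fragments(frags, self.atlas).loc["chrS:100-200", "s1"] == 1

    def test_column_sum_counts_only_in_peak_fragments(self):
        inside = [("chrS", 100 + 10 * i, 110 + 10 * i, "s1") for i in range(10)]
        outside = [("chrS", 500 + 10 * i, 520 + 10 * i, "s1") for i in range(5)]
        frags = frame(inside + outside, columns=("chrom", "start", "end", "sample"))
        counts = count_fragments(frags, self.atlas)
        assert counts["s1"].sum() == 10


# ---------------------------------------------------------------------------
# size factors


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_column_splits_symmetrically(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        f = size_factors(counts)
        assert f["a"] == pytest.approx(1 / np.sqrt(2))
        assert f["b"] == pytest.approx(np.sqrt(2))

    def test_single_sample_gets_factor_one(self):
        f = size_factors(pd.DataFrame({"a": [5, 8, 2]}))
        assert f.to_numpy() == pytest.approx([1.0])

    def test_all_zero_rows_fall_back_to_totals_with_warning(self):
        counts = pd.DataFrame({"a": [0, 10], "b": [5, 0]})
        with pytest.warns(UserWarning, match="total-count"):
            f = size_factors(counts)
        assert np.allclose(np.exp(np.mean(np.log(f))), 1.0)


# ---------------------------------------------------------------------------
# NB GLM


def make_counts(rng, mu_by_group, n_per_group=10, n_peaks=50, alpha=0.0):
    """Direct NB count construction with trivial covariates."""
    samples = [f"r{i}" for i in range(n_per_group)] + [
        f"n{i}" for i in range(n_per_group)
    ]
    groups = ["recurrent"] * n_per_group + ["non_recurrent"] * n_per_group
    mus = np.array([mu_by_group[g] for g in groups], dtype=float)
    if alpha > 0:
        r = 1 / alpha
        mat = rng.negative_binomial(r, r / (r + mus), size=(n_peaks, len(mus)))
    else:
        mat = rng.poisson(mus, size=(n_peaks, len(mus)))
    counts = pd.DataFrame(mat, columns=samples,
                          index=[f"chrS:{i * 100}-{i * 100 + 50}"
                                 for i in range(n_peaks)])
    meta = pd.DataFrame(
        {
            "group": groups,
            "nuclear_read_depth": 1e7,
            "margin_status": 0,
        },
        index=samples,
    )
    return counts, meta


class TestNBGLM:
    def test_null_fit_gives_small_lfc_and_uniformish_p(self, rng):
        counts, meta = make_counts(rng, {"recurrent": 200, "non_recurrent": 200},
                                   n_peaks=200)
        res = fit_nb_glm(counts, meta, covariates=())
        assert res["log2fc"].abs().mean() < 0.1
        assert stats.kstest(res["pvalue"], "uniform").pvalue > 0.01

    def test_planted_fourfold_recovered_in_poisson_limit(self, rng):
        # 10 planted 4-fold peaks among 60 mostly-null peaks, so the
        # median-of-ratios normalization is anchored by the null majority
        null_counts, meta = make_counts(
            rng, {"recurrent": 100, "non_recurrent": 100}, n_per_group=20,
            n_peaks=200,
        )
        planted, _ = make_counts(
            rng, {"recurrent": 400, "non_recurrent": 100}, n_per_group=20,
            n_peaks=10,
        )
        planted.index = [f"chrS:{(200 + i) * 100}-{(200 + i) * 100 + 50}"
                         for i in range(10)]
        counts = pd.concat([null_counts, planted])
        res = fit_nb_glm(counts, meta, covariates=())
        assert np.allclose(res.loc[planted.index, "log2fc"], 2.0, atol=0.1)

    def test_group_label_swap_negates_log2fc(self, rng):
        counts, meta = make_counts(
            rng, {"recurrent": 300, "non_recurrent": 120}, n_peaks=30
        )
        res = fit_nb_glm(counts, meta, covariates=())
        flipped = meta.copy()
        flipped["group"] = np.where(
            meta["group"] == "recurrent", "non_recurrent", "recurrent"
        )
        res2 = fit_nb_glm(counts, flipped, covariates=())
        assert np.allclose(res["log2fc"], -res2["log2fc"], atol=1e-6)

    def test_covariate_absorbs_a_confounded_difference(self, rng):
        # nuclear read depth correlates with group and drives a subset of
        # peaks (so it is not absorbed by the size factors); adjusting for it
        # should shrink the group coefficient on those peaks
        n = 15
        samples = [f"s{i}" for i in range(2 * n)]
        groups = ["recurrent"] * n + ["non_recurrent"] * n
        depth = np.exp(
            rng.normal(np.log(4e7), 0.4, n).tolist()
            + rng.normal(np.log(1e7), 0.4, n).tolist()
        )
        n_resp, n_null = 30, 70
        mu_resp = 200 * (depth / 2e7)  # responding peaks follow depth
        mat = np.vstack(
            [
                rng.poisson(np.tile(mu_resp, (n_resp, 1))),
                rng.poisson(200, size=(n_null, 2 * n)),
            ]
        )
        counts = pd.DataFrame(mat, columns=samples)
        counts.index = [f"chrS:{i * 100}-{i * 100 + 50}"
                        for i in range(n_resp + n_null)]
        meta = pd.DataFrame(
            {"group": groups, "nuclear_read_depth": depth, "margin_status": 0},
            index=samples,
        )
        resp = counts.index[:n_resp]
        adj = fit_nb_glm(counts, meta, covariates=("log_nuclear_read_depth",))
        raw = fit_nb_glm(counts, meta, covariates=())
        assert (
            adj.loc[resp, "log2fc"].abs().mean()
            < 0.5 * raw.loc[resp, "log2fc"].abs().mean()
        )

    def test_too_small_groups_rejected(self, rng):
        counts, meta = make_counts(rng, {"recurrent": 10, "non_recurrent": 10},
                                   n_per_group=1, n_peaks=3)
        with pytest.raises(ValueError):
            fit_nb_glm(counts, meta)

    def test_bh_adjustment_monotone_and_above_raw(self, small_cohort):
        res = fit_nb_glm(small_cohort["counts"], small_cohort["metadata"])
        ok = res.dropna(subset=["pvalue"])
        assert (ok["padj"] >= ok["pvalue"] - 1e-15).all()
        s = ok.sort_values("pvalue")
        assert (np.diff(s["padj"]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# signature calling


def results_frame(lfcs, pvals):
    return pd.DataFrame(
        {
            "log2fc": lfcs,
            "se": 0.1,
            "pvalue": pvals,
            "padj": np.nan,
            "converged": True,
        },
        index=[f"chrS:{i * 100}-{i * 100 + 50}" for i in range(len(lfcs))],
    )


class TestCallDifferential:
    def test_hand_computed_bh_thresholding(self):
        # m=3, raw p (0.0001, 0.0006, 0.9) -> BH padj (0.0003, 0.0009, 0.9)
        res = results_frame([2.0, -2.0, 3.0], [0.0001, 0.0006, 0.9])
        sig = call_differential(res, lfc_threshold=1, fdr=0.001)
        assert set(sig.peak_ids) == set(res.index[:2])
        assert sig.open_in_recurrent == [res.index[0]]
        assert sig.open_in_nonrecurrent == [res.index[1]]

    def test_lfc_exactly_at_threshold_excluded(self):
        res = results_frame([1.0, 1.0001], [1e-9, 1e-9])
        sig = call_differential(res, lfc_threshold=1, fdr=0.001)
        assert sig.peak_ids == [res.index[1]]

    def test_all_unit_pvalues_give_empty_signature(self):
        res = results_frame([3.0, -3.0], [1.0, 1.0])
        assert len(call_differential(res)) == 0

    def test_empty_results_give_empty_signature(self):
        assert len(call_differential(results_frame([], []))) == 0


# ---------------------------------------------------------------------------
# expression concordance


class TestExpressionConcordance:
    @staticmethod
    def setup_peaks(n_sig=5, n_bg=20):
        sig_ids = [f"chrS:{i * 1000}-{i * 1000 + 500}" for i in range(n_sig)]
        bg_ids = [
            f"chrS:{(i + n_sig) * 1000}-{(i + n_sig) * 1000 + 500}"
            for i in range(n_bg)
        ]
        res = results_frame(
            [-2.0] * n_sig + [0.0] * n_bg, [1e-9] * n_sig + [0.9] * n_bg
        )
        res.index = sig_ids + bg_ids
        genes = pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(n_sig + n_bg)],
                "chrom": "chrS",
                "tss": [i * 1000 + 250 for i in range(n_sig + n_bg)],
            }
        )
        return res, sig_ids, bg_ids, genes

    def test_identical_distributions_give_zero_distance(self):
        res, sig_ids, bg_ids, genes = self.setup_peaks()
        expr = pd.Series(
            list(range(5)) * 5, index=[f"G{i}" for i in range(25)], dtype=float
        )
        # closed-peak genes G0..G4 carry values 0..4; background G5..G24
        # cycles the same values, so the two empirical distributions agree
        sig = Signature([], sig_ids)
        out = expression_concordance(res, sig, expr, genes)
        d, p = out["closed"]
        assert d == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_shifted_closed_peak_genes_detected(self, rng):
        n_sig, n_bg = 200, 400
        res, sig_ids, bg_ids, genes = self.setup_peaks(n_sig, n_bg)
        lfc = pd.Series(
            np.concatenate([rng.normal(-1, 1, n_sig), rng.normal(0, 1, n_bg)]),
            index=[f"G{i}" for i in range(n_sig + n_bg)],
        )
        sig = Signature([], sig_ids)
        d, p = expression_concordance(res, sig, lfc, genes)["closed"]
        assert p < 1e-3
        assert d > 0.2

    def test_single_gene_sets_use_exact_small_sample_p(self):
        res, sig_ids, bg_ids, genes = self.setup_peaks(1, 3)
        expr = pd.Series([5.0, 0.0, 0.1, -0.1], index=[f"G{i}" for i in range(4)])
        sig = Signature([], sig_ids[:1])
        d, p = expression_concordance(res, sig, expr, genes)["closed"]
        # one observation above all three background values: D = 1,
        # exact two-sided p = 2 * 1/C(4,1) = 0.5
        assert d == pytest.approx(1.0)
        assert p == pytest.approx(0.5)

    def test_unmappable_peaks_raise(self):
        res, sig_ids, _, genes = self.setup_peaks(1, 3)
        sig = Signature([], sig_ids[:1])
        empty_genes = genes.iloc[:0]
        with pytest.raises(ValueError):
            expression_concordance(res, sig, pd.Series(dtype=float), empty_genes)


class TestNearestGene:
    def test_tie_broken_toward_smaller_coordinate(self):
        genes = pd.DataFrame(
            {"gene": ["B", "A"], "chrom": "chrS", "tss": [300, 100]}
        )
        # peak midpoint 200 is equidistant from TSS 100 and 300
        out = nearest_gene(["chrS:150-250"], genes)
        assert out["chrS:150-250"] == "A"
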