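"""Constraint statistics: rates, Wilcoxon, Fisher + Woolf CI, SFS, promoters."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import egburden.constraint_stats as cs
import egburden.synthetic_data as sd
from tests.conftest import make_universe


def variants_frame(gene_ids, effect="MISSENSE_BROAD", af=0.1):
    n = len(gene_ids)
    return pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(n) + 1,
            "ref": "A",
            "alt": "T",
            "gene_id": gene_ids,
            "raw_effect": "NON_SYNONYMOUS_CODING",
            "effect_class": effect,
            "polyphen": "missing",
            "sift": "missing",
            "damaging_consensus": False,
            "af": af,
            "rare": af < 0.01,
            "quality_avgpost": 0.99,
        }
    )


class TestLengthCorrectedRate:
    def test_two_gene_arithmetic(self):
        genes = make_universe([("a", 100, 40.0, "EG"), ("b", 100, 40.0, "NLG")])
        v = variants_frame(["a", "a"])
        rates = cs.length_corrected_rate(v, genes, transform="rate")
        assert rates["value"].tolist() == pytest.approx([0.02, 0.0])
        z = cs.length_corrected_rate(v, genes, transform="z")
        assert z["value"].tolist() == pytest.approx([0.7071, -0.7071], abs=1e-4)

    def test_zero_count_gene(self):
        genes = make_universe([("a", 1000, 40.0, "EG")])
        rates = cs.length_corrected_rate(variants_frame([]), genes, transform="rate")
        assert rates["value"].tolist() == [0.0]

    def test_log1p_pseudocount(self):
        genes = make_universe([("a", 1000, 40.0, "EG"), ("b", 1000, 40.0, "NLG")])
        out = cs.length_corrected_rate(variants_frame(["b"]), genes, transform="log1p")
        assert out.loc[out["gene_id"] == "a", "value"].iloc[0] == 0.0
        assert out.loc[out["gene_id"] == "b", "value"].iloc[0] == pytest.approx(np.log(2))

    def test_zero_length_rejected(self):
        genes = make_universe([("a", 0, 40.0, "EG")])
        with pytest.raises(ValueError):
            cs.length_corrected_rate(variants_frame([]), genes)

    def test_zscores_standardized(self):
        rng = np.random.default_rng(0)
        z = cs.zscores(rng.exponential(size=500))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-12)


class TestWilcoxon:
    def test_one_sided_enumeration_value(self):
        # all 3-subsets of ranks 1..6: only one split as extreme → p = 1/20
        res = cs.wilcoxon_compare([1, 2, 3], [4, 5, 6], alternative="less")
        assert res.p_value == pytest.approx(0.05)

    def test_paired_all_zero_differences(self):
        res = cs.wilcoxon_compare([1, 2, 3], [1, 2, 3], paired=True, alternative="less")
        assert res.p_value == 1.0

    def test_identical_multisets_two_sided(self):
        res = cs.wilcoxon_compare([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value >= 0.99

    def test_paired_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            cs.wilcoxon_compare([1, 2], [1, 2, 3], paired=True)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cs.wilcoxon_compare([], [1.0])


def fisher_enumeration_p(table):
    """Independent oracle: full enumeration of the hypergeometric support.

    Two-sided p sums the probabilities of all tables (same margins) whose
    point probability does not exceed the observed one (standard relative
    tolerance for floating-point ties).
    """
    a, b = table[0]
    c, d = table[1]
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[support == a][0]
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


class TestFisher:
    def test_printed_brain_table(self):
        # the conditional MLE is 1.0550010, on the 1.055 rounding knife edge;
        # agreement with the printed 1.05 is asserted to half a printed unit
        res = cs.fisher_2x2([[399, 2073], [588, 3223]])
        assert res.or_ == pytest.approx(1.05, abs=0.006)
        assert (round(res.ci95[0], 2), round(res.ci95[1], 2)) == (0.92, 1.21)
        assert res.p_value > 0.05  # no enrichment

    def test_symmetric_table(self):
        res = cs.fisher_2x2([[7, 7], [7, 7]])
        assert res.or_ == 1.0 and res.p_value == pytest.approx(1.0)

    def test_derived_example_or_and_p(self):
        res = cs.fisher_2x2([[3, 7], [6, 4]], or_kind="sample")
        assert res.or_ == pytest.approx(2 / 7, rel=1e-12)
        assert res.p_value == pytest.approx(fisher_enumeration_p([[3, 7], [6, 4]]), abs=1e-12)

    def test_enumeration_agreement_sample(self):
        """Exact p matches the enumeration oracle (spot grid; the full n ≤ 60
        sweep runs in the acceptance suite)."""
        rng = np.random.default_rng(1)
        for _ in range(200):
            t = rng.integers(0, 15, size=(2, 2))
            assert cs.fisher_2x2(t, or_kind="sample").p_value == pytest.approx(
                fisher_enumeration_p(t), abs=1e-12
            )

    def test_or_invariances(self):
        def sample_or(t):
            return cs.fisher_2x2(t, or_kind="sample").or_

        t = [[3, 7], [6, 4]]
        both_swapped = [[4, 6], [7, 3]]  # swap rows AND columns
        assert sample_or(both_swapped) == pytest.approx(sample_or(t))
        rows_swapped = [[6, 4], [3, 7]]
        assert sample_or(rows_swapped) == pytest.approx(1 / sample_or(t))
        cols_swapped = [[7, 3], [4, 6]]
        assert sample_or(cols_swapped) == pytest.approx(1 / sample_or(t))

    def test_zero_cell_continuity_flagged(self):
        res = cs.fisher_2x2([[0, 10], [5, 5]])
        assert "continuity_corrected" in res.flags
        assert np.isfinite(res.or_) and res.or_ > 0


class TestSfs:
    def test_identity_zero_excess(self):
        af = [0.001, 0.02, 0.3] * 10
        tab, _ = cs.sfs_relative_excess(af, af)
        assert tab["excess"].to_numpy() == pytest.approx(np.zeros(len(tab)), abs=1e-12)

    def test_two_bin_arithmetic(self):
        tab, _ = cs.sfs_relative_excess(
            [0.001] * 10, [0.001] * 5 + [0.5] * 5, bins=(0.0, 0.01, 0.5)
        )
        assert tab["excess"].tolist() == pytest.approx([0.5, -0.5])

    def test_excess_sums_to_zero(self):
        rng = np.random.default_rng(2)
        tab, _ = cs.sfs_relative_excess(rng.uniform(0, 0.5, 100), rng.uniform(0, 0.5, 500))
        assert tab["excess"].sum() == pytest.approx(0.0, abs=1e-12)

    def test_singletons_excess_in_lowest_bin(self):
        tab, test = cs.sfs_relative_excess(
            [0.0005] * 50, np.linspace(0.001, 0.5, 200)
        )
        assert tab["excess"].iloc[0] > 0
        assert test.p_value < 0.01  # set is rarer

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            cs.sfs_relative_excess([], [0.1])


class TestPromoter:
    def test_constant_track(self):
        genes = make_universe([("a", 1000, 40.0, "EG")])
        genes.loc[0, "tss"] = 5000
        track = pd.DataFrame(
            {"chrom": ["1"], "start": [0], "end": [10_000], "score": [1.0]}
        )
        out = cs.promoter_mean_score(track, genes)
        assert out["value"].iloc[0] == pytest.approx(1.0)

    def test_window_mean_arithmetic(self):
        # per-base scores 1..201 across [tss-100, tss+100] → mean 101
        genes = make_universe([("a", 1000, 40.0, "EG")])
        genes.loc[0, "tss"] = 500
        starts = np.arange(399, 600)  # 0-based starts of bases 400..600
        track = pd.DataFrame(
            {"chrom": "1", "start": starts, "end": starts + 1,
             "score": np.arange(1, 202, dtype=float)}
        )
        out = cs.promoter_mean_score(track, genes)
        assert out["value"].iloc[0] == pytest.approx(101.0)

    def test_minus_strand_same_window(self):
        genes = make_universe([("a", 1000, 40.0, "EG"), ("b", 1000, 40.0, "EG")])
        genes.loc[:, "tss"] = 500
        genes.loc[1, "strand"] = "-"
        starts = np.arange(380, 620)
        track = pd.DataFrame(
            {"chrom": "1", "start": starts, "end": starts + 1,
             "score": np.sin(starts / 7.0)}
        )
        out = cs.promoter_mean_score(track, genes)
        assert out["value"].iloc[0] == pytest.approx(out["value"].iloc[1])

    def test_uncovered_gene_missing(self):
        genes = make_universe([("a", 1000, 40.0, "EG")])
        genes.loc[0, "tss"] = 10_000_000
        track = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [10], "score": [1.0]})
        out = cs.promoter_mean_score(track, genes)
        assert np.isnan(out["value"].iloc[0])


class TestCompareGeneSets:
    def test_constant_metric(self):
        m = pd.DataFrame({"gene_id": [f"g{i}" for i in range(20)],
                          "metric": "m", "value": 1.0})
        out = cs.compare_gene_sets(m, [f"g{i}" for i in range(10)],
                                   [f"g{i}" for i in range(10, 20)])
        assert out["test"].p_value >= 0.99

    def test_identical_sets(self):
        rng = np.random.default_rng(3)
        ids = [f"g{i}" for i in range(30)]
        m = pd.DataFrame({"gene_id": ids, "metric": "m", "value": rng.normal(size=30)})
        out = cs.compare_gene_sets(m, ids, ids)
        assert out["test"].p_value >= 0.99

    def test_synthetic_dnds_power(self):
        """EG dN/dS scaled by 0.5 → one-sided rejection in ≥95% of replicates
        at n = 200 genes per set."""
        n_rep, hits = 20, 0
        for r in range(n_rep):
            g = make_universe(
                [(f"e{i}", 1000, 40.0, "EG") for i in range(200)]
                + [(f"n{i}", 1000, 40.0, "NLG") for i in range(200)]
            )
            m = sd.simulate_gene_metrics(
                g, seed=100 + r, species=("rhesus",),
                dnds_multiplier={"EG": 0.5, "NLG": 1.0},
            )
            eg = g.loc[g["ess_class"] == "EG", "gene_id"]
            nlg = g.loc[g["ess_class"] == "NLG", "gene_id"]
            out = cs.compare_gene_sets(m, eg, nlg, alternative="less",
                                       metric_name="dnds_rhesus")
            hits += out["test"].p_value < 0.05
        assert hits >= int(np.ceil(0.95 * n_rep))

    def test_metric_missing_on_set_rejected(self):
        m = pd.DataFrame({"gene_id": ["g1"], "metric": "m", "value": [1.0]})
        with pytest.raises(ValueError):
            cs.compare_gene_sets(m, ["g1"], ["g2"])
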