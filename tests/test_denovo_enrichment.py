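"""Matched permutation: pools, expectation oracles, p-values, meta-analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import egburden.denovo_enrichment as dn
import egburden.synthetic_data as sd
from tests.conftest import make_universe


def events_frame(gene_ids, study="s1", arm="case", mtype="missense"):
    return pd.DataFrame(
        {"study": study, "arm": arm, "gene_id": gene_ids, "mutation_type": mtype}
    )


class TestFilterEvents:
    def test_multi_annotation_resolves_to_coding(self, small_universe):
        ev = events_frame(["g1"], mtype="missense,synonymous")
        out = dn.filter_events(ev, small_universe)
        assert out["mutation_type"].tolist() == ["missense"]

    def test_synonymous_dropped_when_excluded(self, small_universe):
        ev = events_frame(["g1", "g2"])
        ev.loc[1, "mutation_type"] = "synonymous"
        out = dn.filter_events(ev, small_universe, include_synonymous=False)
        assert len(out) == 1 and out["gene_id"].iloc[0] == "g1"

    def test_out_of_universe_dropped(self, small_universe):
        out = dn.filter_events(events_frame(["g1", "nope"]), small_universe)
        assert out["gene_id"].tolist() == ["g1"]

    def test_unknown_token_raises_with_token_named(self, small_universe):
        with pytest.raises(ValueError, match="weird_type"):
            dn.filter_events(events_frame(["g1"], mtype="weird_type"), small_universe)

    def test_proband_deduplication(self, small_universe):
        ev = events_frame(["g1", "g1"], mtype="missense")
        ev["mutation_type"] = ["synonymous", "nonsense"]
        ev["proband"] = "p1"
        out = dn.filter_events(ev, small_universe)
        assert out["mutation_type"].tolist() == ["nonsense"]


class TestMatchPool:
    def test_spec_pool_example(self):
        # target (1000, 40): matches itself and (1050, 41); (1200, 40) fails
        # length, (1000, 45) fails GC
        universe = make_universe(
            [("g1", 1000, 40.0, "EG"), ("g2", 1050, 41.0, "OTHER"),
             ("g3", 1200, 40.0, "OTHER"), ("g4", 1000, 45.0, "OTHER")]
        )
        assert sorted(dn.build_match_pool("g1", universe)) == ["g1", "g2"]

    def test_infinite_tolerances_whole_universe(self, small_universe):
        pool = dn.build_match_pool("g1", small_universe, np.inf, np.inf)
        assert sorted(pool) == sorted(small_universe["gene_id"])

    def test_singleton_pool_self_match(self, small_universe):
        assert dn.build_match_pool("g6", small_universe) == ["g6"]

    def test_pools_respect_both_tolerances(self, small_universe):
        mu = dn.MatchedUniverse(small_universe)
        for gid in small_universe["gene_id"]:
            r = mu.row(gid)
            pool = mu.pool_rows(gid)
            assert (np.abs(mu.lengths[pool] - mu.lengths[r]) <= 100).all()
            assert (np.abs(mu.gc[pool] - mu.gc[r]) <= 2.5).all()
            assert r in pool


class TestPermuteStudy:
    def test_identity_permutation(self, small_universe):
        # g6's pool is itself only; all events on g6; set = {g6}
        ev = events_frame(["g6", "g6", "g6"])
        res = dn.permute_study(ev, small_universe, ["g6"], n_perm=50, seed=1)
        assert res.exp_in_set == res.obs_in_set == 3
        assert res.adjusted_or == pytest.approx(1.0)
        assert res.perm_p == 1.0
        assert not np.isfinite(res.se_log_or)

    def test_exact_expectation_matches_enumeration(self, small_universe):
        """Independent oracle: enumerate every joint pool assignment."""
        ev = events_frame(["g1", "g3", "g5"])
        eg = small_universe.loc[small_universe["ess_class"] == "EG", "gene_id"]
        res = dn.permute_study(
            ev, small_universe, eg, n_perm=100_000, seed=2, exact=True
        )
        mu = dn.MatchedUniverse(small_universe)
        eg_set = set(eg)
        pools = [
            [mu.gene_ids[i] for i in mu.pool_rows(g)] for g in ev["gene_id"]
        ]
        counts = [
            sum(g in eg_set for g in combo)
            for combo in itertools.product(*pools)
        ]
        exact = float(np.mean(counts))
        assert res.exact_exp_in_set == pytest.approx(exact, abs=1e-12)
        # MC mean within 3 SE of the exact value
        se = np.std(counts) / np.sqrt(res.n_perm)
        assert abs(res.exp_in_set - exact) < 3 * max(se, 1e-9)

    def test_repeated_gene_resampled_per_event(self, homogeneous_universe):
        """A gene hit twice contributes two independent draws (variance check)."""
        ev = events_frame(["h000"] * 40)
        eg = homogeneous_universe.loc[
            homogeneous_universe["ess_class"] == "EG", "gene_id"
        ]
        res = dn.permute_study(ev, homogeneous_universe, eg, n_perm=4000, seed=3)
        res_pg = dn.permute_study(
            ev, homogeneous_universe, eg, n_perm=4000, seed=3, per_gene=True
        )
        # per-event: Binomial(40, .5) sd ≈ 3.16; per-gene: 40·Bernoulli sd = 20
        assert res.se_log_or < res_pg.se_log_or
        assert res.exp_in_set == pytest.approx(20, abs=1.0)

    def test_permutation_respects_matching(self, small_universe):
        ev = events_frame(["g1", "g2", "g4"])
        matched = dn.MatchedUniverse(small_universe)
        for g in ev["gene_id"]:
            pool = matched.pool_rows(g)
            r = matched.row(g)
            assert (np.abs(matched.lengths[pool] - matched.lengths[r]) <= 100).all()
            assert (np.abs(matched.gc[pool] - matched.gc[r]) <= 2.5).all()

    def test_empty_gene_set_rejected(self, small_universe):
        with pytest.raises(ValueError):
            dn.permute_study(events_frame(["g1"]), small_universe, [], n_perm=10)

    def test_empty_events_rejected(self, small_universe):
        with pytest.raises(ValueError):
            dn.permute_study(events_frame([]), small_universe, ["g1"], n_perm=10)

    def test_quick_null_calibration(self, homogeneous_universe):
        """One-sided rejection at α=0.05 near nominal under the null."""
        rng = np.random.default_rng(4)
        eg = homogeneous_universe.loc[
            homogeneous_universe["ess_class"] == "EG", "gene_id"
        ]
        mu = dn.MatchedUniverse(homogeneous_universe)
        gene_arr = homogeneous_universe["gene_id"].to_numpy()
        rej = 0
        n_stud = 300
        for _ in range(n_stud):
            ev = events_frame(gene_arr[rng.integers(0, 200, size=300)])
            res = dn.permute_study(
                ev, homogeneous_universe, eg, n_perm=200, seed=rng, matched=mu
            )
            rej += res.perm_p <= 0.05
        assert 0.02 <= rej / n_stud <= 0.09


@given(
    counts=st.lists(st.integers(min_value=0, max_value=50), min_size=5, max_size=60),
)
@settings(max_examples=50, deadline=None)
def test_perm_p_monotone_in_observed_count(counts):
    counts = np.array(counts)
    ps = [dn.permutation_pvalue(counts, obs) for obs in range(0, 52)]
    assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))
    assert all(0 < p <= 1 for p in ps)


class TestMeta:
    def test_closed_form_worked_example(self):
        res = dn.meta_fixed_effects([(0.2, 0.1), (0.4, 0.2)])
        assert res.log_combined == pytest.approx(0.24)
        assert res.se_combined == pytest.approx(0.08944, abs=1e-5)
        assert res.cochran_q == pytest.approx(0.8)
        assert res.q_df == 1
        assert res.q_p == pytest.approx(0.3711, abs=1e-4)

    def test_statsmodels_cross_check(self):
        from statsmodels.stats.meta_analysis import combine_effects

        theta = [0.15, -0.05, 0.3, 0.22]
        se = [0.12, 0.2, 0.4, 0.09]
        ours = dn.meta_fixed_effects(list(zip(theta, se)))
        sm = combine_effects(np.array(theta), np.array(se) ** 2)
        frame = sm.summary_frame()
        assert ours.log_combined == pytest.approx(frame.loc["fixed effect", "eff"])
        assert ours.se_combined == pytest.approx(frame.loc["fixed effect", "sd_eff"])
        assert ours.cochran_q == pytest.approx(sm.q)

    def test_identical_studies_zero_q(self):
        res = dn.meta_fixed_effects([(0.3, 0.1), (0.3, 0.1)])
        assert res.cochran_q == pytest.approx(0.0, abs=1e-12)

    def test_single_study_degenerate(self):
        res = dn.meta_fixed_effects([(0.3, 0.1)])
        assert res.log_combined == pytest.approx(0.3)
        assert res.cochran_q == 0.0 and res.q_df == 0 and res.q_p == 1.0

    def test_order_invariance_and_equal_weights(self):
        studies = [(0.1, 0.2), (0.5, 0.2), (0.3, 0.2)]
        a = dn.meta_fixed_effects(studies)
        b = dn.meta_fixed_effects(studies[::-1])
        assert a.log_combined == pytest.approx(b.log_combined)
        assert a.log_combined == pytest.approx(np.mean([s[0] for s in studies]))

    def test_combined_within_study_range(self):
        studies = [(0.1, 0.05), (0.6, 0.3), (0.4, 0.1)]
        res = dn.meta_fixed_effects(studies)
        assert 0.1 <= res.log_combined <= 0.6

    def test_nonfinite_se_skipped(self):
        res = dn.meta_fixed_effects([(0.3, 0.1), (99.0, float("nan"))])
        assert res.n_studies == 1 and res.log_combined == pytest.approx(0.3)

    def test_no_usable_study_rejected(self):
        with pytest.raises(ValueError):
            dn.meta_fixed_effects([(0.3, float("nan"))])


class TestRunAnalysis:
    def test_case_enriched_control_null(self):
        g = sd.generate_gene_universe(
            sd.UniverseConfig(n_genes=6000, eg_length_multiplier=1.0, seed=55)
        )
        ev = pd.concat(
            [
                sd.simulate_denovo_study(
                    g,
                    sd.DeNovoStudyConfig(
                        study_id=f"s{i}", n_case_events=300, n_control_events=300,
                        true_or=1.8, seed=60 + i,
                    ),
                )
                for i in range(3)
            ],
            ignore_index=True,
        )
        rep = dn.run_denovo_analysis(ev, g, "EG", n_perm=500, seed=5)
        assert rep["case"]["meta"].combined_or > rep["control"]["meta"].combined_or
        assert rep["case"]["meta"].combined_or > 1.2
        assert 0.6 < rep["control"]["meta"].combined_or < 1.4

    def test_deterministic_for_seed(self, homogeneous_universe):
        gene_arr = homogeneous_universe["gene_id"].to_numpy()
        rng = np.random.default_rng(6)
        ev = events_frame(gene_arr[rng.integers(0, 200, size=50)])
        r1 = dn.run_denovo_analysis(ev, homogeneous_universe, "EG", n_perm=200, seed=9)
        r2 = dn.run_denovo_analysis(ev, homogeneous_universe, "EG", n_perm=200, seed=9)
        pd.testing.assert_frame_equal(r1["case"]["table"], r2["case"]["table"])
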