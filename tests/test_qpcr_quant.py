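"""Standard-curve efficiency, plate QC, Pfaffl NRQ arithmetic, classification
and the exact Mann-Whitney test."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from mircode.qpcr_quant import (CtRecord, DilutionSeries, QpcrConfig, classification_summary,
                                classify_interaction, estimate_efficiency, fold_difference,
                                mann_whitney_exact, mitrap_nrq_table, mitrap_ratio,
                                pfaffl_nrq, qc_filter, relative_expression)
from mircode import synthetic_data as synth


class TestEstimateEfficiency:
    def test_printed_slope_gives_1_952(self):
        pts = [(float(k), 10.0 + 3.4426 * k) for k in range(5)]
        est = estimate_efficiency(DilutionSeries(pts))
        assert round(est.efficiency, 3) == 1.952
        assert est.r2 == pytest.approx(1.0)

    def test_perfect_doubling_slope(self):
        pts = [(float(k), 10.0 + k / math.log10(2)) for k in range(5)]
        assert round(estimate_efficiency(DilutionSeries(pts)).efficiency, 3) == 2.0

    @pytest.mark.parametrize("e", [1.8, 1.9, 1.952, 2.0])
    def test_generator_round_trip_recovers_configured_efficiency(self, e):
        series = synth.gen_dilution_series(e, n_points=6)
        assert estimate_efficiency(series).efficiency == pytest.approx(e, abs=1e-9)

    def test_noisy_curve_raises_low_r2_warning_flag(self):
        series = synth.gen_dilution_series(1.9, n_points=6, noise_sd=2.0, rng_seed=3)
        assert estimate_efficiency(series).low_r2_warning

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            DilutionSeries([(0.0, 20.0), (1.0, 23.0)])

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            estimate_efficiency(DilutionSeries([(0.0, 20.0), (1.0, 20.0), (2.0, 20.0)]))


class TestQcFilter:
    def test_no_rt_margin_exclusion(self):
        recs = [CtRecord("s1", "miR-x", "wt_utr", 1, 30.0),
                CtRecord("s1", "miR-x", "wt_utr", 1, 38.0, rt_control=True)]
        res = qc_filter(recs)
        assert res.kept == []
        assert [(r.sample, reason) for r, reason in res.discarded] == [("s1", "no_rt_margin")]

    def test_margin_of_12_cycles_passes(self):
        recs = [CtRecord("s1", "miR-x", "wt_utr", 1, 26.0),
                CtRecord("s1", "miR-x", "wt_utr", 1, 38.0, rt_control=True)]
        res = qc_filter(recs)
        assert len(res.kept) == 1 and res.discarded == []

    def test_triplicate_sd_above_half_cycle_discarded(self):
        recs = [CtRecord("s1", "miR-x", "wt_utr", i, ct)
                for i, ct in enumerate((25.0, 25.4, 26.2), 1)]
        assert np.std([25.0, 25.4, 26.2], ddof=1) > 0.5  # independent check
        res = qc_filter(recs)
        assert res.kept == []
        assert {reason for _, reason in res.discarded} == {"replicate_sd"}

    def test_tight_triplicate_kept(self):
        recs = [CtRecord("s1", "miR-x", "wt_utr", i, ct)
                for i, ct in enumerate((25.0, 25.2, 25.4), 1)]
        assert len(qc_filter(recs).kept) == 3

    def test_undetermined_control_substituted_when_detected_in_all_wt(self):
        recs = ([CtRecord(f"wt{i}", "miR-x", "wt_utr", 1, 28.0) for i in range(1, 5)]
                + [CtRecord("ctl1", "miR-x", "control_utr", 1, None)])
        res = qc_filter(recs)
        subbed = [r for r in res.kept if r.condition == "control_utr"]
        assert subbed[0].ct == 40.0 and res.substituted

    def test_no_substitution_when_wt_detection_fails(self):
        recs = ([CtRecord(f"wt{i}", "miR-x", "wt_utr", 1, 28.0) for i in range(1, 4)]
                + [CtRecord("wt4", "miR-x", "wt_utr", 1, None)]
                + [CtRecord("ctl1", "miR-x", "control_utr", 1, None)])
        res = qc_filter(recs)
        assert not res.detected["miR-x"]
        assert all(r.ct is None for r in res.kept if r.condition == "control_utr")

    def test_idempotent_and_reasons_partition_discards(self):
        recs = ([CtRecord("s1", "a", "wt_utr", i, ct)
                 for i, ct in enumerate((25.0, 25.4, 26.2), 1)]
                + [CtRecord("s2", "b", "wt_utr", 1, 30.0),
                   CtRecord("s2", "b", "wt_utr", 1, 35.0, rt_control=True),
                   CtRecord("s3", "c", "wt_utr", 1, 22.0)])
        res = qc_filter(recs)
        n_input = len([r for r in recs if not r.rt_control])
        assert len(res.kept) + len(res.discarded) == n_input
        again = qc_filter(res.kept)
        assert again.kept == res.kept and again.discarded == []

    def test_missing_rt_partner_error_mode(self):
        recs = [CtRecord("s1", "a", "wt_utr", 1, 25.0),
                CtRecord("s2", "b", "wt_utr", 1, 25.0, rt_control=True)]
        with pytest.raises(ValueError):
            qc_filter(recs, QpcrConfig(missing_rt_partner="error"))


class TestQuantArithmetic:
    def test_relative_expression_examples(self):
        assert relative_expression(25.0, 25.0) == 1.0
        assert relative_expression(30.0, 20.0) == pytest.approx(2.0 ** -10)
        # an expression bracket of 0.01% of the reference corresponds to
        # dCt = log2(1e-4)
        dct = math.log2(1e-4)
        assert relative_expression(20.0 - dct, 20.0) == pytest.approx(1e-4)
        assert relative_expression(None, 20.0) is None

    def test_fold_difference_examples(self):
        assert fold_difference(1.5, 22.0, 22.0) == 1.0
        assert fold_difference(1.952, 25.0, 20.0) == pytest.approx(1.952 ** 5)
        assert fold_difference(2.0, 22.32, 20.0) == pytest.approx(5.0, abs=2e-2)
        with pytest.raises(ValueError):
            fold_difference(0.9, 20.0, 18.0)

    def test_pfaffl_nrq_examples(self):
        assert pfaffl_nrq(0.0, 0.0) == 1.0
        assert pfaffl_nrq(3.0, 1.0) == pytest.approx(8.0 / 1.952)
        assert pfaffl_nrq(None, 1.0) is None

    def test_pfaffl_reduces_to_ddct_when_both_efficiencies_are_2(self):
        cfg = QpcrConfig(e_bait=2.0, e_taqman=2.0)
        for dm, db in ((3.0, 1.0), (-2.0, 0.5), (0.0, 0.0)):
            assert pfaffl_nrq(dm, db, cfg) == pytest.approx(2.0 ** (dm - db))

    def test_mitrap_ratio_examples(self):
        cfg = QpcrConfig()
        pulldown = 1.952 ** 20 / 2.0 ** 25
        assert mitrap_ratio(20.0, 25.0, pulldown) == pytest.approx(1.0)
        assert mitrap_ratio(20.0, 25.0, 0.01) == pytest.approx(pulldown / 0.01)
        one_cycle_more = mitrap_ratio(20.0, 26.0, 0.01, cfg)
        assert one_cycle_more == pytest.approx(mitrap_ratio(20.0, 25.0, 0.01, cfg) / 2)
        assert mitrap_ratio(20.0, 25.0, 0.0) is None


class TestClassifyInteraction:
    def test_all_replicates_clear_of_1_is_high_confidence(self):
        r = classify_interaction("miR-x", [3.5, 4.2, 5.0, 3.9], True)
        assert r.category == "high_confidence"
        assert r.ci95[0] > 1 and r.ci95[0] <= r.nrq <= r.ci95[1]

    def test_wide_interval_reaching_1_is_low_confidence(self):
        r = classify_interaction("miR-x", [0.6, 1.2, 2.8, 4.0], True)
        assert r.nrq > 1 and r.ci95[0] <= 1
        assert r.category == "low_confidence"

    def test_nrq_at_or_below_1_is_non_specific(self):
        r = classify_interaction("miR-x", [0.9, 1.1, 0.95, 1.05], True)
        assert r.category == "non_specific"

    def test_undetected_is_no_interaction(self):
        r = classify_interaction("miR-x", [], False)
        assert r.category == "no_interaction" and r.nrq is None

    def test_fewer_replicates_than_required_rejected(self):
        with pytest.raises(ValueError):
            classify_interaction("miR-x", [2.0, 3.0], True)

    def test_geometric_mean_is_the_point_estimate(self):
        vals = [2.0, 8.0, 4.0, 1.0]
        r = classify_interaction("miR-x", vals, True)
        assert r.nrq == pytest.approx(float(np.exp(np.mean(np.log(vals)))))

    def test_summary_percentages_sum_to_100(self):
        results = {f"m{i}": classify_interaction(f"m{i}", [2.0 + i, 3.0, 4.0, 5.0], True)
                   for i in range(3)}
        results["m9"] = classify_interaction("m9", [], False)
        s = classification_summary(results)
        assert sum(s["percent"].values()) == pytest.approx(100.0)
        assert s["interactors"]["count"] == sum(
            s["counts"][c] for c in ("high_confidence", "low_confidence"))


class TestPipelineRoundTrip:
    def test_noiseless_synthetic_nrq_equals_configured_enrichment(self):
        spec = synth.CtSimSpec(enrichments={"miR-a": 8.0, "miR-b": 2.5, "miR-c": 1.0})
        results = mitrap_nrq_table(synth.gen_ct_experiment(spec, rng_seed=17))
        assert results["miR-a"].nrq == pytest.approx(8.0)
        assert results["miR-b"].nrq == pytest.approx(2.5)
        assert results["miR-c"].category == "non_specific"

    def test_dropout_yields_no_interaction(self):
        spec = synth.CtSimSpec(enrichments={"miR-a": 8.0, "miR-gone": 8.0},
                               mirna_baseline_ct=24.0)
        recs = synth.gen_ct_experiment(spec, rng_seed=17)
        # push one assay's wild-type wells over the detection ceiling
        recs = [r if r.assay != "miR-gone" or r.condition != "wt_utr"
                else type(r)(r.sample, r.assay, r.condition, r.replicate, None,
                             r.rt_control)
                for r in recs]
        results = mitrap_nrq_table(recs)
        assert results["miR-gone"].category == "no_interaction"
        assert results["miR-a"].category == "high_confidence"


class TestMannWhitneyExact:
    def test_complete_separation_5v5(self):
        r = mann_whitney_exact([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert round(r.p_two_sided, 4) == 0.0079
        assert r.p_two_sided == pytest.approx(2 / math.comb(10, 5))
        assert r.exact

    def test_identical_groups_give_p_1(self):
        assert mann_whitney_exact([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]).p_two_sided == 1.0

    def test_symmetric_under_group_exchange(self, rng):
        for _ in range(20):
            a = rng.normal(size=4).tolist()
            b = rng.normal(size=5).tolist()
            assert mann_whitney_exact(a, b).p_two_sided == \
                pytest.approx(mann_whitney_exact(b, a).p_two_sided, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        a = rng.normal(size=5).tolist()
        b = rng.normal(size=4).tolist()
        p0 = mann_whitney_exact(a, b).p_two_sided
        assert mann_whitney_exact([math.exp(v) for v in a],
                                  [math.exp(v) for v in b]).p_two_sided == \
            pytest.approx(p0, abs=1e-12)

    def test_matches_scipy_exact_on_tie_free_samples(self, rng):
        for _ in range(50):
            na, nb = int(rng.integers(3, 7)), int(rng.integers(3, 7))
            pooled = rng.permutation(np.arange(1.0, na + nb + 1))
            a, b = pooled[:na].tolist(), pooled[na:].tolist()
            ours = mann_whitney_exact(a, b).p_two_sided
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(float(ref), abs=1e-12)

    def test_tied_data_matches_hand_permutation_oracle(self):
        a, b = [1.0, 2.0, 2.0], [2.0, 3.0]
        pooled = a + b
        ranks = stats.rankdata(pooled)
        u_obs = sum(ranks[:3]) - 3 * 4 / 2
        n_le = n_ge = 0
        combos = list(itertools.combinations(range(5), 3))
        for idx in combos:
            u = sum(ranks[i] for i in idx) - 3 * 4 / 2
            n_le += u <= u_obs + 1e-9
            n_ge += u >= u_obs - 1e-9
        expected = min(1.0, 2 * min(n_le / len(combos), n_ge / len(combos)))
        assert mann_whitney_exact(a, b).p_two_sided == pytest.approx(expected, abs=1e-12)

    def test_large_samples_fall_back_to_flagged_approximation(self, rng):
        a = rng.normal(size=10).tolist()
        b = rng.normal(size=10).tolist()
        r = mann_whitney_exact(a, b)
        assert not r.exact and 0 <= r.p_two_sided <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0])
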