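"""Time-course analysis: profiles, IC50 screen, trends, selection, PDPs."""

import numpy as np
import pandas as pd
import pytest

from bcproteodyn.dynamics import (ic50_screen, opposite_dynamics_select,
                                  pathway_consistency, pdp_detect,
                                  summarize_timecourse, trend_stats,
                                  trend_table)
from bcproteodyn.io import (DrugResponseTable, PathwayAnnotation,
                            TimeCourseExperiment)
from bcproteodyn.simulate import TimeCourseSimSpec, generate_timecourse

TIMES = (0.0, 4.0, 12.0, 24.0, 48.0, 72.0)


def _tc(values, lines, tnbc, drugs=("d1",), n_reps=3):
    cols = pd.MultiIndex.from_product(
        [lines, drugs, TIMES, range(1, n_reps + 1)],
        names=["cell_line", "drug", "time_h", "replicate"])
    df = pd.DataFrame(values, columns=cols,
                      index=[f"P{i}" for i in range(values.shape[0])])
    return TimeCourseExperiment(df, dict(zip(lines, tnbc)))


class TestSummarize:
    def test_identical_replicates_preserved(self):
        vals = np.tile(np.arange(18, dtype=float), (2, 1))
        tc = _tc(np.tile(vals, (1, 1)), ["L1"], [True])
        prof = summarize_timecourse(tc)
        assert np.allclose(prof.values.iloc[0],
                           tc.values.iloc[0].groupby(level="time_h").mean())

    def test_mean_skips_missing(self):
        vals = np.full((1, 18), 5.0)
        vals[0, 0] = np.nan
        vals[0, 1] = 5.0
        vals[0, 2] = 7.0
        tc = _tc(vals, ["L1"], [True])
        prof = summarize_timecourse(tc)
        assert prof.values.loc["P0", ("L1", "d1", 0.0)] == 6.0
        assert prof.counts.loc["P0", ("L1", "d1", 0.0)] == 2

    def test_noiseless_planted_ratio(self, ):
        spec = TimeCourseSimSpec(n_proteins=420, noise_sd=0.0,
                                 target_missing_fraction=0.0, seed=1)
        tc, _resp, truth = generate_timecourse(spec)
        prof = summarize_timecourse(tc)
        drug = tc.drugs[0]
        prot, fc = next(iter(truth.monotone[drug].items()))
        line = tc.cell_lines[0]
        row = prof.values.loc[prot, (line, drug)]
        assert 2 ** (row[72.0] - row[0.0]) == pytest.approx(fc)


class TestIc50Screen:
    def _planted(self, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        lines = [f"L{i}" for i in range(9)]
        ic50 = rng.normal(-6, 1, 9)
        vals = np.empty((3, 9 * 1 * 6 * 3))
        z = (ic50 - ic50.mean()) / ic50.std()
        col = 0
        for li in range(9):
            for _t in TIMES:
                for _r in range(3):
                    vals[0, col] = 20 + z[li] + noise * rng.standard_normal()
                    vals[1, col] = 20 - z[li] + noise * rng.standard_normal()
                    vals[2, col] = 20.0
                    col += 1
        tc = _tc(vals, lines, [True] * 5 + [False] * 4)
        resp = DrugResponseTable(pd.DataFrame({"d1": ic50}, index=lines))
        return tc, resp

    def test_noiseless_tracking_classified(self):
        tc, resp = self._planted()
        screen = ic50_screen(summarize_timecourse(tc), resp)
        assert screen.loc[("d1", "P0"), "ic50_class"] == "resistance_associated"
        assert screen.loc[("d1", "P1"), "ic50_class"] == "sensitivity_associated"
        assert screen.loc[("d1", "P0"), "mean_r"] == pytest.approx(1.0)

    def test_constant_protein_excluded(self):
        tc, resp = self._planted()
        screen = ic50_screen(summarize_timecourse(tc), resp)
        assert not screen.loc[("d1", "P2"), "eligible"]
        assert screen.loc[("d1", "P2"), "ic50_class"] == "none"

    def test_invariant_to_linear_ic50_rescaling(self):
        tc, resp = self._planted(noise=0.3, seed=3)
        screen1 = ic50_screen(summarize_timecourse(tc), resp)
        resp2 = DrugResponseTable(resp.values * 2.0 + 3.0)
        screen2 = ic50_screen(summarize_timecourse(tc), resp2)
        pd.testing.assert_series_equal(screen1["mean_r"], screen2["mean_r"])

    def test_planted_r08_detection_rate(self):
        detected = []
        for seed in range(10):
            spec = TimeCourseSimSpec(n_proteins=420, seed=200 + seed)
            tc, resp, truth = generate_timecourse(spec)
            screen = ic50_screen(summarize_timecourse(tc), resp)
            correct = total = 0
            for drug, planted in truth.ic50_tracking.items():
                for prot, sign in planted.items():
                    want = ("resistance_associated" if sign > 0
                            else "sensitivity_associated")
                    correct += screen.loc[(drug, prot), "ic50_class"] == want
                    total += 1
            detected.append(correct / total)
        assert np.mean([d >= 0.8 for d in detected]) >= 0.8


class TestTrendStats:
    def _flat_tc(self):
        return _tc(np.full((1, 18), 7.0), ["L1"], [True])

    def test_flat_profile_no_direction(self):
        p, fc, direction = trend_stats(self._flat_tc(), "P0", "L1", "d1")
        assert p == 1.0 and fc == 1.0 and direction == 0

    def test_noiseless_doubling_direction_up(self):
        prof = np.repeat([10, 11, 12, 13, 14, 15.0], 3)
        tc = _tc(prof[None, :], ["L1"], [True])
        p, fc, direction = trend_stats(tc, "P0", "L1", "d1")
        assert direction == 1
        assert fc == pytest.approx(2.0 ** 5)
        assert p == 0.0      # zero within-group variance, shifted means

    def test_missing_endpoint_makes_fc_uncomputable(self):
        prof = np.repeat([10, 11, 12, 13, 14, 15.0], 3)
        prof_missing = prof.copy()
        prof_missing[-3:] = np.nan
        tc = _tc(prof_missing[None, :], ["L1"], [True])
        _p, fc, direction = trend_stats(tc, "P0", "L1", "d1")
        assert np.isnan(fc) and direction == 0

    def test_planted_trends_significant_after_bh(self, timecourse):
        tc, _resp, truth = timecourse
        table = trend_table(tc)
        drug = tc.drugs[0]
        planted = set(truth.monotone[drug])
        sub = table[(table["drug"] == drug)
                    & table["feature"].isin(planted) & table["tested"]]
        called = sub[(sub["adj_p"] < 0.05) & (sub["log2_fc"].abs() > 1)
                     & (sub["direction"] != 0)]
        assert len(called) / len(sub) >= 0.9


class TestOppositeDynamics:
    def test_planted_set_recovered(self, timecourse):
        tc, _resp, truth = timecourse
        sel = opposite_dynamics_select(tc)
        got, want = set(sel.selected), set(truth.opposite)
        assert len(got & want) / len(want) >= 0.9
        assert len(got & want) / max(len(got), 1) >= 0.9

    def test_same_direction_proteins_never_selected(self, timecourse):
        tc, _resp, truth = timecourse
        sel = opposite_dynamics_select(tc)
        monotone_everywhere = set().union(*truth.monotone.values())
        assert not set(sel.selected) & monotone_everywhere

    def test_small_fold_change_rejected(self):
        spec = TimeCourseSimSpec(n_proteins=420, opposite_fc=1.5,
                                 noise_sd=0.05, seed=4)
        tc, _resp, truth = generate_timecourse(spec)
        sel = opposite_dynamics_select(tc)
        assert not set(sel.selected) & set(truth.opposite)

    def test_mixed_relabeling_destroys_selection(self, timecourse):
        """Selection must track the group structure, not arbitrary labels.

        With 5+4 lines, any relabeling other than the maximally mixed one
        (3 of 5 new-TNBC slots filled by true TNBC lines) leaves both groups
        with a true-direction majority, so the planted opposition genuinely
        persists there; the informative null is the mixed relabeling, which
        must destroy the selection.
        """
        tc, _resp, truth = timecourse
        rng = np.random.default_rng(0)
        lines = np.array(sorted(tc.tnbc))
        true_flags = np.array([tc.tnbc[l] for l in lines])
        retained = []
        n_shuffles = 0
        while n_shuffles < 5:
            perm = rng.permutation(true_flags)
            if (perm & true_flags).sum() != 3:   # keep maximally mixed only
                continue
            n_shuffles += 1
            shuffled = TimeCourseExperiment(tc.values,
                                            dict(zip(lines, perm)))
            sel = opposite_dynamics_select(shuffled)
            want = set(truth.opposite)
            retained.append(len(set(sel.selected) & want) / len(want))
        assert np.mean(retained) <= 0.05

    def test_intersection_mode_is_subset_of_union(self, timecourse):
        tc, _resp, _truth = timecourse
        union = opposite_dynamics_select(tc, intersect_drugs=False)
        inter = opposite_dynamics_select(tc, intersect_drugs=True)
        assert set(inter.selected) <= set(union.selected)


class TestPathwayConsistency:
    def _selection(self, timecourse):
        tc, _resp, _truth = timecourse
        return tc, opposite_dynamics_select(tc)

    def test_pathway_hit_in_all_lines_passes(self, timecourse):
        tc, sel = self._selection(timecourse)
        pw = PathwayAnnotation({"ALL": frozenset(sel.selected)})
        table = pathway_consistency(sel, pw, tc)
        assert table.loc["ALL", "passes"]

    def test_unrepresented_pathway_fails(self, timecourse):
        tc, sel = self._selection(timecourse)
        pw = PathwayAnnotation({"NONE": frozenset({"not_a_protein"})})
        table = pathway_consistency(sel, pw, tc)
        assert not table.loc["NONE", "passes"]

    def test_boundary_thresholds_inclusive(self, timecourse):
        # thresholds 3/5 TNBC and 2/4 non-TNBC are inclusive at the boundary
        tc, sel = self._selection(timecourse)
        pw = PathwayAnnotation({"ALL": frozenset(sel.selected)})
        table = pathway_consistency(sel, pw, tc, tnbc_min=3 / 5,
                                    non_tnbc_min=2 / 4)
        assert table.loc["ALL", "n_tnbc_lines_hit"] >= 3
        assert table.loc["ALL", "n_non_tnbc_lines_hit"] >= 2
        assert table.loc["ALL", "passes"]

    def test_empty_annotation_gives_empty_table(self, timecourse):
        tc, sel = self._selection(timecourse)
        assert pathway_consistency(sel, PathwayAnnotation({}), tc).empty


class TestPdpDetect:
    def test_boundary_fraction_strict(self):
        # protein DE in 3/5 TNBC lines (= 60 %) is NOT a PDP under "> 60 %"
        rng = np.random.default_rng(5)
        lines = [f"L{i}" for i in range(5)]
        vals = rng.normal(20, 0.05, (2, 5 * 6 * 3))
        tc = _tc(vals, lines, [True] * 5)
        shifted = tc.values.copy()
        # shift protein P0 at 72h in 3 of 5 lines; P1 in 5 of 5
        for li, line in enumerate(lines):
            cols = [c for c in shifted.columns
                    if c[0] == line and c[2] == 72.0]
            if li < 3:
                shifted.loc["P0", cols] += 2.0
            shifted.loc["P1", cols] += 2.0
        tc2 = TimeCourseExperiment(shifted, tc.tnbc)
        pdps = pdp_detect(tc2, "d1")
        assert "P1" in pdps and "P0" not in pdps

    def test_persistent_recovered_transient_excluded(self, timecourse):
        tc, _resp, truth = timecourse
        drug = tc.drugs[0]
        pdps = set(pdp_detect(tc, drug))
        persistent = set(truth.monotone[drug]) | set(truth.opposite)
        transient = set(truth.transient)
        assert not pdps & transient
        assert len(pdps & persistent) / len(set(truth.monotone[drug])) >= 0.5
        # everything detected is explained by a planted persistent signal
        assert (pdps - persistent) == set()
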