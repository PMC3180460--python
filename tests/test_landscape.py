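"""Coverage arithmetic, rate regression, interval building/scoring, hotspot
merging and the centromere coldspot statistics."""

import numpy as np
import pandas as pd
import pytest

from tetrascope import landscape as ls
from tetrascope import meiosis_sim as ms
from tetrascope.genome_io import Chromosome, GenomeMap


class TestCoverageAdjust:
    def test_study_arithmetic(self):
        assert ls.coverage_adjust(8_501, 0.23) == pytest.approx(10_456.23)
        assert ls.coverage_adjust(2_976, 0.23) / 120 == pytest.approx(30.504)

    def test_identity_and_monotonicity(self):
        assert ls.coverage_adjust(123.0, 0.0) == 123.0
        for u in (0.1, 0.5, 0.9):
            assert ls.coverage_adjust(100, u) >= 100
        assert ls.coverage_adjust(100, 0.23, mode="renormalize") == \
            pytest.approx(100 / 0.77)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            ls.coverage_adjust(1, 1.0)


class TestRegression:
    def test_exact_linear_input(self, study_genome):
        n = 120
        counts = {c.id: n * (0.6 + 6.5 * c.effective_length / 1e6)
                  for c in study_genome.chromosomes}
        fit = ls.chromosome_event_regression(counts, study_genome, n)
        assert fit["intercept"] == pytest.approx(0.6, abs=1e-9)
        assert fit["slope"] == pytest.approx(6.5, abs=1e-9)

    def test_all_zero_counts(self, study_genome):
        fit = ls.chromosome_event_regression({}, study_genome, 10)
        assert fit["intercept"] == 0.0 and fit["slope"] == 0.0

    def test_simulated_cohort_recovery(self, study_genome, study_cohort):
        """True per-chromosome CO counts from the generator recover the
        configured (0.6, 6.5) rate law within 3 standard errors."""
        _, truth = study_cohort
        counts = truth[truth["type"] == "CO"].groupby("chrom").size().to_dict()
        fit = ls.chromosome_event_regression(counts, study_genome, 60)
        assert abs(fit["slope"] - 6.5) < 3 * fit["slope_se"]
        # obligate resampling biases the intercept upward slightly
        assert abs(fit["intercept"] - 0.6) < 3 * fit["intercept_se"] + 0.15


class TestIntervals:
    def test_short_gap_merges_right(self):
        chrom = Chromosome("1", 100_000, 50_000)
        g = GenomeMap([chrom], pd.DataFrame({
            "chrom": "1", "pos": [1_000, 1_500, 4_000],
            "marker_id": ["a", "b", "c"]}))
        iv = ls.build_intervals(g)
        assert iv[["left", "right"]].values.tolist() == [[1_000, 4_000]]

    def test_wide_spacing_unchanged(self):
        chrom = Chromosome("1", 100_000, 50_000)
        pos = list(range(10_000, 40_000, 3_000))
        g = GenomeMap([chrom], pd.DataFrame({
            "chrom": "1", "pos": pos,
            "marker_id": [f"m{i}" for i in range(len(pos))]}))
        iv = ls.build_intervals(g)
        assert len(iv) == len(pos) - 1
        assert (iv["size"] == 3_000).all()

    def test_merge_is_idempotent(self, study_genome):
        iv = ls.build_intervals(study_genome)
        assert (iv["size"] >= 2_000).all()
        spans = [(r.left, r.right, r.n_markers)
                 for r in iv.itertuples(index=False)]
        assert ls._merge_short(spans, 2_000) == spans

    def test_trailing_short_interval_merges_left(self):
        chrom = Chromosome("1", 100_000, 50_000)
        g = GenomeMap([chrom], pd.DataFrame({
            "chrom": "1", "pos": [1_000, 4_000, 4_500],
            "marker_id": ["a", "b", "c"]}))
        iv = ls.build_intervals(g)
        assert iv[["left", "right"]].values.tolist() == [[1_000, 4_500]]


class TestScoring:
    def _interval(self):
        return pd.DataFrame({"chrom": ["1"], "left": [10_000],
                             "right": [20_000], "size": [10_000],
                             "n_markers": [2]})

    def test_expected_and_score_arithmetic(self):
        ev = pd.DataFrame({
            "tetrad": [f"t{i}" for i in range(16)], "chrom": "1",
            "type": "CO", "left": 12_000, "right": 14_000,
            "multiplicity": 1, "direction": "",
        })
        st = ls.score_intervals(ev, self._interval(), n_tetrads=120)
        assert st["expected_co"].iloc[0] == pytest.approx(7.8)
        assert st["score_co"].iloc[0] == pytest.approx(16 / 7.8)

    def test_zero_observed_zero_score(self):
        ev = pd.DataFrame(columns=["tetrad", "chrom", "type", "left", "right",
                                   "multiplicity", "direction"])
        st = ls.score_intervals(ev, self._interval(), n_tetrads=120)
        assert st["score_co"].iloc[0] == 0.0

    def test_event_conservation_under_assignment(self, study_genome,
                                                 study_events):
        """Midpoint assignment neither loses nor double-counts events that
        fall inside the covered span."""
        events, summary = study_events
        iv = ls.build_intervals(study_genome)
        st = ls.score_intervals(events, iv, n_tetrads=summary["n_tetrads"])
        idx = ls.assign_events_to_intervals(events, iv)
        co = events["type"] == "CO"
        in_cover = idx >= 0
        assert st["co_count"].sum() == \
            events.loc[co & in_cover, "multiplicity"].sum()
        assert st["ncogc_count"].sum() == \
            ((events["type"] == "NCOGC") & in_cover).sum()
        # CO events always sit between two markers, hence inside an interval
        assert in_cover[co].all()

    def test_uniform_simulation_mean_score_near_one(self):
        """With a pure 6.5/Mb crossover process (no intercept, no obligate
        event, no suppression) on a fully markered chromosome, the
        expectation-weighted mean interval score is ~1."""
        chrom = Chromosome("1", 1_000_000, 500_000)
        pos = np.arange(1_000, 1_000_000, 2_500)
        g = GenomeMap([chrom], pd.DataFrame({
            "chrom": "1", "pos": pos,
            "marker_id": [f"m{i}" for i in range(len(pos))]}))
        cfg = ms.SimulationConfig(co_intercept=0.0, obligate_co=False,
                                  ncogc_intercept=0.0, ncogc_slope=0.0,
                                  centromere_suppression=None,
                                  lsp_suppression=None, seed=31)
        _, truth = ms.simulate_cohort(g, cfg, 120)
        truth = truth.rename(columns={"start": "left", "end": "right"})
        truth["multiplicity"] = 1
        iv = ls.build_intervals(g)
        st = ls.score_intervals(truth, iv, 120)
        weighted = (st["score_co"] * st["expected_co"]).sum() / st["expected_co"].sum()
        assert weighted == pytest.approx(1.0, abs=0.1)


class TestHotspots:
    def _stats(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "left", "right", "size",
                                           "n_markers", "score_co",
                                           "score_ncogc"])

    def test_contiguous_hot_intervals_merge(self):
        st = self._stats([
            ("1", 1_000, 3_000, 2_000, 2, 2.5, 0.0),
            ("1", 3_000, 5_000, 2_000, 2, 3.0, 0.0),
            ("1", 5_000, 7_000, 2_000, 2, 0.5, 0.0),
        ])
        hot = ls.detect_hotspots(st)
        assert len(hot) == 1
        assert hot.iloc[0]["midpoint"] == pytest.approx(3_000)
        assert hot.iloc[0]["kind"] == "CO"

    def test_threshold_is_strict_at_two(self):
        st = self._stats([("1", 1_000, 3_000, 2_000, 2, 1.99, 0.0)])
        assert ls.detect_hotspots(st).empty

    def test_both_kind_label_and_tetrad_fraction(self):
        st = self._stats([("1", 1_000, 3_000, 2_000, 2, 2.5, 2.5)])
        ev = pd.DataFrame({
            "tetrad": [f"t{i}" for i in range(34)], "chrom": "1",
            "type": "CO", "left": 1_500, "right": 2_500,
            "multiplicity": 1, "direction": "",
        })
        hot = ls.detect_hotspots(st, events=ev, n_tetrads=120)
        assert set(hot["kind"]) == {"both"}
        assert hot["tetrad_fraction"].iloc[0] == pytest.approx(34 / 120)

    def test_merging_is_order_invariant_and_disjoint(self, study_genome,
                                                     study_events):
        events, summary = study_events
        iv = ls.build_intervals(study_genome)
        st = ls.score_intervals(events, iv, n_tetrads=summary["n_tetrads"])
        hot1 = ls.detect_hotspots(st)
        hot2 = ls.detect_hotspots(st.sample(frac=1.0, random_state=0))
        cols = ["kind", "scored_by", "chrom", "left", "right"]
        a = hot1[cols].sort_values(cols).reset_index(drop=True)
        b = hot2[cols].sort_values(cols).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
        # hotspots of one origin kind never overlap each other
        for _, grp in hot1.groupby(["chrom", "scored_by"]):
            grp = grp.sort_values("left")
            assert (grp["left"].to_numpy()[1:] >= grp["right"].to_numpy()[:-1]).all()


class TestCentromeres:
    def test_suppressed_simulation_recovers_multiplier(self, study_genome):
        cfg = ms.SimulationConfig(seed=41, lsp_suppression=None,
                                  centromere_suppression=(22_900, 0.1))
        tetrads, truth = ms.simulate_cohort(study_genome, cfg, 40)
        truth = truth.rename(columns={"start": "left", "end": "right"})
        truth["multiplicity"] = 1
        iv = ls.build_intervals(study_genome)
        st = ls.score_intervals(truth, iv, 40)
        out = ls.centromere_analysis(truth, study_genome, st, 40)
        assert out["window_rate"] / out["genome_rate"] == \
            pytest.approx(0.1, abs=0.06)
        assert out["mannwhitney_p"] < 0.001

    def test_zero_crossovers_reports_na(self, study_genome):
        ev = pd.DataFrame(columns=["tetrad", "chrom", "type", "left", "right",
                                   "multiplicity", "direction"])
        st = pd.DataFrame(columns=["chrom", "left", "right", "size",
                                   "n_markers", "co_count"])
        out = ls.centromere_analysis(ev, study_genome, st, 10)
        assert out["window_rate"] == 0.0
        assert np.isnan(out["mannwhitney_p"])
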