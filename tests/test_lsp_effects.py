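"""LSP effect analyses: adjacent-region suppression, hotspot spacing,
sub-telomeric windows, non-parity association and distance correlations."""

import numpy as np
import pandas as pd
import pytest

from tetrascope import event_calling as ec
from tetrascope import landscape as ls
from tetrascope import lsp_effects as le
from tetrascope import meiosis_sim as ms
from tetrascope.genome_io import LSP, Chromosome, GenomeMap


def test_merge_spans_unions_overlaps():
    assert le.merge_spans([(1, 10), (5, 20), (30, 40)]) == [(1, 20), (30, 40)]
    assert le.merge_spans([]) == []


def test_reduction_arithmetic_on_study_rates():
    """A 1.72 CO/Mb adjacent rate against the 6.5 genome-wide rate is a 74%
    reduction."""
    ev = pd.DataFrame({"tetrad": ["t1"], "chrom": ["1"], "type": ["CO"],
                       "left": [50_000], "right": [52_000],
                       "multiplicity": [1], "direction": [""]})
    chrom = Chromosome("1", 1_000_000, 500_000)
    g = GenomeMap([chrom], pd.DataFrame({
        "chrom": "1", "pos": [1_000, 999_000], "marker_id": ["a", "b"]}))
    g.add_lsp(LSP("L1", "1", 45_000, 55_000, "heterozygous"))
    # choose tetrad count so the pooled rate is exactly 1.72/Mb
    pooled_mb = (55_000 - 45_000 + 2 * 10_000 + 1) / 1e6
    n = 1 / (1.72 * pooled_mb)
    out = le.lsp_adjacent_rates(ev, g, n_tetrads=n)
    assert out["co_rate"] == pytest.approx(1.72)
    assert round(out["co_reduction_pct"]) == 74


class TestAdjacentRates:
    @pytest.fixture(scope="class")
    def suppressed_cohort(self):
        genome = ms.synthetic_genome()
        lsps = ms.synthetic_lsps(genome, n_nonsub=15, n_sub=0)
        cfg = ms.SimulationConfig(seed=51, centromere_suppression=None,
                                  lsp_suppression=(10_000, 0.25))
        tetrads, truth = ms.simulate_cohort(genome, cfg, 60)
        events, _ = ec.call_all_events(tetrads, genome)
        return genome, events, truth

    def test_suppression_recovered(self, suppressed_cohort):
        """A 0.25 suppression multiplier over LSP regions shows up as a ~75%
        reduction in the adjacent-region CO rate, measured on the true event
        positions against the dataset's own genome-wide rate."""
        genome, _, truth = suppressed_cohort
        truth = truth.rename(columns={"start": "left", "end": "right"})
        truth["multiplicity"] = 1
        cos = truth[truth["type"] == "CO"]
        genome_mb = sum(c.effective_length for c in genome.chromosomes) / 1e6
        rate = {"CO": len(cos) / genome_mb / 60, "NCOGC": 1.0}
        out = le.lsp_adjacent_rates(cos, genome, 60, genome_rates=rate)
        assert out["co_reduction_pct"] == pytest.approx(75, abs=12)

    def test_no_lsps_returns_na(self):
        genome = ms.synthetic_genome()
        ev = pd.DataFrame(columns=["tetrad", "chrom", "type", "left",
                                   "right", "multiplicity", "direction"])
        out = le.lsp_adjacent_rates(ev, genome, 10)
        assert np.isnan(out["co_rate"]) and out["n_lsps"] == 0

    def test_pooled_region_merges_overlapping_flanks(self):
        chrom = Chromosome("1", 1_000_000, 500_000)
        g = GenomeMap([chrom], pd.DataFrame({
            "chrom": "1", "pos": [1_000, 999_000], "marker_id": ["a", "b"]}))
        g.add_lsp(LSP("L1", "1", 100_000, 110_000, "heterozygous"))
        g.add_lsp(LSP("L2", "1", 115_000, 125_000, "heterozygous"))
        ev = pd.DataFrame(columns=["tetrad", "chrom", "type", "left",
                                   "right", "multiplicity", "direction"])
        out = le.lsp_adjacent_rates(ev, g, 10)
        # 90k-135k as one merged region, not two overlapping 30/31-kb ones
        assert out["pooled_mb"] == pytest.approx(45_001 / 1e6)


class TestHotspotSpacing:
    def test_gap_classification(self):
        chrom = Chromosome("1", 1_000_000, 500_000)
        g = GenomeMap([chrom], pd.DataFrame({
            "chrom": "1", "pos": [1_000, 999_000], "marker_id": ["a", "b"]}))
        g.add_lsp(LSP("L1", "1", 120_000, 130_000, "heterozygous"))
        hot = pd.DataFrame({"chrom": ["1", "1", "1"],
                            "midpoint": [100_000.0, 160_000.0, 200_000.0]})
        out = le.hotspot_spacing_vs_lsp(hot, g)
        assert out["n_lsp_between"] == 1
        assert out["mean_gap_lsp_between"] == pytest.approx(60_000)
        assert out["n_baseline"] == 1
        assert out["mean_gap_baseline"] == pytest.approx(40_000)

    def test_no_lsps_all_baseline(self):
        genome = ms.synthetic_genome()
        hot = pd.DataFrame({"chrom": ["1"] * 3,
                            "midpoint": [1e5, 2e5, 3e5]})
        out = le.hotspot_spacing_vs_lsp(hot, genome)
        assert out["n_lsp_between"] == 0 and out["n_baseline"] == 2

    def test_suppression_widens_lsp_spanning_gaps(self):
        """Erasing recombination over LSP regions pushes hotspot spacing up
        when an LSP lies between consecutive hotspots."""
        genome = ms.synthetic_genome()
        ms.synthetic_lsps(genome, n_nonsub=15, n_sub=0)
        cfg = ms.SimulationConfig(seed=61, centromere_suppression=None,
                                  lsp_suppression=(10_000, 0.05))
        tetrads, _ = ms.simulate_cohort(genome, cfg, 60)
        events, _ = ec.call_all_events(tetrads, genome)
        iv = ls.build_intervals(genome)
        st = ls.score_intervals(events, iv, 60,
                                rates=ls.rates_from_events(events, genome, 60))
        hot = ls.detect_hotspots(st)
        out = le.hotspot_spacing_vs_lsp(hot, genome)
        assert out["n_lsp_between"] >= 3
        assert out["mean_gap_lsp_between"] > out["mean_gap_baseline"]


class TestSubtelomeres:
    def test_rates_and_distances_per_end(self):
        chrom = Chromosome("1", 400_000, 200_000)
        g = GenomeMap([chrom], pd.DataFrame({
            "chrom": "1", "pos": [5_000, 395_000], "marker_id": ["a", "b"]}))
        g.add_lsp(LSP("L1", "1", 2_000, 9_000, "heterozygous"))
        ev = pd.DataFrame({"tetrad": ["t1"], "chrom": ["1"], "type": ["CO"],
                           "left": [9_000], "right": [11_000],
                           "multiplicity": [1], "direction": [""]})
        hot = pd.DataFrame({"chrom": ["1"], "midpoint": [32_801.0]})
        out = le.subtelomere_analysis(ev, hot, g, n_tetrads=10)
        ends = out["ends"].set_index("end")
        assert bool(ends.loc["L", "lsp_class"]) and not bool(ends.loc["R", "lsp_class"])
        assert ends.loc["L", "co_rate"] == pytest.approx(1 / 0.03 / 10)
        assert ends.loc["L", "first_hotspot_distance"] == pytest.approx(32_800)

    def test_no_hotspots_distance_na(self):
        chrom = Chromosome("1", 400_000, 200_000)
        g = GenomeMap([chrom], pd.DataFrame({
            "chrom": "1", "pos": [5_000, 395_000], "marker_id": ["a", "b"]}))
        ev = pd.DataFrame(columns=["tetrad", "chrom", "type", "left",
                                   "right", "multiplicity", "direction"])
        hot = pd.DataFrame({"chrom": pd.Series(dtype=str),
                            "midpoint": pd.Series(dtype=float)})
        out = le.subtelomere_analysis(ev, hot, g, n_tetrads=10)
        assert out["ends"]["first_hotspot_distance"].isna().all()

    def test_nonsub_suppression_leaves_subtelomeres_null(self):
        """Suppression applied only to non-sub-telomeric LSPs produces no
        significant sub-telomeric class difference."""
        genome = ms.synthetic_genome()
        ms.synthetic_lsps(genome)
        cfg = ms.SimulationConfig(seed=71, centromere_suppression=None)
        tetrads, _ = ms.simulate_cohort(genome, cfg, 40)
        events, _ = ec.call_all_events(tetrads, genome)
        hot = pd.DataFrame({"chrom": pd.Series(dtype=str),
                            "midpoint": pd.Series(dtype=float)})
        out = le.subtelomere_analysis(events, hot, genome, n_tetrads=40)
        assert out["p_co_rate"] > 0.01


class TestNonparityAssociation:
    def _records(self, nonparity, distances):
        return pd.DataFrame({"nonparity": nonparity,
                             "lsp_distance": distances})

    def test_enumerated_table(self):
        rec = self._records(
            [True] * 3 + [False] * 49,
            [1_000, 5_000, 16_000] + [5_000] * 5 + [50_000] * 44)
        p = le.nonparity_lsp_association(rec)
        from scipy.stats import fisher_exact
        ref = fisher_exact([[3, 0], [5, 44]], alternative="two-sided")[1]
        assert p == pytest.approx(ref)

    def test_degenerate_cases(self):
        rec = self._records([False] * 4, [1.0, 2.0, 3.0, 4.0])
        assert le.nonparity_lsp_association(rec) == 1.0
        rec2 = self._records([True, False], [np.nan, np.nan])
        assert np.isnan(le.nonparity_lsp_association(rec2))
        rec3 = self._records([True, False], [5.0, 6.0])
        assert le.nonparity_lsp_association(rec3, distance_threshold=0) == 1.0


class TestCorrelations:
    def _frame(self, x, y):
        return pd.DataFrame({
            "chrom": "1", "pos": 1_000,
            "lsp_distance": x, "ratio_ncogc_co": y, "kb_per_cm": y,
            "ratio_is_bound": False, "kb_per_cm_is_bound": False,
        })

    def test_monotone_and_antimonotone(self):
        genome = ms.synthetic_genome()
        x = np.arange(1, 11, dtype=float)
        out = le.distance_correlations(self._frame(x, x * 3), genome)
        lsp_rows = out[out["distance"] == "lsp_distance"]
        assert lsp_rows["rho"].tolist() == pytest.approx([1.0, 1.0])
        out2 = le.distance_correlations(self._frame(x, -x), genome)
        assert out2[out2["distance"] == "lsp_distance"]["rho"].tolist() == \
            pytest.approx([-1.0, -1.0])

    def test_small_n_reports_na(self):
        genome = ms.synthetic_genome()
        out = le.distance_correlations(self._frame([1.0, 2.0], [1.0, 2.0]),
                                       genome)
        assert out["rho"].isna().all()
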