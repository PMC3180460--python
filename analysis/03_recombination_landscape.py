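#!/usr/bin/env python
"""Genome-wide recombination landscape of the simulated cohort.

Builds >=2-kb marker intervals, scores them against the homogeneous
6.5 CO / 2.6 NCOGC per-Mb expectations, merges contiguous >=2-fold intervals
into hotspots (TSV + BED), tests centromeric crossover suppression, and fits
the per-chromosome linear rate law on the ground-truth event counts.
"""

from pathlib import Path

import pandas as pd

from tetrascope import genome_io as gio
from tetrascope import landscape as ls

ROOT = Path(__file__).resolve().parents[1] / "results"
N_TETRADS = 120


def main() -> None:
    out = ROOT / "landscape"
    out.mkdir(parents=True, exist_ok=True)
    genome = gio.read_marker_map(ROOT / "cohort" / "marker_map.tsv")
    gio.read_lsp_table(ROOT / "cohort" / "lsps.tsv", genome)
    events = gio.read_events(ROOT / "events" / "events.tsv")
    truth = pd.read_csv(ROOT / "cohort" / "true_events.tsv", sep="\t",
                        dtype={"chrom": str})

    intervals = ls.build_intervals(genome)
    stats = ls.score_intervals(events, intervals, N_TETRADS)
    hotspots = ls.detect_hotspots(stats, events=events, n_tetrads=N_TETRADS)
    gio.write_outputs(out, intervals=stats, hotspots=hotspots)

    print(f"{len(stats)} intervals (median size "
          f"{stats['size'].median() / 1e3:.1f} kb)")
    kinds = hotspots["kind"].value_counts().to_dict()
    print(f"{len(hotspots)} hotspots at the 2-fold threshold: {kinds}")
    hottest = hotspots.sort_values("tetrad_fraction", ascending=False).iloc[0]
    print(f"hottest span chr{hottest['chrom']}:{hottest['left']}-"
          f"{hottest['right']} with >=1 event in "
          f"{100 * hottest['tetrad_fraction']:.1f}% of tetrads")

    cen = ls.centromere_analysis(events, genome, stats, N_TETRADS)
    print(f"pericentromeric CO rate {cen['window_rate']:.2f}/Mb vs "
          f"genome {cen['genome_rate']:.2f}/Mb "
          f"(Mann-Whitney p {cen['mannwhitney_p']:.2g}); mean nearest CO "
          f"{cen['mean_nearest_co_distance'] / 1e3:.1f} kb from centromere")

    rows = []
    for kind in ("CO", "NCOGC"):
        counts = truth[truth["type"] == kind].groupby("chrom").size().to_dict()
        fit = ls.chromosome_event_regression(counts, genome, N_TETRADS)
        rows.append({"event": kind, **fit})
        print(f"{kind} rate law (true counts): "
              f"{fit['intercept']:.2f} + {fit['slope']:.2f}/Mb "
              f"(SE {fit['intercept_se']:.2f}, {fit['slope_se']:.2f})")
    pd.DataFrame(rows).to_csv(out / "rate_regression.tsv", sep="\t",
                              index=False)
    print(f"wrote {out}/")


if __name__ == "__main__":
    main()
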