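#!/usr/bin/env python
"""Call recombination events from the simulated cohort.

Reads the marker map and genotype matrix written by 01_simulate_cohort.py
through the standard readers, classifies crossovers and gene conversions
per tetrad, and reports cohort totals with the coverage adjustment the
study's arithmetic uses (detected count x (1 + uncovered fraction)).
"""

from pathlib import Path

from tetrascope import event_calling as ec
from tetrascope import genome_io as gio
from tetrascope import landscape as ls

ROOT = Path(__file__).resolve().parents[1] / "results"
IN = ROOT / "cohort"
OUT = ROOT / "events"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = gio.read_marker_map(IN / "marker_map.tsv")
    gio.read_lsp_table(IN / "lsps.tsv", genome)
    tetrads = gio.read_genotype_matrix(IN / "genotypes.tsv", genome)
    n = len(tetrads)

    events, summary = ec.call_all_events(tetrads, genome)
    gio.write_events(events, OUT / "events.tsv")

    uncovered = 1 - genome.covered_fraction()
    co_adj = ls.coverage_adjust(summary["n_co"], uncovered)
    gc_adj = ls.coverage_adjust(summary["n_ncogc"], uncovered)

    lines = [
        f"tetrads analysed: {n}",
        f"detected COs: {summary['n_co']}",
        f"detected GCs: {summary['n_gc']} "
        f"({summary['n_coagc']} COAGC + {summary['n_ncogc']} NCOGC)",
        f"uncovered genome fraction: {uncovered:.2f}",
        f"coverage-adjusted COs: {co_adj:.0f} "
        f"({co_adj / n:.1f} per meiosis)",
        f"coverage-adjusted NCOGCs: {gc_adj:.0f} "
        f"({gc_adj / n:.1f} per meiosis)",
        f"implied DSBs per meiosis: {(co_adj + gc_adj) / n:.0f}",
        f"eventless chromosome copies: "
        f"{len(summary['eventless_chromosomes'])} of "
        f"{n * len(genome.chromosomes)} "
        f"({100 * summary['eventless_fraction']:.2f}%)",
    ]
    text = "\n".join(lines)
    (OUT / "summary.txt").write_text(text + "\n")
    print(text)
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
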