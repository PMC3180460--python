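"""Genome-wide recombination landscape: coverage-adjusted totals,
per-chromosome rate regression, interval scoring, hotspot detection and the
centromere coldspot analysis.

Interval scores are observed/expected event counts where the expectation
assumes a homogeneous genome-wide rate (events/Mb/meiosis x interval size x
number of tetrads).  A hotspot is a maximal run of contiguous intervals each
scoring at least twice the expectation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GenomeMap

logger = logging.getLogger(__name__)

#: genome-wide homogeneous rates (events / Mb / meiosis) used for expectations
DEFAULT_RATES = {"CO": 6.5, "NCOGC": 2.6}


def coverage_adjust(count: float, uncovered_fraction: float,
                    mode: str = "multiply") -> float:
    """Adjust a detected event count for the unmarkered genome fraction.

    ``multiply`` (default) scales by (1 + uncovered_fraction) — the
    convention the totals in this package follow; ``renormalize`` divides by
    (1 - uncovered_fraction), the estimator one would use if events were
    uniform and detection proportional to coverage.
    """
    if not (0 <= uncovered_fraction < 1):
        raise ValueError("uncovered_fraction must lie in [0, 1)")
    if mode == "multiply":
        return count * (1.0 + uncovered_fraction)
    if mode == "renormalize":
        return count / (1.0 - uncovered_fraction)
    raise ValueError(f"unknown mode {mode!r}")


def chromosome_event_regression(per_chrom_counts: dict[str, float],
                                genome: GenomeMap, n_tetrads: int
                                ) -> dict[str, float]:
    """OLS of per-meiosis event count against chromosome length (Mb).

    The rDNA span is excluded from chromosome length.  Returns intercept
    (events/chromosome), slope (events/Mb) and their standard errors.
    """
    x = np.array([c.effective_length / 1e6 for c in genome.chromosomes])
    y = np.array([per_chrom_counts.get(c.id, 0.0) / n_tetrads
                  for c in genome.chromosomes])
    if len(x) < 3:
        raise ValueError("regression needs at least 3 chromosomes")
    if np.ptp(x) == 0:
        raise ValueError("degenerate chromosome lengths")
    fit = stats.linregress(x, y)
    return {
        "intercept": float(fit.intercept),
        "slope": float(fit.slope),
        "intercept_se": float(fit.intercept_stderr),
        "slope_se": float(fit.stderr),
        "r": float(fit.rvalue),
    }


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------

def _merge_short(spans: list[tuple[int, int, int]], min_interval: int
                 ) -> list[tuple[int, int, int]]:
    """Greedy left-to-right merge of (left, right, n_markers) spans shorter
    than ``min_interval`` with their right neighbour; a trailing short span
    merges left."""
    out: list[tuple[int, int, int]] = []
    pending: tuple[int, int, int] | None = None
    for span in spans:
        if pending is not None:
            span = (pending[0], span[1], pending[2] + span[2] - 1)
            pending = None
        if span[1] - span[0] < min_interval:
            pending = span
        else:
            out.append(span)
    if pending is not None:
        if out:
            last = out.pop()
            out.append((last[0], pending[1], last[2] + pending[2] - 1))
        else:
            out.append(pending)
    return out


def build_intervals(genome: GenomeMap, min_interval: int = 2_000) -> pd.DataFrame:
    """Partition each chromosome's covered span into marker intervals of at
    least ``min_interval`` bp.

    Starts from adjacent-marker intervals and greedily merges each interval
    shorter than ``min_interval`` with its right neighbour (the last interval
    merges left), so single events in closely spaced markers cannot score as
    spurious hotspots.  Idempotent: re-applying the merge rule changes
    nothing.
    """
    rows = []
    for chrom in genome.chromosomes:
        pos = genome.chrom_positions(chrom.id)
        if len(pos) < 2:
            logger.info("chromosome %s has <2 markers; no intervals", chrom.id)
            continue
        spans = [(int(pos[i]), int(pos[i + 1]), 2) for i in range(len(pos) - 1)]
        for left, right, n in _merge_short(spans, min_interval):
            rows.append((chrom.id, left, right, right - left, n))
    return pd.DataFrame(rows,
                        columns=["chrom", "left", "right", "size", "n_markers"])


def assign_events_to_intervals(events: pd.DataFrame, intervals: pd.DataFrame
                               ) -> np.ndarray:
    """Interval row index for each event (by span midpoint), -1 if outside."""
    out = np.full(len(events), -1, dtype=int)
    if events.empty or intervals.empty:
        return out
    mid = (events["left"].to_numpy() + events["right"].to_numpy()) / 2.0
    for chrom, grp in intervals.groupby("chrom", sort=False):
        sel = np.flatnonzero(events["chrom"].to_numpy() == chrom)
        if not len(sel):
            continue
        lefts = grp["left"].to_numpy()
        rights = grp["right"].to_numpy()
        k = np.searchsorted(lefts, mid[sel], side="right") - 1
        ok = (k >= 0) & (mid[sel] <= rights[np.clip(k, 0, len(rights) - 1)])
        out[sel[ok]] = grp.index.to_numpy()[k[ok]]
    return out


def score_intervals(events: pd.DataFrame, intervals: pd.DataFrame,
                    n_tetrads: int, rates: dict[str, float] | None = None
                    ) -> pd.DataFrame:
    """Per-interval observed and expected counts and observed/expected scores.

    Events are assigned to the interval containing their span midpoint.  CO
    counts are multiplicity-weighted; NCOGC counts are event counts.
    ``rates`` defaults to the genome-wide homogeneous rates (6.5 CO and 2.6
    NCOGC per Mb per meiosis).
    """
    rates = rates or DEFAULT_RATES
    intervals = intervals.reset_index(drop=True)
    events = events.reset_index(drop=True)
    stats_tab = intervals.copy()
    idx = assign_events_to_intervals(events, intervals)
    co_counts = np.zeros(len(intervals))
    gc_counts = np.zeros(len(intervals))
    if len(events):
        w = np.where(events["type"] == "CO", events["multiplicity"], 1)
        for kind, counts in (("CO", co_counts), ("NCOGC", gc_counts)):
            mask = (events["type"].to_numpy() == kind) & (idx >= 0)
            np.add.at(counts, idx[mask], w[mask] if kind == "CO" else 1)
    mb = stats_tab["size"].to_numpy() / 1e6
    stats_tab["co_count"] = co_counts
    stats_tab["ncogc_count"] = gc_counts
    stats_tab["expected_co"] = rates["CO"] * mb * n_tetrads
    stats_tab["expected_ncogc"] = rates["NCOGC"] * mb * n_tetrads
    stats_tab["score_co"] = co_counts / stats_tab["expected_co"]
    stats_tab["score_ncogc"] = gc_counts / stats_tab["expected_ncogc"]
    return stats_tab


def rates_from_events(events: pd.DataFrame, genome: GenomeMap,
                      n_tetrads: int) -> dict[str, float]:
    """Genome-wide rates (events/Mb/meiosis) computed from a dataset over the
    covered span (first-to-last marker per chromosome)."""
    covered_mb = sum(
        (genome.chrom_positions(c.id)[-1] - genome.chrom_positions(c.id)[0])
        for c in genome.chromosomes
        if len(genome.chrom_positions(c.id)) >= 2) / 1e6
    co = events.loc[events["type"] == "CO", "multiplicity"].sum()
    gc = (events["type"] == "NCOGC").sum()
    return {"CO": float(co / covered_mb / n_tetrads),
            "NCOGC": float(gc / covered_mb / n_tetrads)}


# ---------------------------------------------------------------------------
# hotspots
# ---------------------------------------------------------------------------

def detect_hotspots(stats_tab: pd.DataFrame, threshold: float = 2.0,
                    events: pd.DataFrame | None = None,
                    n_tetrads: int | None = None) -> pd.DataFrame:
    """Detect hotspots per event kind from scored intervals.

    Intervals with score >= ``threshold`` are flagged; maximal runs of
    contiguous flagged intervals (adjacent rows sharing a boundary on one
    chromosome) merge into one hotspot whose midpoint is the centre of the
    merged span.  A hotspot whose span overlaps a hotspot of the other kind
    is labelled ``both``.  When ``events`` and ``n_tetrads`` are given, the
    fraction of tetrads with at least one event of the kind inside the
    merged span is reported.
    """
    rows = []
    for kind, score_col in (("CO", "score_co"), ("NCOGC", "score_ncogc")):
        flagged = stats_tab[stats_tab[score_col] >= threshold]
        for chrom, grp in flagged.groupby("chrom", sort=False):
            grp = grp.sort_values("left")
            start = None
            prev_right = None
            for r in grp.itertuples(index=False):
                if start is None:
                    start, prev_right = r.left, r.right
                elif r.left == prev_right:
                    prev_right = r.right
                else:
                    rows.append((kind, chrom, start, prev_right))
                    start, prev_right = r.left, r.right
            if start is not None:
                rows.append((kind, chrom, start, prev_right))
    hot = pd.DataFrame(rows, columns=["scored_by", "chrom", "left", "right"])
    hot["midpoint"] = (hot["left"] + hot["right"]) / 2.0

    # overlap between kinds -> both (sorted sweep per chromosome); the
    # scored_by column keeps the origin so hotspots stay disjoint per kind
    lab = hot["scored_by"].to_numpy().copy()
    for chrom, grp in hot.groupby("chrom", sort=False):
        co = grp[grp["scored_by"] == "CO"].sort_values("left")
        gc = grp[grp["scored_by"] == "NCOGC"].sort_values("left")
        for side_a, side_b in ((co, gc), (gc, co)):
            if side_a.empty or side_b.empty:
                continue
            starts = side_b["left"].to_numpy()
            ends = side_b["right"].to_numpy()
            order = np.argsort(starts)
            starts, ends = starts[order], ends[order]
            for i, r in zip(side_a.index, side_a.itertuples(index=False)):
                k = np.searchsorted(starts, r.right, side="right")
                if k > 0 and (ends[:k] >= r.left).any():
                    lab[i] = "both"
    hot["kind"] = lab

    if events is not None and n_tetrads:
        fracs = []
        for r in hot.itertuples(index=False):
            kinds = ("CO", "NCOGC") if r.kind == "both" else (r.kind,)
            mid = (events["left"] + events["right"]) / 2.0
            sel = (events["chrom"] == r.chrom) & events["type"].isin(kinds) \
                & (mid >= r.left) & (mid <= r.right)
            fracs.append(events.loc[sel, "tetrad"].nunique() / n_tetrads)
        hot["tetrad_fraction"] = fracs
    hot = hot.sort_values(["chrom", "left", "kind"]).reset_index(drop=True)
    hot.insert(0, "id", [f"hs{i + 1}" for i in range(len(hot))])
    return hot


# ---------------------------------------------------------------------------
# centromeres
# ---------------------------------------------------------------------------

def centromere_analysis(events: pd.DataFrame, genome: GenomeMap,
                        stats_tab: pd.DataFrame, n_tetrads: int,
                        window: float = 22_900, mode: str = "centered"
                        ) -> dict[str, float]:
    """Crossover suppression around centromeres.

    The pericentromeric window has total width ``window`` (centred on the
    centromere; ``one_sided`` uses [centromere, centromere + window]).
    Reports the CO rate inside the windows vs the genome-wide rate, a
    Mann-Whitney U test comparing per-interval CO rates inside vs outside
    (an interval is inside when its midpoint is), and the mean over
    chromosomes of the nearest detected CO's distance to the centromere.
    """
    spans = {}
    for c in genome.chromosomes:
        if mode == "centered":
            spans[c.id] = (c.centromere_pos - window / 2,
                           c.centromere_pos + window / 2)
        elif mode == "one_sided":
            spans[c.id] = (c.centromere_pos, c.centromere_pos + window)
        else:
            raise ValueError(f"unknown mode {mode!r}")

    cos = events[events["type"] == "CO"]
    if cos.empty:
        return {"window_rate": 0.0, "genome_rate": 0.0,
                "mannwhitney_p": np.nan, "mean_nearest_co_distance": np.nan}
    mid = (cos["left"].to_numpy() + cos["right"].to_numpy()) / 2.0
    w = cos["multiplicity"].to_numpy()

    in_window = np.zeros(len(cos), dtype=bool)
    for cid, (lo, hi) in spans.items():
        in_window |= (cos["chrom"].to_numpy() == cid) & (mid >= lo) & (mid <= hi)
    window_mb = window * len(genome.chromosomes) / 1e6
    genome_mb = sum(c.effective_length for c in genome.chromosomes) / 1e6
    window_rate = w[in_window].sum() / window_mb / n_tetrads
    genome_rate = w.sum() / genome_mb / n_tetrads

    imid = (stats_tab["left"].to_numpy() + stats_tab["right"].to_numpy()) / 2.0
    inside = np.zeros(len(stats_tab), dtype=bool)
    for cid, (lo, hi) in spans.items():
        inside |= (stats_tab["chrom"].to_numpy() == cid) & (imid >= lo) & (imid <= hi)
    irates = stats_tab["co_count"].to_numpy() / stats_tab["size"].to_numpy()
    if inside.any() and (~inside).any():
        p = float(stats.mannwhitneyu(irates[inside], irates[~inside],
                                     alternative="two-sided").pvalue)
    else:
        p = np.nan

    dists = []
    for c in genome.chromosomes:
        sel = cos["chrom"].to_numpy() == c.id
        if sel.any():
            dists.append(np.abs(mid[sel] - c.centromere_pos).min())
    return {
        "window_rate": float(window_rate),
        "genome_rate": float(genome_rate),
        "mannwhitney_p": p,
        "mean_nearest_co_distance": float(np.mean(dists)) if dists else np.nan,
    }
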