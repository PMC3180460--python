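"""Genetic-map distances, NCOGC frequency ranking and conversion parity.

Map distances use the Perkins tetrad formula,
cM = 100 x (3·NPD + TT/2) / n, on the PD/TT/NPD counts of a two-marker
interval.  Conversion parity at a polymorphism compares its 1:3 (S:N) and
3:1 NCOGC counts: an unbiased (parity) polymorphism converts toward either
allele equally often, and bias is tested with an exact binomial test against
0.5 (a pooled Fisher test against the remaining ranked polymorphisms is
reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .event_calling import CO_MULTIPLICITY, _n_set, _usable_mask
from .genome_io import CALL_MISSING, CALL_N, GenomeMap, TetradGenotypes
from .interference import fisher_exact_2x2


@dataclass
class TetradTypeCounts:
    """PD/TT/NPD tetrad counts for one two-marker interval; incomplete
    tetrads are excluded, so PD + TT + NPD <= n."""

    pd: int
    tt: int
    npd: int
    n: int

    def __post_init__(self) -> None:
        if self.pd + self.tt + self.npd > self.n:
            raise ValueError("type counts exceed total tetrads")


def perkins_cm(counts: TetradTypeCounts) -> float:
    """Perkins map distance: cM = 100 x (3·NPD + TT/2) / n."""
    if counts.n <= 0:
        raise ValueError("n must be > 0")
    return 100.0 * (3.0 * counts.npd + counts.tt / 2.0) / counts.n


def kb_per_cm(span_bp: float, cm: float, n_tetrads: int | None = None
              ) -> tuple[float, bool]:
    """Physical-to-genetic distance ratio for an interval.

    Returns (value, is_lower_bound).  When cM is 0, the interval showed no
    crossover; the value returned is the lower bound implied by the one-event
    resolution limit (one tetratype among ``n_tetrads``) and the bound flag
    is set.
    """
    if cm < 0:
        raise ValueError("cM must be >= 0")
    if cm == 0:
        if not n_tetrads:
            return float("inf"), True
        resolution_cm = 100.0 * 0.5 / n_tetrads
        return (span_bp / 1_000.0) / resolution_cm, True
    return (span_bp / 1_000.0) / cm, False


def interval_type_counts(tetrads: list[TetradGenotypes], left: int, right: int
                         ) -> TetradTypeCounts:
    """PD/TT/NPD counts over a cohort for the interval between marker indices
    ``left`` and ``right``; tetrads where either marker is not a complete
    2:2 are excluded."""
    pd_n = tt = npd = 0
    for t in tetrads:
        ok = True
        sets = []
        for j in (left, right):
            col = t.spores[:, j]
            if (col == CALL_MISSING).any() or int((col == CALL_N).sum()) != 2:
                ok = False
                break
            sets.append(_n_set(col))
        if not ok:
            continue
        shared = len(sets[0] & sets[1])
        if shared == 2:
            pd_n += 1
        elif shared == 1:
            tt += 1
        else:
            npd += 1
    return TetradTypeCounts(pd_n, tt, npd, len(tetrads))


def parity_test(n_13: int, n_31: int,
                pooled: tuple[int, int] | None = None) -> dict[str, float]:
    """Test a polymorphism's conversion-direction bias.

    Primary statistic: exact two-sided binomial test of ``n_13`` successes in
    ``n_13 + n_31`` trials against 0.5.  When ``pooled`` (the 1:3/3:1 totals
    of the comparison set, excluding this marker) is given, a two-sided
    Fisher exact p of [n_13, n_31] against the pooled counts is reported as
    ``p_fisher``.  Both counts zero -> p = 1.
    """
    if n_13 < 0 or n_31 < 0:
        raise ValueError("counts must be >= 0")
    total = n_13 + n_31
    p_binom = 1.0 if total == 0 else \
        float(stats.binomtest(n_13, total, 0.5).pvalue)
    out = {"p_binomial": p_binom}
    if pooled is not None:
        out["p_fisher"] = fisher_exact_2x2([[n_13, n_31],
                                            [pooled[0], pooled[1]]])
    return out


def ncogc_marker_counts(events: pd.DataFrame, genome: GenomeMap
                        ) -> pd.DataFrame:
    """Per-marker NCOGC attribution: every marker covered by an NCOGC tract
    counts that event once, split by conversion direction (to_N = 1:3 S:N,
    to_S = 3:1)."""
    positions = genome.markers["pos"].to_numpy()
    chroms = genome.markers["chrom"].to_numpy()
    n13 = np.zeros(len(positions), dtype=int)
    n31 = np.zeros(len(positions), dtype=int)
    nco = events[events["type"] == "NCOGC"]
    for r in nco.itertuples(index=False):
        sl = genome.chrom_slice(r.chrom)
        lo = np.searchsorted(positions[sl], r.left) + sl.start
        hi = np.searchsorted(positions[sl], r.right, side="right") + sl.start
        if r.direction == "to_N":
            n13[lo:hi] += 1
        else:
            n31[lo:hi] += 1
    return pd.DataFrame({
        "chrom": chroms, "pos": positions,
        "marker_id": genome.markers["marker_id"].to_numpy(),
        "n_13": n13, "n_31": n31, "ncogc_total": n13 + n31,
    })


def rank_ncogc(events: pd.DataFrame, genome: GenomeMap,
               tetrads: list[TetradGenotypes], top_n: int = 50,
               alpha: float = 0.05) -> pd.DataFrame:
    """Rank polymorphisms by NCOGC frequency and build the parity report.

    For each of the ``top_n`` highest-NCOGC markers (ties broken by (chrom,
    pos)): the nearest flanking markers that never converted, the CO count
    between those flanks over all tetrads (TT + 2·NPD), the Perkins map
    distance of the flanking interval and its kb/cM, the NCOGC/CO ratio
    (infinite ratios are reported as a ``>total`` bound), the exact binomial
    parity p-value and the pooled-Fisher alternative, and the distance to
    the nearest LSP on the marker's chromosome (NaN when it has none).
    """
    counts = ncogc_marker_counts(events, genome)
    chrom_order = {c.id: k for k, c in enumerate(genome.chromosomes)}
    order = counts.assign(_chrom_rank=counts["chrom"].map(chrom_order)) \
        .sort_values(["ncogc_total", "_chrom_rank", "pos"],
                     ascending=[False, True, True], kind="mergesort") \
        .drop(columns="_chrom_rank")
    top = order.head(top_n)
    positions = genome.markers["pos"].to_numpy()
    converted = counts["ncogc_total"].to_numpy() > 0
    pool13 = int(top["n_13"].sum())
    pool31 = int(top["n_31"].sum())

    lsp_by_chrom: dict[str, list] = {}
    for l in genome.lsps:
        lsp_by_chrom.setdefault(l.chrom, []).append(l)

    rows = []
    for rank, (i, rec) in enumerate(top.iterrows(), start=1):
        sl = genome.chrom_slice(rec["chrom"])
        li = None
        for j in range(i - 1, sl.start - 1, -1):
            if not converted[j]:
                li = j
                break
        ri = None
        for j in range(i + 1, sl.stop):
            if not converted[j]:
                ri = j
                break
        if li is None or ri is None:          # no clean flank: use chrom ends
            li = sl.start if li is None else li
            ri = sl.stop - 1 if ri is None else ri
        tc = interval_type_counts(tetrads, li, ri)
        co_total = tc.tt * CO_MULTIPLICITY["TT"] + tc.npd * CO_MULTIPLICITY["NPD"]
        cm = perkins_cm(tc)
        span = float(positions[ri] - positions[li])
        kbcm, kb_bound = kb_per_cm(span, cm, len(tetrads))
        total = int(rec["ncogc_total"])
        if co_total:
            ratio, ratio_bound = total / co_total, False
        else:
            ratio, ratio_bound = float(total), True
        ptest = parity_test(int(rec["n_13"]), int(rec["n_31"]),
                            pooled=(pool13 - int(rec["n_13"]),
                                    pool31 - int(rec["n_31"])))
        lsps = lsp_by_chrom.get(rec["chrom"], [])
        lsp_dist = min((_span_distance(rec["pos"], l.start, l.end)
                        for l in lsps), default=np.nan)
        rows.append({
            "rank": rank, "chrom": rec["chrom"], "pos": int(rec["pos"]),
            "marker_id": rec["marker_id"], "lsp_distance": lsp_dist,
            "ncogc_total": total, "n_13": int(rec["n_13"]),
            "n_31": int(rec["n_31"]),
            "flank_left": int(positions[li]), "flank_right": int(positions[ri]),
            "co_total": int(co_total),
            "ratio_ncogc_co": ratio, "ratio_is_bound": ratio_bound,
            "kb_per_cm": kbcm, "kb_per_cm_is_bound": kb_bound,
            "p_parity": ptest["p_binomial"],
            "p_parity_fisher": ptest.get("p_fisher", np.nan),
            "nonparity": ptest["p_binomial"] < alpha,
        })
    return pd.DataFrame(rows)


def _span_distance(pos: float, start: float, end: float) -> float:
    """Distance from a point to a span (0 if inside)."""
    if pos < start:
        return start - pos
    if pos > end:
        return pos - end
    return 0.0


def format_ratio(value: float, is_bound: bool, decimals: int = 1) -> str:
    """Render a ratio for reports: plain number, or ``>x`` for a zero
    denominator bound."""
    return f">{value:.{decimals}f}" if is_bound else f"{value:.{decimals}f}"
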