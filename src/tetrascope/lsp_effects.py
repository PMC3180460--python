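"""Effects of large sequence polymorphisms (LSPs) on recombination.

Heterozygous LSPs are spans where the two homologs cannot pair; the analyses
here quantify their local effect on recombination: event rates in regions
adjacent to non-sub-telomeric LSPs, hotspot spacing across LSPs,
sub-telomeric window comparisons, the association between conversion
non-parity and LSP proximity, and rank correlations between distances and
conversion statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import LSP, SUBTELOMERE_BP, GenomeMap
from .interference import fisher_exact_2x2


def merge_spans(spans: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of closed intervals (overlaps merged, no double counting)."""
    if not spans:
        return []
    spans = sorted(spans)
    out = [list(spans[0])]
    for s, e in spans[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _events_in_spans(events: pd.DataFrame, chrom: str,
                     spans: list[tuple[float, float]], kind: str) -> float:
    sel = events[(events["chrom"] == chrom) & (events["type"] == kind)]
    if sel.empty:
        return 0.0
    mid = (sel["left"].to_numpy() + sel["right"].to_numpy()) / 2.0
    w = sel["multiplicity"].to_numpy() if kind == "CO" else np.ones(len(sel))
    inside = np.zeros(len(sel), dtype=bool)
    for s, e in spans:
        inside |= (mid >= s) & (mid <= e)
    return float(w[inside].sum())


def lsp_adjacent_rates(events: pd.DataFrame, genome: GenomeMap,
                       n_tetrads: int, flank: float = 10_000,
                       genome_rates: dict[str, float] | None = None
                       ) -> dict[str, float]:
    """CO and NCOGC rates in regions adjacent to heterozygous
    non-sub-telomeric LSPs, and the percent reduction vs genome-wide rates.

    The region for each LSP is its span extended by ``flank`` on both sides;
    regions are pooled with overlaps merged.  Rates are events (midpoint
    inside) per pooled Mb per meiosis.  ``genome_rates`` defaults to the
    homogeneous 6.5 CO and 2.6 NCOGC per Mb per meiosis.
    """
    lsps = genome.heterozygous_nonsub_lsps()
    if not lsps:
        return {"co_rate": np.nan, "ncogc_rate": np.nan,
                "co_reduction_pct": np.nan, "ncogc_reduction_pct": np.nan,
                "pooled_mb": 0.0, "n_lsps": 0}
    genome_rates = genome_rates or {"CO": 6.5, "NCOGC": 2.6}
    pooled_mb = 0.0
    co = gc = 0.0
    by_chrom: dict[str, list] = {}
    for l in lsps:
        by_chrom.setdefault(l.chrom, []).append(l)
    for cid, group in by_chrom.items():
        length = genome.chromosome(cid).length
        spans = merge_spans([(max(1, l.start - flank), min(length, l.end + flank))
                             for l in group])
        pooled_mb += sum(e - s + 1 for s, e in spans) / 1e6
        co += _events_in_spans(events, cid, spans, "CO")
        gc += _events_in_spans(events, cid, spans, "NCOGC")
    co_rate = co / pooled_mb / n_tetrads
    gc_rate = gc / pooled_mb / n_tetrads
    return {
        "co_rate": co_rate,
        "ncogc_rate": gc_rate,
        "co_reduction_pct": 100.0 * (1 - co_rate / genome_rates["CO"]),
        "ncogc_reduction_pct": 100.0 * (1 - gc_rate / genome_rates["NCOGC"]),
        "pooled_mb": pooled_mb,
        "n_lsps": len(lsps),
    }


def hotspot_spacing_vs_lsp(hotspots: pd.DataFrame, genome: GenomeMap
                           ) -> dict[str, float]:
    """Consecutive-hotspot spacing split by whether a heterozygous
    non-sub-telomeric LSP lies strictly between the two midpoints.

    Gaps are midpoint-to-midpoint distances between consecutive hotspots on
    the same chromosome; a gap is in the LSP class when at least one
    qualifying LSP's whole span falls strictly inside the gap.  Classes are
    compared with a two-sided Mann-Whitney U test.
    """
    lsps = genome.heterozygous_nonsub_lsps()
    with_lsp, without = [], []
    for chrom, grp in hotspots.groupby("chrom", sort=False):
        mids = np.sort(grp["midpoint"].to_numpy())
        for a, b in zip(mids[:-1], mids[1:]):
            has = any(l.chrom == chrom and l.start > a and l.end < b
                      for l in lsps)
            (with_lsp if has else without).append(b - a)
    out = {
        "mean_gap_lsp_between": float(np.mean(with_lsp)) if with_lsp else np.nan,
        "mean_gap_baseline": float(np.mean(without)) if without else np.nan,
        "n_lsp_between": len(with_lsp),
        "n_baseline": len(without),
        "mannwhitney_p": np.nan,
    }
    if with_lsp and without:
        out["mannwhitney_p"] = float(stats.mannwhitneyu(
            with_lsp, without, alternative="two-sided").pvalue)
    return out


def _end_windows(genome: GenomeMap, window: float
                 ) -> list[tuple[str, str, float, float]]:
    """(chrom, end label, lo, hi) for both ends of every chromosome."""
    out = []
    for c in genome.chromosomes:
        out.append((c.id, "L", 1.0, float(window)))
        out.append((c.id, "R", float(c.length - window + 1), float(c.length)))
    return out


def subtelomere_analysis(events: pd.DataFrame, hotspots: pd.DataFrame,
                         genome: GenomeMap, n_tetrads: int,
                         window: float = 30_000) -> dict:
    """Recombination in sub-telomeric windows, split by LSP heterozygosity.

    Each chromosome end covered by markers (>=1 marker within ``window`` of
    the end) contributes one observation: CO and NCOGC rates inside the
    window, classified by whether a heterozygous sub-telomeric LSP sits at
    that end (within SUBTELOMERE_BP).  Classes are compared per rate with a
    two-sided Mann-Whitney U test; the distance from the chromosome end to
    the first hotspot midpoint is compared the same way.
    """
    sub_lsps = [l for l in genome.lsps if l.zygosity == "heterozygous"
                and l.positional_class == "sub_telomeric"]
    rows = []
    for cid, end, lo, hi in _end_windows(genome, window):
        pos = genome.chrom_positions(cid)
        if len(pos) == 0 or not ((pos >= lo) & (pos <= hi)).any():
            continue                       # end without marker coverage
        length = genome.chromosome(cid).length
        has_lsp = any(
            l.chrom == cid and (
                (end == "L" and l.end <= SUBTELOMERE_BP)
                or (end == "R" and l.start > length - SUBTELOMERE_BP))
            for l in sub_lsps)
        mb = window / 1e6
        co = _events_in_spans(events, cid, [(lo, hi)], "CO") / mb / n_tetrads
        gc = _events_in_spans(events, cid, [(lo, hi)], "NCOGC") / mb / n_tetrads
        hmids = hotspots.loc[hotspots["chrom"] == cid, "midpoint"].to_numpy()
        if len(hmids):
            dist = float(np.min(hmids - 1)) if end == "L" \
                else float(np.min(length - hmids))
        else:
            dist = np.nan
        rows.append({"chrom": cid, "end": end, "lsp_class": has_lsp,
                     "co_rate": co, "ncogc_rate": gc,
                     "first_hotspot_distance": dist})
    ends = pd.DataFrame(rows)
    out = {"ends": ends}
    for col in ("co_rate", "ncogc_rate", "first_hotspot_distance"):
        a = ends.loc[ends["lsp_class"], col].dropna()
        b = ends.loc[~ends["lsp_class"], col].dropna()
        out[f"mean_{col}_lsp"] = float(a.mean()) if len(a) else np.nan
        out[f"mean_{col}_free"] = float(b.mean()) if len(b) else np.nan
        out[f"p_{col}"] = float(stats.mannwhitneyu(
            a, b, alternative="two-sided").pvalue) if len(a) and len(b) else np.nan
    return out


def nonparity_lsp_association(parity: pd.DataFrame,
                              distance_threshold: float = 17_000) -> float:
    """Fisher exact association between conversion non-parity and LSP
    proximity: {non-parity, parity} x {within threshold, beyond}.

    ``parity`` needs boolean ``nonparity`` and numeric ``lsp_distance``
    columns; rows with no LSP on the chromosome (NaN distance) are excluded.
    Returns NaN when every row is excluded.
    """
    rec = parity.dropna(subset=["lsp_distance"])
    if rec.empty:
        return float("nan")
    within = rec["lsp_distance"] <= distance_threshold
    table = [[int((rec["nonparity"] & within).sum()),
              int((rec["nonparity"] & ~within).sum())],
             [int((~rec["nonparity"] & within).sum()),
              int((~rec["nonparity"] & ~within).sum())]]
    return fisher_exact_2x2(table)


def distance_correlations(parity: pd.DataFrame, genome: GenomeMap
                          ) -> pd.DataFrame:
    """Spearman rank correlations of LSP and telomere distances against
    NCOGC/CO and kb/cM.

    Rows with a bound ratio (no CO between the flanks) or a bound kb/cM are
    excluded from the corresponding pair, as are rows with no LSP on the
    chromosome for the LSP pairs.  Pairs with n < 3 report NaN.
    """
    rec = parity.copy()
    lengths = {c.id: c.length for c in genome.chromosomes}
    rec["telomere_distance"] = [
        min(p, lengths[c] - p + 1) for c, p in zip(rec["chrom"], rec["pos"])]
    pairs = [
        ("lsp_distance", "ratio_ncogc_co", "ratio_is_bound"),
        ("lsp_distance", "kb_per_cm", "kb_per_cm_is_bound"),
        ("telomere_distance", "ratio_ncogc_co", "ratio_is_bound"),
        ("telomere_distance", "kb_per_cm", "kb_per_cm_is_bound"),
    ]
    rows = []
    for xcol, ycol, bound_col in pairs:
        sel = rec.dropna(subset=[xcol])
        sel = sel[~sel[bound_col]]
        if len(sel) < 3:
            rows.append((xcol, ycol, len(sel), np.nan, np.nan))
            continue
        rho, p = stats.spearmanr(sel[xcol], sel[ycol])
        rows.append((xcol, ycol, len(sel), float(rho), float(p)))
    return pd.DataFrame(rows, columns=["distance", "statistic", "n", "rho", "p"])
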