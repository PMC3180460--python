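"""Crossover-interference scan.

Chromosomes are cut into ~50-kb bins; for each ordered pair of adjacent bins
a 2x2 table counts tetrads with/without a crossover in the reference bin
against with/without one in the adjacent bin.  Interference shows up as a
negative association (tetrads with a CO in one bin are depleted for COs next
door), tested by a two-sided Fisher exact test with a per-chromosome
Bonferroni threshold, plus a pooled whole-chromosome test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import Chromosome

SCAN_COLUMNS = ["chrom", "ref_left", "ref_right", "adj_left", "adj_right",
                "both", "ref_only", "adj_only", "neither",
                "odds_ratio", "p", "threshold", "significant_interference"]


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact probability of a 2x2 contingency table.

    Exact minimum-likelihood construction: with margins fixed, the first cell
    is hypergeometric; the p-value sums the probabilities of all tables no
    more probable than the observed one.  A table with an all-zero margin has
    p = 1 by convention.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("cells must be non-negative integers")
        t = t.astype(int)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum()))


def bin_chromosome(chrom: Chromosome | int, width: int = 50_000
                   ) -> list[tuple[int, int]]:
    """Consecutive fixed-width bins from position 1 (1-based inclusive).

    The trailing partial bin is merged into the previous one when shorter
    than width/2, so all bins are between width/2 and 1.5x width; a
    chromosome shorter than the width is a single bin.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    length = chrom.length if isinstance(chrom, Chromosome) else int(chrom)
    n_full = length // width
    if n_full == 0:
        return [(1, length)]
    bins = [(i * width + 1, (i + 1) * width) for i in range(n_full)]
    remainder = length - n_full * width
    if remainder:
        if remainder >= width / 2:
            bins.append((n_full * width + 1, length))
        else:
            bins[-1] = (bins[-1][0], length)
    return bins


def _tetrad_bin_presence(events: pd.DataFrame, chrom_id: str,
                         bins: list[tuple[int, int]], tetrad_ids: list[str]
                         ) -> np.ndarray:
    """Boolean (n_tetrads, n_bins): tetrad has >=1 CO with midpoint in bin."""
    presence = np.zeros((len(tetrad_ids), len(bins)), dtype=bool)
    cos = events[(events["type"] == "CO") & (events["chrom"] == str(chrom_id))]
    if cos.empty:
        return presence
    tindex = {t: i for i, t in enumerate(tetrad_ids)}
    mid = (cos["left"].to_numpy() + cos["right"].to_numpy()) / 2.0
    lefts = np.array([b[0] for b in bins])
    k = np.searchsorted(lefts, mid, side="right") - 1
    k = np.clip(k, 0, len(bins) - 1)
    for tid, bi in zip(cos["tetrad"], k):
        if tid in tindex:
            presence[tindex[tid], bi] = True
    return presence


def interference_scan(events: pd.DataFrame, chrom: Chromosome,
                      tetrad_ids: list[str], width: int = 50_000,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Adjacent-bin Fisher scan for one chromosome.

    For each ordered adjacent bin pair, builds the 2x2 tetrad table, computes
    the two-sided Fisher p, and flags interference when p falls below the
    per-chromosome Bonferroni threshold (alpha / number of pairs tested) AND
    the association is negative (odds ratio < 1).
    """
    bins = bin_chromosome(chrom, width)
    presence = _tetrad_bin_presence(events, chrom.id, bins, tetrad_ids)
    n_pairs = max(len(bins) - 1, 0)
    threshold = alpha / n_pairs if n_pairs else np.nan
    rows = []
    for i in range(n_pairs):
        ref, adj = presence[:, i], presence[:, i + 1]
        both = int((ref & adj).sum())
        ref_only = int((ref & ~adj).sum())
        adj_only = int((~ref & adj).sum())
        neither = int((~ref & ~adj).sum())
        p = fisher_exact_2x2([[both, ref_only], [adj_only, neither]])
        odds = (both * neither) / (ref_only * adj_only) \
            if ref_only * adj_only else np.inf
        sig = bool(p < threshold and both * neither < ref_only * adj_only)
        rows.append((chrom.id, bins[i][0], bins[i][1],
                     bins[i + 1][0], bins[i + 1][1],
                     both, ref_only, adj_only, neither, odds, p, threshold, sig))
    return pd.DataFrame(rows, columns=SCAN_COLUMNS)


def chromosome_interference(events: pd.DataFrame, chrom: Chromosome,
                            tetrad_ids: list[str], width: int = 50_000
                            ) -> float:
    """Pooled whole-chromosome interference test: adjacent-pair 2x2 tables
    are summed cell-wise and one two-sided Fisher exact p is computed.
    Returns NaN for a single-bin chromosome."""
    scan = interference_scan(events, chrom, tetrad_ids, width)
    if scan.empty:
        return float("nan")
    pooled = [[int(scan["both"].sum()), int(scan["ref_only"].sum())],
              [int(scan["adj_only"].sum()), int(scan["neither"].sum())]]
    return fisher_exact_2x2(pooled)
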