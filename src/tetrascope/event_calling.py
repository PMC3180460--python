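"""Recombination-event calling from tetrad genotypes.

The core classification: between two adjacent markers that both segregate 2:2
in a tetrad, the pair of N-carrying spore sets defines the two-marker tetrad
class — parental ditype (PD, identical sets), tetratype (TT, sets sharing one
spore) or non-parental ditype (NPD, disjoint sets).  TT implies at least one
crossover in the interval and NPD at least two (the minimum-crossover
interpretation: two-strand doubles collapse to PD and three-strand doubles to
TT, so the detected count is a lower bound).  Markers segregating 3:1 or 1:3
are gene conversions; maximal runs of adjacent markers with the identical
converted spore vector merge into one tract (a co-conversion).  A conversion
whose nearest usable 2:2 flanking markers underwent a crossover is
crossover-associated (COAGC); otherwise it is a non-crossover gene conversion
(NCOGC).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genome_io import CALL_MISSING, CALL_N, CALL_S, GenomeMap, TetradGenotypes

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["tetrad", "chrom", "type", "left", "right",
                 "multiplicity", "direction", "flagged"]


def _n_set(col: np.ndarray) -> frozenset:
    return frozenset(np.flatnonzero(col == CALL_N).tolist())


def _usable_mask(spores: np.ndarray) -> np.ndarray:
    """Markers that are complete 2:2 in this tetrad (usable for CO calling)."""
    complete = (spores != CALL_MISSING).all(axis=0)
    two_two = (spores == CALL_N).sum(axis=0) == 2
    return complete & two_two


def interval_tetrad_type(t: TetradGenotypes, left: int, right: int) -> str:
    """Two-marker tetrad class between marker indices ``left`` and ``right``.

    Both markers must be complete 2:2 in this tetrad.  |A ∩ B| of the
    N-carrying spore sets: 2 -> PD, 1 -> TT, 0 -> NPD.
    """
    for j in (left, right):
        col = t.spores[:, j]
        if (col == CALL_MISSING).any() or int((col == CALL_N).sum()) != 2:
            raise ValueError(f"marker {j} is not a complete 2:2 in {t.tetrad_id}")
    shared = len(_n_set(t.spores[:, left]) & _n_set(t.spores[:, right]))
    return {2: "PD", 1: "TT", 0: "NPD"}[shared]


#: crossovers implied by each two-marker tetrad class (minimum estimate)
CO_MULTIPLICITY = {"PD": 0, "TT": 1, "NPD": 2}


def call_crossovers(t: TetradGenotypes, genome: GenomeMap,
                    npd_multiplicity: int = 2) -> pd.DataFrame:
    """Call crossovers for one tetrad.

    For each pair of successive usable (complete 2:2) markers on a
    chromosome, a TT interval emits one CO event of multiplicity 1 and an NPD
    interval one event of multiplicity ``npd_multiplicity`` (default 2, the
    minimum-crossover arithmetic).  The detected CO count of the tetrad is
    the sum of multiplicities.
    """
    if t.spores.shape[1] != genome.n_markers:
        raise ValueError("tetrad genotypes not aligned to the marker table")
    usable = _usable_mask(t.spores)
    rows = []
    positions = genome.markers["pos"].to_numpy()
    for chrom in genome.chromosomes:
        sl = genome.chrom_slice(chrom.id)
        idx = np.flatnonzero(usable[sl]) + sl.start
        if len(idx) < 2:
            if sl.stop > sl.start:
                logger.debug("%s: <2 usable markers on chromosome %s",
                             t.tetrad_id, chrom.id)
            continue
        sets = [_n_set(t.spores[:, j]) for j in idx]
        for k in range(len(idx) - 1):
            shared = len(sets[k] & sets[k + 1])
            if shared == 2:
                continue
            mult = 1 if shared == 1 else npd_multiplicity
            rows.append((t.tetrad_id, chrom.id, "CO",
                         int(positions[idx[k]]), int(positions[idx[k + 1]]),
                         mult, "", False))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def call_gene_conversions(t: TetradGenotypes, genome: GenomeMap) -> pd.DataFrame:
    """Call gene-conversion tracts for one tetrad (type left as ``GC``;
    :func:`classify_gc` splits COAGC from NCOGC).

    Maximal runs of adjacent markers with the identical complete non-2:2
    spore vector merge into one tract.  Runs are broken by any other pattern,
    including missing calls (tracts do not merge across a missing marker).
    Anomalous 4:0/0:4 markers are excluded and logged.
    """
    if t.spores.shape[1] != genome.n_markers:
        raise ValueError("tetrad genotypes not aligned to the marker table")
    spores = t.spores
    complete = (spores != CALL_MISSING).all(axis=0)
    n_count = (spores == CALL_N).sum(axis=0)
    converted = complete & ((n_count == 1) | (n_count == 3))
    anomalous = complete & ((n_count == 0) | (n_count == 4))
    # a 2:2 everywhere dataset has no anomalies; only log when present
    positions = genome.markers["pos"].to_numpy()
    rows = []
    for chrom in genome.chromosomes:
        sl = genome.chrom_slice(chrom.id)
        if anomalous[sl].any():
            logger.info("%s: %d anomalous 4:0/0:4 markers on chromosome %s "
                        "excluded", t.tetrad_id, int(anomalous[sl].sum()), chrom.id)
        j = sl.start
        while j < sl.stop:
            if not converted[j]:
                j += 1
                continue
            k = j
            while (k + 1 < sl.stop and converted[k + 1]
                   and np.array_equal(spores[:, k + 1], spores[:, j])):
                k += 1
            direction = "to_N" if n_count[j] == 3 else "to_S"
            rows.append((t.tetrad_id, chrom.id, "GC",
                         int(positions[j]), int(positions[k]), 0, direction,
                         False))
            j = k + 1
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def classify_gc(t: TetradGenotypes, genome: GenomeMap,
                gc_events: pd.DataFrame) -> pd.DataFrame:
    """Split GC tracts into COAGC vs NCOGC by the flanking-interval class.

    The flanking interval is the nearest usable 2:2 marker on each side of
    the tract (skipping other converted or missing markers).  TT or NPD
    between the flanks -> COAGC; PD -> NCOGC.  A tract at a chromosome end
    with only one usable flank is NCOGC, flagged.  A tract with no usable
    flank on either side cannot be classified and is dropped (logged).
    """
    usable = _usable_mask(t.spores)
    positions = genome.markers["pos"].to_numpy()
    out = []
    for row in gc_events.itertuples(index=False):
        sl = genome.chrom_slice(row.chrom)
        li = int(np.searchsorted(positions[sl], row.left) + sl.start)
        ri = int(np.searchsorted(positions[sl], row.right, side="right") + sl.start)
        left_flank = None
        for j in range(li - 1, sl.start - 1, -1):
            if usable[j]:
                left_flank = j
                break
        right_flank = None
        for j in range(ri, sl.stop):
            if usable[j]:
                right_flank = j
                break
        rec = row._asdict()
        if left_flank is None and right_flank is None:
            logger.info("%s: conversion tract %s:%d-%d has no usable flank; "
                        "unclassified", t.tetrad_id, row.chrom, row.left, row.right)
            continue
        if left_flank is None or right_flank is None:
            rec["type"] = "NCOGC"
            rec["flagged"] = True
        else:
            itype = interval_tetrad_type(t, left_flank, right_flank)
            rec["type"] = "COAGC" if itype in ("TT", "NPD") else "NCOGC"
        out.append(rec)
    return pd.DataFrame(out, columns=EVENT_COLUMNS)


def call_tetrad_events(t: TetradGenotypes, genome: GenomeMap,
                       npd_multiplicity: int = 2) -> pd.DataFrame:
    """All events (CO + classified GC) for one tetrad."""
    cos = call_crossovers(t, genome, npd_multiplicity)
    gcs = classify_gc(t, genome, call_gene_conversions(t, genome))
    return pd.concat([cos, gcs], ignore_index=True)


def call_all_events(tetrads: list[TetradGenotypes], genome: GenomeMap,
                    npd_multiplicity: int = 2,
                    ) -> tuple[pd.DataFrame, dict]:
    """Call events for a cohort and summarise.

    Returns the concatenated event table and a summary dict with total CO
    (multiplicity-weighted), GC split into COAGC/NCOGC, per-tetrad and
    per-chromosome counts, and the list and fraction of (tetrad, chromosome)
    copies without any detected event.
    """
    frames = [call_tetrad_events(t, genome, npd_multiplicity) for t in tetrads]
    events = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=EVENT_COLUMNS)

    co_mask = events["type"] == "CO"
    n_co = int(events.loc[co_mask, "multiplicity"].sum())
    n_coagc = int((events["type"] == "COAGC").sum())
    n_ncogc = int((events["type"] == "NCOGC").sum())

    per_tetrad = (events.assign(
        weight=np.where(co_mask, events["multiplicity"], 1))
        .groupby(["tetrad", "type"])["weight"].sum().unstack(fill_value=0))
    per_chrom = (events.assign(
        weight=np.where(co_mask, events["multiplicity"], 1))
        .groupby(["chrom", "type"])["weight"].sum().unstack(fill_value=0))

    eventless = []
    seen = set(zip(events["tetrad"], events["chrom"]))
    for t in tetrads:
        for chrom in genome.chromosomes:
            if (t.tetrad_id, chrom.id) not in seen:
                eventless.append((t.tetrad_id, chrom.id))
    n_copies = len(tetrads) * len(genome.chromosomes)
    summary = {
        "n_tetrads": len(tetrads),
        "n_co": n_co,
        "n_gc": n_coagc + n_ncogc,
        "n_coagc": n_coagc,
        "n_ncogc": n_ncogc,
        "per_tetrad": per_tetrad,
        "per_chromosome": per_chrom,
        "eventless_chromosomes": eventless,
        "eventless_fraction": len(eventless) / n_copies if n_copies else np.nan,
    }
    return events, summary
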