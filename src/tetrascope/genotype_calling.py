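"""From replicate probe intensities to genotype calls, marker QC, per-tetrad
segregation patterns, and linkage-based phasing of the two parental homologs.

Genotyping arrays for a heterozygous diploid carry probes matching one allele
(here the S288C-like one), so segregants carrying that allele hybridise
strongly and the per-marker intensity distribution across segregants is
bimodal.  Calling is a deterministic 1-D two-cluster k-means per marker; QC
keeps markers whose clusters separate by a large fold ratio at a significant
two-sample t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import CALL_MISSING, CALL_N, CALL_S, GenomeMap, TetradGenotypes

logger = logging.getLogger(__name__)

SEGREGATION_PATTERNS = ("2:2", "3:1", "1:3", "4:0", "0:4", "INCOMPLETE")


# ---------------------------------------------------------------------------
# intensity normalisation and calling
# ---------------------------------------------------------------------------

def normalize_and_average(intensities: np.ndarray) -> np.ndarray:
    """Mean-normalise each segregant's array and average probe replicates.

    ``intensities`` has shape (n_segregants, n_markers, n_replicates).  Each
    segregant's values are divided by that segregant's grand mean (removing
    array-to-array scale effects), then replicates are averaged per marker.
    Non-positive intensities are treated as failed probes (NaN, logged).
    """
    x = np.asarray(intensities, dtype=float)
    if x.ndim == 2:                      # single replicate given as 2-D
        x = x[:, :, None]
    bad = x <= 0
    if bad.any():
        logger.info("rejected %d non-positive intensity cells", int(bad.sum()))
        x = np.where(bad, np.nan, x)
    grand = np.nanmean(x.reshape(x.shape[0], -1), axis=1)
    x = x / grand[:, None, None]
    return np.nanmean(x, axis=2)


def _kmeans_1d(values: np.ndarray, max_iter: int = 100) -> tuple[np.ndarray, float, float]:
    """Two-cluster 1-D k-means with deterministic initialisation at the 10th
    and 90th percentiles.  Returns (labels (1 = upper cluster), low mean,
    high mean).  Ties go to the lower cluster."""
    lo, hi = np.percentile(values, [10, 90])
    if lo == hi:
        return np.zeros(len(values), dtype=int), float(lo), float(hi)
    for _ in range(max_iter):
        d_lo = np.abs(values - lo)
        d_hi = np.abs(values - hi)
        labels = (d_hi < d_lo).astype(int)       # tie -> lower cluster
        if not labels.any() or labels.all():
            break
        new_lo = values[labels == 0].mean()
        new_hi = values[labels == 1].mean()
        if new_lo == lo and new_hi == hi:
            break
        lo, hi = new_lo, new_hi
    if lo > hi:                                  # keep orientation canonical
        lo, hi = hi, lo
        labels = 1 - labels
    return labels, float(lo), float(hi)


def call_genotypes(norm: np.ndarray, min_fold: float = 2.0,
                   alpha: float = 0.05, min_segregants: int = 8,
                   ) -> tuple[np.ndarray, pd.DataFrame]:
    """Call genotypes per marker from normalised mean intensities.

    ``norm`` has shape (n_segregants, n_markers).  Per marker the segregant
    means are split into two clusters; the higher-intensity cluster carries
    the probe allele and is called S (probes are S288C-like sequences).
    Hybridisation intensities are approximately log-normal and residual
    per-array scale effects are multiplicative, so clustering runs on log
    intensities.  QC records the cluster fold ratio (geometric-mean ratio)
    and a two-sample t-test p-value on the log values; markers failing
    ``fold >= min_fold`` and ``p < alpha`` are flagged (calls are still
    returned, downstream steps exclude flagged markers).

    Returns (calls int8 (n_segregants, n_markers), qc DataFrame).
    """
    norm = np.asarray(norm, dtype=float)
    n_seg, n_mark = norm.shape
    calls = np.full((n_seg, n_mark), CALL_MISSING, dtype=np.int8)
    qc_rows = []
    for j in range(n_mark):
        col = norm[:, j]
        ok = np.isfinite(col) & (col > 0)
        vals = col[ok]
        if len(vals) < min_segregants:
            qc_rows.append((j, np.nan, np.nan, False, "too_few_segregants"))
            continue
        if np.all(vals == vals[0]):
            qc_rows.append((j, 1.0, 1.0, False, "constant_intensity"))
            continue
        log_vals = np.log(vals)
        labels, lo, hi = _kmeans_1d(log_vals)
        upper = log_vals[labels == 1]
        lower = log_vals[labels == 0]
        if len(upper) == 0 or len(lower) == 0:
            qc_rows.append((j, np.nan, np.nan, False, "single_cluster"))
            continue
        fold = float(np.exp(hi - lo))
        if len(upper) >= 2 and len(lower) >= 2:
            p = stats.ttest_ind(upper, lower, equal_var=False).pvalue
        else:
            p = np.nan
        ok_idx = np.flatnonzero(ok)
        calls[ok_idx[labels == 1], j] = CALL_S
        calls[ok_idx[labels == 0], j] = CALL_N
        passed = bool(fold >= min_fold and np.isfinite(p) and p < alpha)
        note = "" if passed else "low_separation"
        qc_rows.append((j, float(fold), float(p) if np.isfinite(p) else np.nan,
                        passed, note))
    qc = pd.DataFrame(qc_rows,
                      columns=["marker_index", "fold", "p", "pass", "note"])
    return calls, qc


def select_markers(candidates: pd.DataFrame, target_spacing: float = 3_400,
                   min_fold: float = 2.0, alpha: float = 0.05) -> pd.DataFrame:
    """Greedy marker selection: keep candidates passing the fold and t-test
    thresholds, then thin to roughly ``target_spacing`` by keeping the
    highest-fold candidate per window (ties to the lower coordinate).

    ``candidates`` needs columns chrom, pos, fold, p.
    """
    if candidates.empty:
        return candidates.copy()
    keep = candidates[(candidates["p"] < alpha)
                      & (candidates["fold"] >= min_fold)].copy()
    if keep.empty:
        return keep
    keep["_window"] = (keep["pos"] // target_spacing).astype(int)
    keep = keep.sort_values(["chrom", "_window", "fold", "pos"],
                            ascending=[True, True, False, True])
    out = keep.groupby(["chrom", "_window"], sort=False).head(1)
    return out.drop(columns="_window").sort_values(["chrom", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# segregation patterns
# ---------------------------------------------------------------------------

def classify_segregation(spore_calls: np.ndarray) -> str:
    """Segregation pattern of one marker in one tetrad, counted S:N.

    Any missing call makes the pattern INCOMPLETE; 4:0 / 0:4 are anomalous
    (possible miscall or unexpected homozygosity) and are excluded from event
    calling by the callers.
    """
    c = np.asarray(spore_calls)
    if c.shape != (4,):
        raise ValueError("expected 4 spore calls")
    if (c == CALL_MISSING).any():
        return "INCOMPLETE"
    s = int((c == CALL_S).sum())
    return f"{s}:{4 - s}"


def segregation_matrix(t: TetradGenotypes) -> np.ndarray:
    """Vectorised S-count per marker: returns int array with values 0..4, or
    -1 where any spore call is missing."""
    missing = (t.spores == CALL_MISSING).any(axis=0)
    s_count = (t.spores == CALL_S).sum(axis=0)
    return np.where(missing, -1, s_count)


# ---------------------------------------------------------------------------
# phasing
# ---------------------------------------------------------------------------

@dataclass
class PhasedStructure:
    """Per-marker homolog assignment of the N allele, plus derived N-blocks.

    ``assignments`` has columns chrom, pos, marker_id, homolog (1/2),
    low_confidence; ``blocks`` has columns chrom, homolog, left, right
    (maximal runs of markers whose N allele sits on the same homolog).
    """

    assignments: pd.DataFrame
    blocks: pd.DataFrame


def _n_spore_sets(tetrads: list[TetradGenotypes], j: int) -> list[frozenset | None]:
    """N-carrying spore sets at marker j for each tetrad; None unless the
    marker is a complete 2:2 in that tetrad."""
    out = []
    for t in tetrads:
        col = t.spores[:, j]
        if (col == CALL_MISSING).any() or int((col == CALL_N).sum()) != 2:
            out.append(None)
        else:
            out.append(frozenset(np.flatnonzero(col == CALL_N).tolist()))
    return out


def phase_markers(tetrads: list[TetradGenotypes], genome: GenomeMap
                  ) -> PhasedStructure:
    """Phase markers into the two-homolog structure by linkage.

    Walks each chromosome left to right; the first marker's N allele is put
    on homolog 1.  Each subsequent marker is assigned in coupling or
    repulsion with the previous marker by majority vote over tetrads (equal
    N-spore sets vote coupling, complementary sets vote repulsion, other
    patterns abstain).  A 50/50 vote resolves to coupling and is flagged; a
    vote with no informative tetrads propagates the previous assignment and
    is flagged low-confidence.
    """
    if len(tetrads) < 2:
        raise ValueError("phasing needs at least 2 tetrads")
    rows = []
    for chrom in genome.chromosomes:
        sl = genome.chrom_slice(chrom.id)
        idx = range(sl.start, sl.stop)
        prev_sets: list[frozenset | None] | None = None
        prev_hom = 1
        for k, j in enumerate(idx):
            sets = _n_spore_sets(tetrads, j)
            flag = False
            if k == 0:
                hom = 1
            else:
                coupling = repulsion = 0
                for a, b in zip(prev_sets, sets):
                    if a is None or b is None:
                        continue
                    if a == b:
                        coupling += 1
                    elif a.isdisjoint(b):
                        repulsion += 1
                if coupling == 0 and repulsion == 0:
                    hom, flag = prev_hom, True
                elif coupling >= repulsion:
                    hom = prev_hom
                    flag = coupling == repulsion
                else:
                    hom = 3 - prev_hom
            rows.append((chrom.id, int(genome.markers["pos"].iloc[j]),
                         genome.markers["marker_id"].iloc[j], hom, flag))
            prev_sets, prev_hom = sets, hom
    assignments = pd.DataFrame(
        rows, columns=["chrom", "pos", "marker_id", "homolog", "low_confidence"])

    block_rows = []
    for chrom, grp in assignments.groupby("chrom", sort=False):
        grp = grp.reset_index(drop=True)
        start = 0
        for i in range(1, len(grp) + 1):
            if i == len(grp) or grp["homolog"].iloc[i] != grp["homolog"].iloc[start]:
                block_rows.append((chrom, int(grp["homolog"].iloc[start]),
                                   int(grp["pos"].iloc[start]),
                                   int(grp["pos"].iloc[i - 1])))
                start = i
    blocks = pd.DataFrame(block_rows, columns=["chrom", "homolog", "left", "right"])
    return PhasedStructure(assignments, blocks)
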