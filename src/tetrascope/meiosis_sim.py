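"""Synthetic meiosis generator with ground-truth event logs.

The generator emulates the statistical structure a tetrad-genotyping study
assumes: per-chromosome crossover (CO) and non-crossover gene-conversion
(NCOGC) counts that are Poisson with a mean linear in chromosome length
(an intercept per chromosome — the obligate event — plus a per-Mb slope),
crossover interference via a gamma-renewal spacing model, hotspot/coldspot
structure via a piecewise-constant intensity profile, gene-conversion tracts
with a direction-bias (parity) parameter, and two-cluster probe intensities
with a large fold separation.

Counts and positions are decoupled on purpose: suppression multipliers and
hotspots reshape *where* events fall on a chromosome, not how many occur, so
the per-chromosome count regression stays linear by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import (
    CALL_N,
    CALL_S,
    Chromosome,
    GenomeMap,
    LSP,
    TetradGenotypes,
    default_chromosomes,
)

TRUE_EVENT_COLUMNS = ["tetrad", "chrom", "type", "start", "end",
                      "chromatids", "direction", "n_markers"]

#: non-sister chromatid pairs (chromatids 0,1 copy homolog 1; 2,3 homolog 2)
_NON_SISTER_PAIRS = ((0, 2), (0, 3), (1, 2), (1, 3))


@dataclass
class SimulationConfig:
    """Generative parameters for a simulated tetrad cohort.

    Defaults are the study conditions of the EM93 cross this package models:
    0.6 obligate CO plus 6.5 COs/Mb and 0.04 obligate NCOGC plus 2.6
    NCOGCs/Mb per chromosome per meiosis; centromeric crossover suppression
    over a 22.9-kb window (multiplier ~0.1, the observed 0.69/6.5 coldspot
    ratio); recombination suppression over heterozygous non-sub-telomeric
    LSPs plus a 10-kb flank (multiplier 0.26, i.e. a ~74% reduction);
    unbiased conversion (parity 0.5) with 2-kb mean tracts.

    interference_shape is the gamma-renewal shape for inter-CO spacings:
    1 = no interference (Poisson positions), larger = more regular spacing.
    """

    co_intercept: float = 0.6          # events / chromosome
    co_slope: float = 6.5              # events / Mb
    ncogc_intercept: float = 0.04      # events / chromosome
    ncogc_slope: float = 2.6           # events / Mb
    interference_shape: float = 1.0    # gamma shape, >= 1
    obligate_co: bool = True
    hotspot_map: tuple = ()            # (chrom, start, end, multiplier)
    centromere_suppression: tuple[float, float] | None = (22_900, 0.1)
    lsp_suppression: tuple[float, float] | None = (10_000, 0.26)
    tract_mean: float = 2_000.0        # bp, mean conversion-tract length
    parity: float = 0.5                # P(conversion copies N onto an S chromatid)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interference_shape < 1:
            raise ValueError("interference_shape must be >= 1")
        if not (0.0 <= self.parity <= 1.0):
            raise ValueError("parity must lie in [0, 1]")
        if self.centromere_suppression is not None:
            if self.centromere_suppression[1] <= 0:
                raise ValueError("centromere multiplier must be > 0")
        if self.lsp_suppression is not None:
            if self.lsp_suppression[1] <= 0:
                raise ValueError("LSP multiplier must be > 0")
        for h in self.hotspot_map:
            if h[3] <= 0:
                raise ValueError("hotspot multipliers must be > 0")


# ---------------------------------------------------------------------------
# synthetic genome
# ---------------------------------------------------------------------------

def synthetic_genome(n_markers: int = 2_965, coverage: float = 0.77,
                     seed: int = 20_110_926,
                     chromosomes: list[Chromosome] | None = None) -> GenomeMap:
    """A marker map emulating the study design: ~2,965 markers at jittered
    ~3-kb spacing over a covered span totalling ``coverage`` of the genome.

    The unmarkered fraction mimics the real structure of a partially
    homozygous hybrid: small chromosomes are heterozygous (hence markered)
    end to end, while the uncovered share of the genome sits in terminal
    homozygous blocks on the right arms of the largest chromosomes.  Markers
    falling in the rDNA span are dropped.

    The default seed fixes one canonical synthetic map; the map is a study
    condition, not a tuning knob.
    """
    chroms = chromosomes or default_chromosomes()
    total = sum(c.length for c in chroms)
    uncovered = (1.0 - coverage) * total
    largest = sorted(chroms, key=lambda c: -c.length)[:8]
    big_total = sum(c.length for c in largest)
    trim = {c.id: uncovered * c.length / big_total for c in largest}

    rng = np.random.default_rng(seed)
    margin = 1_000
    rows = []
    k = 0
    for c in chroms:
        first = margin
        last = int(c.length - trim.get(c.id, 0.0)) - margin
        span = last - first + 1
        n_c = max(2, int(round(n_markers * span / (coverage * total))))
        base = np.linspace(first, last, n_c)
        step = (last - first) / max(n_c - 1, 1)
        jitter = rng.uniform(-0.3, 0.3, n_c) * step
        pos = np.clip(np.round(base + jitter), first, last).astype(np.int64)
        pos = np.unique(pos)
        if c.rdna_span is not None:
            s, e = c.rdna_span
            pos = pos[(pos < s) | (pos > e)]
        for p in pos:
            k += 1
            rows.append((c.id, int(p), f"m{k:04d}"))
    markers = pd.DataFrame(rows, columns=["chrom", "pos", "marker_id"])
    return GenomeMap(chroms, markers)


def synthetic_lsps(genome: GenomeMap, n_nonsub: int = 15, n_sub: int = 11,
                   span: int = 6_000, seed: int = 7) -> list[LSP]:
    """Place heterozygous LSPs emulating the study's annotation: ``n_nonsub``
    non-sub-telomeric LSPs on the larger chromosomes and ``n_sub``
    sub-telomeric ones (inside the terminal 20 kb).  Synthetic stand-in for a
    real LSP annotation table."""
    rng = np.random.default_rng(seed)
    chroms = sorted(genome.chromosomes, key=lambda c: -c.length)
    lsps = []
    for i in range(n_nonsub):
        c = chroms[i % len(chroms)]
        lo = 40_000
        hi = c.length - 40_000 - span
        start = int(rng.integers(lo, hi))
        lsp = LSP(f"lsp_ns{i + 1}", c.id, start, start + span - 1, "heterozygous")
        genome.add_lsp(lsp)
        lsps.append(lsp)
    for i in range(n_sub):
        c = chroms[i % len(chroms)]
        if rng.random() < 0.5:
            start = int(rng.integers(1, 20_000 - span))
        else:
            start = int(rng.integers(c.length - 20_000 + 1, c.length - span))
        lsp = LSP(f"lsp_st{i + 1}", c.id, start, start + span - 1, "heterozygous")
        genome.add_lsp(lsp)
        lsps.append(lsp)
    return lsps


# ---------------------------------------------------------------------------
# event-position sampling
# ---------------------------------------------------------------------------

def _intensity_profile(chrom: Chromosome, cfg: SimulationConfig,
                       lsps: list[LSP]) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant relative recombination intensity over [1, length].

    Returns (edges, weights): edges is a sorted breakpoint array starting at 0
    and ending at chromosome length; weights[i] applies on
    (edges[i], edges[i+1]].
    """
    spans: list[tuple[float, float, float]] = []
    if cfg.centromere_suppression is not None:
        w, m = cfg.centromere_suppression
        spans.append((chrom.centromere_pos - w / 2, chrom.centromere_pos + w / 2, m))
    if cfg.lsp_suppression is not None:
        flank, m = cfg.lsp_suppression
        for l in lsps:
            if (l.chrom == chrom.id and l.zygosity == "heterozygous"
                    and l.positional_class == "non_sub_telomeric"):
                spans.append((l.start - flank, l.end + flank, m))
    for h in cfg.hotspot_map:
        if str(h[0]) == chrom.id:
            spans.append((float(h[1]), float(h[2]), float(h[3])))

    cuts = {0.0, float(chrom.length)}
    for s, e, _ in spans:
        cuts.add(min(max(s, 0.0), chrom.length))
        cuts.add(min(max(e, 0.0), chrom.length))
    edges = np.array(sorted(cuts))
    weights = np.ones(len(edges) - 1)
    mids = (edges[:-1] + edges[1:]) / 2
    for s, e, m in spans:
        weights[(mids > s) & (mids < e)] *= m
    return edges, weights


def sample_event_positions(chrom: Chromosome, n: int, cfg: SimulationConfig,
                           rng: np.random.Generator,
                           lsps: list[LSP] | None = None) -> np.ndarray:
    """Sample ``n`` event positions on one chromosome.

    With ``interference_shape == 1`` positions are i.i.d. draws from the
    intensity profile (uniform x hotspot multipliers x centromere/LSP
    suppression).  With shape > 1, n+1 gamma(shape) spacings are drawn and
    normalised over the intensity-transformed coordinate, which yields a
    gamma-renewal spacing pattern (more regular than Poisson) while leaving
    the marginal position density unchanged.  Positions are returned sorted.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return np.array([], dtype=np.int64)
    edges, weights = _intensity_profile(chrom, cfg, lsps or [])
    seg_mass = weights * np.diff(edges)
    cum = np.concatenate([[0.0], np.cumsum(seg_mass)])
    total = cum[-1]

    g = rng.gamma(cfg.interference_shape, size=n + 1)
    u = np.cumsum(g[:n]) / g.sum()          # n ordered points in (0, 1)
    t = u * total                            # transformed coordinate
    idx = np.clip(np.searchsorted(cum, t, side="right") - 1, 0, len(seg_mass) - 1)
    pos = edges[idx] + (t - cum[idx]) / np.maximum(weights[idx], 1e-300)
    pos = np.clip(np.round(pos), 1, chrom.length - 1).astype(np.int64)
    return np.sort(pos)


# ---------------------------------------------------------------------------
# tetrad simulation
# ---------------------------------------------------------------------------

def _phase_array(genome: GenomeMap, phase: np.ndarray | None) -> np.ndarray:
    """Homolog (1 or 2) carrying the N allele at each marker; default: all 1."""
    if phase is None:
        return np.ones(genome.n_markers, dtype=np.int8)
    phase = np.asarray(phase, dtype=np.int8)
    if phase.shape != (genome.n_markers,):
        raise ValueError("phase must have one entry per marker")
    return phase


def simulate_tetrad(genome: GenomeMap, cfg: SimulationConfig,
                    rng: np.random.Generator, tetrad_id: str = "t1",
                    phase: np.ndarray | None = None,
                    ) -> tuple[TetradGenotypes, list[dict]]:
    """Simulate one meiosis: returns genotypes at the marker positions and the
    ground-truth event list.

    Chromatids 0,1 copy homolog 1 and 2,3 copy homolog 2.  COs are applied in
    position order as suffix swaps between a random non-sister pair;
    conversions then overwrite a tract on one chromatid carrying the donor's
    opposite allele.  The spores are the four chromatids after all exchanges.
    """
    phase = _phase_array(genome, phase)
    spores = np.empty((4, genome.n_markers), dtype=np.int8)
    events: list[dict] = []

    for chrom in genome.chromosomes:
        sl = genome.chrom_slice(chrom.id)
        pos = genome.chrom_positions(chrom.id)
        m = len(pos)
        hom1_is_n = phase[sl] == 1
        alleles = np.empty((4, m), dtype=np.int8)
        alleles[0] = alleles[1] = np.where(hom1_is_n, CALL_N, CALL_S)
        alleles[2] = alleles[3] = np.where(hom1_is_n, CALL_S, CALL_N)

        mb = chrom.effective_length / 1e6
        n_co = rng.poisson(cfg.co_intercept + cfg.co_slope * mb)
        if cfg.obligate_co:
            while n_co == 0:
                n_co = rng.poisson(cfg.co_intercept + cfg.co_slope * mb)
        co_pos = sample_event_positions(chrom, n_co, cfg, rng, genome.lsps)
        for x in co_pos:
            # choose among non-sister pairs whose content differs locally, so
            # every CO is a phase change at its position (the detection model
            # the coverage-adjustment arithmetic assumes); local content is
            # read at the nearest marker right of the breakpoint
            if m:
                probe = min(int(np.searchsorted(pos, x, side="right")), m - 1)
                pairs = [p for p in _NON_SISTER_PAIRS
                         if alleles[p[0], probe] != alleles[p[1], probe]]
            else:
                pairs = list(_NON_SISTER_PAIRS)
            a, b = pairs[rng.integers(len(pairs))]
            right = pos > x
            tmp = alleles[a, right].copy()
            alleles[a, right] = alleles[b, right]
            alleles[b, right] = tmp
            events.append(dict(tetrad=tetrad_id, chrom=chrom.id, type="CO",
                               start=int(x), end=int(x),
                               chromatids=f"{a}-{b}", direction="",
                               n_markers=0))

        n_gc = rng.poisson(cfg.ncogc_intercept + cfg.ncogc_slope * mb)
        gc_pos = sample_event_positions(chrom, n_gc, cfg, rng, genome.lsps)
        for c in gc_pos:
            length = rng.geometric(1.0 / cfg.tract_mean)
            start = max(1, int(c) - length // 2)
            end = min(chrom.length, start + length - 1)
            to_n = rng.random() < cfg.parity
            donor = CALL_N if to_n else CALL_S
            inside = (pos >= start) & (pos <= end)
            n_markers = int(inside.sum())
            if n_markers:
                inside_idx = np.flatnonzero(inside)
                centre = inside_idx[np.argmin(np.abs(pos[inside_idx] - c))]
                recipients = np.flatnonzero(alleles[:, centre] != donor)
                if len(recipients) == 0:       # all chromatids already donor-like
                    recipients = np.arange(4)
                chromatid = int(rng.choice(recipients))
                alleles[chromatid, inside] = donor
            else:
                chromatid = int(rng.integers(4))
            events.append(dict(tetrad=tetrad_id, chrom=chrom.id, type="NCOGC",
                               start=start, end=end,
                               chromatids=str(chromatid),
                               direction="to_N" if to_n else "to_S",
                               n_markers=n_markers))
        spores[:, sl] = alleles

    return TetradGenotypes(tetrad_id, spores), events


def simulate_cohort(genome: GenomeMap, cfg: SimulationConfig,
                    n_tetrads: int, phase: np.ndarray | None = None,
                    ) -> tuple[list[TetradGenotypes], pd.DataFrame]:
    """Simulate ``n_tetrads`` meioses.

    Deterministic given ``cfg.seed``; each tetrad draws from a substream keyed
    by (seed, tetrad index), so results do not depend on iteration order.
    """
    if n_tetrads < 1:
        raise ValueError("n_tetrads must be >= 1")
    tetrads = []
    all_events: list[dict] = []
    for i in range(n_tetrads):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(i,)))
        t, ev = simulate_tetrad(genome, cfg, rng, tetrad_id=f"t{i + 1:03d}",
                                phase=phase)
        tetrads.append(t)
        all_events.extend(ev)
    truth = pd.DataFrame(all_events, columns=TRUE_EVENT_COLUMNS)
    return tetrads, truth


# ---------------------------------------------------------------------------
# probe intensities
# ---------------------------------------------------------------------------

def simulate_intensities(tetrads: list[TetradGenotypes], genome: GenomeMap,
                         rng: np.random.Generator, fold: float = 30.5,
                         cv: float = 0.2, replicates: int = 5) -> np.ndarray:
    """Log-normal replicate probe intensities for every segregant.

    The probes match the S288C-like allele, so S-carriers draw from a
    distribution whose mean is ``fold`` times the non-carrier mean.  Returns a
    (n_segregants, n_markers, replicates) array; segregants are the tetrads'
    spores in order.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    calls = np.vstack([t.spores for t in tetrads])        # (n_seg, n_markers)
    sigma2 = np.log1p(cv ** 2)
    sigma = np.sqrt(sigma2)
    mean = np.where(calls == CALL_S, fold, 1.0)
    mu = np.log(mean) - sigma2 / 2
    n_seg, n_mark = calls.shape
    z = rng.standard_normal((n_seg, n_mark, replicates))
    return np.exp(mu[:, :, None] + sigma * z)


# ---------------------------------------------------------------------------
# desk-scale detection model
# ---------------------------------------------------------------------------

def simulate_detected_co_counts(rng: np.random.Generator,
                                n_tetrads: int = 120,
                                mean_per_meiosis: float = 87.13,
                                detection_prob: float = 1 / 1.23) -> np.ndarray:
    """Per-tetrad detected crossover counts under the coverage model: true
    counts are Poisson(mean_per_meiosis) and each CO is independently seen
    with probability ``detection_prob`` (the reciprocal of the coverage
    adjustment multiplier)."""
    true = rng.poisson(mean_per_meiosis, size=n_tetrads)
    return rng.binomial(true, detection_prob)
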