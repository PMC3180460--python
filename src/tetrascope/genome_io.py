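"""Shared data model and tabular I/O for tetrad-based recombination mapping.

All genomic coordinates are 1-based inclusive, following the S288C reference
convention used throughout yeast genetics.  BED output is the only place where
coordinates are converted to 0-based half-open.

Genotype calls use a three-symbol alphabet at the array level:
``CALL_S`` (S288C-like allele), ``CALL_N`` (non-S288C allele) and
``CALL_MISSING``.  The on-disk genotype dialect encodes S as ``1`` and N as
``10``; any other token maps to missing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CALL_MISSING: int = 0
CALL_S: int = 1
CALL_N: int = 2

#: on-disk genotype dialect (Agilent genotyping-array export convention)
GENOTYPE_CODES = {"1": CALL_S, "10": CALL_N}
_CALL_TO_CODE = {CALL_S: "1", CALL_N: "10", CALL_MISSING: "NA"}

#: a chromosome end region is "sub-telomeric" when it lies within this many
#: base pairs of the telomere
SUBTELOMERE_BP: int = 20_000

#: rDNA repeat locus on chromosome XII (S288C reference span); excluded from
#: chromosome length for rate and regression purposes
RDNA_SPAN_XII: tuple[int, int] = (451_575, 468_931)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Chromosome:
    """One chromosome: physical length, centromere and optional rDNA span."""

    id: str
    length: int
    centromere_pos: int
    rdna_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not (0 < self.centromere_pos < self.length):
            raise ValueError(
                f"chromosome {self.id}: centromere {self.centromere_pos} "
                f"outside (0, {self.length})"
            )
        if self.rdna_span is not None:
            s, e = self.rdna_span
            if not (1 <= s <= e <= self.length):
                raise ValueError(f"chromosome {self.id}: rDNA span {self.rdna_span} "
                                 f"outside [1, {self.length}]")

    @property
    def effective_length(self) -> int:
        """Length with the rDNA span (if any) excluded."""
        if self.rdna_span is None:
            return self.length
        s, e = self.rdna_span
        return self.length - (e - s + 1)


@dataclass
class LSP:
    """Large sequence polymorphism (>=500 bp deletion or highly diverged span).

    ``positional_class`` is always derived from the 20-kb telomere rule, never
    taken from an input file.
    """

    id: str
    chrom: str
    start: int
    end: int
    zygosity: str = "heterozygous"
    association: str = "other"
    positional_class: str = field(default="non_sub_telomeric")

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"LSP {self.id}: start {self.start} > end {self.end}")
        if self.zygosity not in ("heterozygous", "homozygous"):
            raise ValueError(f"LSP {self.id}: bad zygosity {self.zygosity!r}")

    def classify_position(self, chrom_length: int) -> None:
        """Set positional_class: sub-telomeric iff the whole span lies within
        SUBTELOMERE_BP of either chromosome end."""
        if self.end > chrom_length:
            raise ValueError(
                f"LSP {self.id}: span {self.start}-{self.end} outside "
                f"chromosome of length {chrom_length}"
            )
        near_left = self.end <= SUBTELOMERE_BP
        near_right = self.start > chrom_length - SUBTELOMERE_BP
        self.positional_class = (
            "sub_telomeric" if (near_left or near_right) else "non_sub_telomeric"
        )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class TetradGenotypes:
    """Genotype calls for the four spores of one meiosis.

    ``spores`` is a (4, n_markers) int8 array aligned to the genome's marker
    table, with values CALL_S / CALL_N / CALL_MISSING.
    """

    tetrad_id: str
    spores: np.ndarray

    def __post_init__(self) -> None:
        self.spores = np.asarray(self.spores, dtype=np.int8)
        if self.spores.ndim != 2 or self.spores.shape[0] != 4:
            raise ValueError("spores must be a (4, n_markers) array")


class GenomeMap:
    """Chromosome geometry plus the ordered heterozygous-marker table.

    Parameters
    ----------
    chromosomes:
        List of :class:`Chromosome`.
    markers:
        DataFrame with columns ``chrom`` (str), ``pos`` (int, 1-based) and
        ``marker_id`` (str).  Rows are sorted by chromosome (in the order of
        `chromosomes`) then position; markers on a chromosome must be strictly
        increasing and ids unique.
    lsps:
        Optional list of :class:`LSP`; positional classes are (re)derived.
    """

    def __init__(self, chromosomes: list[Chromosome],
                 markers: pd.DataFrame,
                 lsps: list[LSP] | None = None) -> None:
        self.chromosomes = list(chromosomes)
        self._chrom_by_id = {c.id: c for c in self.chromosomes}
        if len(self._chrom_by_id) != len(self.chromosomes):
            raise ValueError("duplicate chromosome ids")

        markers = markers.copy()
        markers["chrom"] = markers["chrom"].astype(str)
        markers["pos"] = markers["pos"].astype(np.int64)
        unknown = set(markers["chrom"]) - set(self._chrom_by_id)
        if unknown:
            raise ValueError(f"markers on unknown chromosomes: {sorted(unknown)}")
        order = {c.id: i for i, c in enumerate(self.chromosomes)}
        markers = markers.sort_values(
            ["chrom", "pos"], key=lambda s: s.map(order) if s.name == "chrom" else s,
            kind="mergesort",
        ).reset_index(drop=True)
        for cid, grp in markers.groupby("chrom", sort=False):
            dup = grp["pos"][grp["pos"].duplicated()]
            if len(dup):
                raise ValueError(
                    f"duplicate marker position {int(dup.iloc[0])} on chromosome {cid}"
                )
            if len(grp) == 1:
                warnings.warn(
                    f"chromosome {cid} carries a single marker: covered span is "
                    "degenerate", stacklevel=2)
        if markers["marker_id"].duplicated().any():
            raise ValueError("duplicate marker ids")
        self.markers = markers

        # row ranges per chromosome for fast slicing
        self._slices: dict[str, slice] = {}
        start = 0
        for cid, grp in markers.groupby("chrom", sort=False):
            self._slices[cid] = slice(start, start + len(grp))
            start += len(grp)

        self.lsps: list[LSP] = []
        for lsp in (lsps or []):
            self.add_lsp(lsp)

    # -- accessors ---------------------------------------------------------

    def chromosome(self, cid: str) -> Chromosome:
        return self._chrom_by_id[str(cid)]

    def chrom_slice(self, cid: str) -> slice:
        """Row slice of `markers` for one chromosome (empty slice if none)."""
        return self._slices.get(str(cid), slice(0, 0))

    def chrom_positions(self, cid: str) -> np.ndarray:
        return self.markers["pos"].to_numpy()[self.chrom_slice(cid)]

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def add_lsp(self, lsp: LSP) -> None:
        chrom = self.chromosome(lsp.chrom)
        lsp.classify_position(chrom.length)
        self.lsps.append(lsp)

    # -- derived quantities ------------------------------------------------

    def covered_fraction(self, exclude_rdna: bool = True) -> float:
        """Fraction of the genome between the first and last marker of each
        chromosome: sum(last - first + 1) / sum(chromosome length).

        With ``exclude_rdna`` the rDNA span is subtracted from the denominator
        (it is a repeat region the marker set cannot represent).
        """
        num = 0
        for cid in self._slices:
            pos = self.chrom_positions(cid)
            if len(pos) >= 1:
                num += int(pos[-1] - pos[0] + 1)
        den = sum(
            c.effective_length if exclude_rdna else c.length
            for c in self.chromosomes
        )
        return num / den

    def heterozygous_nonsub_lsps(self) -> list[LSP]:
        return [l for l in self.lsps
                if l.zygosity == "heterozygous"
                and l.positional_class == "non_sub_telomeric"]


# ---------------------------------------------------------------------------
# default geometry
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("tetrascope.data").joinpath(name)


def default_chromosomes(include_rdna: bool = True) -> list[Chromosome]:
    """The 16 S. cerevisiae chromosomes (S288C lengths and centromeres)."""
    with resources.as_file(_data_path("s288c_chromosomes.tsv")) as p:
        tab = pd.read_csv(p, sep="\t", dtype={"chrom": str})
    out = []
    for row in tab.itertuples(index=False):
        rdna = RDNA_SPAN_XII if (include_rdna and row.chrom == "12") else None
        out.append(Chromosome(row.chrom, int(row.length),
                              int(row.centromere_pos), rdna))
    return out


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, comment="#")


def read_marker_map(path, chromosomes: list[Chromosome] | None = None) -> GenomeMap:
    """Read a tab-separated marker map (chrom, pos, marker_id; 1-based).

    A header row is detected by a non-numeric ``pos`` field.  Rows may appear
    in any order; the resulting map is sorted.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if raw.shape[1] < 3:
        raise ValueError(f"{path}: expected >=3 tab-separated columns")
    first = raw.iloc[0]
    if not str(first[1]).strip().isdigit():
        raw = raw.iloc[1:]
    markers = pd.DataFrame({
        "chrom": raw[0].astype(str).str.strip(),
        "pos": raw[1].astype(np.int64),
        "marker_id": raw[2].astype(str).str.strip(),
    })
    return GenomeMap(chromosomes or default_chromosomes(), markers)


def read_genotype_matrix(path, genome: GenomeMap) -> list[TetradGenotypes]:
    """Read a genotype matrix: rows keyed ``chrom:pos``, columns = segregants.

    Segregant columns are grouped into tetrads of four consecutive columns;
    tetrad ids are taken from a shared ``<prefix>_<spore>`` column-name prefix
    when all four members of a group agree, else generated.  Cell codes: ``1``
    -> S, ``10`` -> N, anything else -> missing (count logged).
    """
    tab = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    n_seg = tab.shape[1]
    if n_seg % 4 != 0:
        raise ValueError(
            f"{path}: {n_seg} segregant columns, not divisible by 4 and no "
            "tetrad assignment given")

    # align rows to the genome's marker order
    key = genome.markers["chrom"].astype(str) + ":" + genome.markers["pos"].astype(str)
    missing_rows = set(key) - set(tab.index)
    extra_rows = set(tab.index) - set(key)
    if extra_rows:
        logger.warning("%s: %d rows do not match any marker; ignored",
                       path, len(extra_rows))
    tab = tab.reindex(key)

    calls = np.full(tab.shape, CALL_MISSING, dtype=np.int8)
    vals = tab.to_numpy(dtype=object)
    unknown = 0
    for code, call in GENOTYPE_CODES.items():
        calls[vals == code] = call
    recognised = np.isin(vals, list(GENOTYPE_CODES)) | pd.isna(vals)
    unknown = int((~recognised).sum())
    if unknown:
        logger.info("%s: %d unrecognised genotype codes mapped to missing",
                    path, unknown)
    if missing_rows:
        logger.info("%s: %d markers absent from the file; filled as missing",
                    path, len(missing_rows))

    tetrads = []
    cols = list(tab.columns)
    for t in range(n_seg // 4):
        group = cols[4 * t: 4 * t + 4]
        prefixes = {c.rsplit("_", 1)[0] for c in group}
        tid = prefixes.pop() if len(prefixes) == 1 else f"tetrad_{t + 1}"
        tetrads.append(TetradGenotypes(tid, calls[:, 4 * t: 4 * t + 4].T))
    return tetrads


def read_lsp_table(path, genome: GenomeMap) -> list[LSP]:
    """Read an LSP table (id, chrom, start, end, zygosity, association).

    The sub-telomeric/non-sub-telomeric class is derived from the 20-kb rule,
    never read from the file.
    """
    tab = _read_table(path)
    lsps = []
    for row in tab.itertuples(index=False):
        lsp = LSP(str(row.id), str(row.chrom), int(row.start), int(row.end),
                  str(row.zygosity), str(getattr(row, "association", "other")))
        genome.add_lsp(lsp)
        lsps.append(lsp)
    return lsps


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ["tetrad", "chrom", "type", "left", "right",
                 "multiplicity", "direction"]


def write_events(events: pd.DataFrame, path) -> None:
    cols = [c for c in EVENT_COLUMNS if c in events.columns]
    extra = [c for c in events.columns if c not in cols]
    events[cols + extra].to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "tetrad": str})


def write_genotype_matrix(tetrads: list[TetradGenotypes], genome: GenomeMap,
                          path) -> None:
    """Write tetrad genotypes in the on-disk dialect (rows ``chrom:pos``,
    four columns per tetrad named ``<tetrad>_<a..d>``)."""
    key = genome.markers["chrom"].astype(str) + ":" + genome.markers["pos"].astype(str)
    data = {}
    for t in tetrads:
        for i, spore in enumerate("abcd"):
            col = f"{t.tetrad_id}_{spore}"
            data[col] = [_CALL_TO_CODE[int(v)] for v in t.spores[i]]
    pd.DataFrame(data, index=key).to_csv(path, sep="\t", index_label="marker")


def spans_to_bed(table: pd.DataFrame, name_col: str | None = None) -> str:
    """Convert 1-based inclusive ``chrom``/``left``/``right`` spans to BED
    text (0-based half-open), preserving span length."""
    lines = []
    for i, row in enumerate(table.itertuples(index=False)):
        name = getattr(row, name_col) if name_col else f"region_{i + 1}"
        lines.append(f"{row.chrom}\t{int(row.left) - 1}\t{int(row.right)}\t{name}")
    return "\n".join(lines) + ("\n" if lines else "")


def write_outputs(out_dir, events: pd.DataFrame | None = None,
                  intervals: pd.DataFrame | None = None,
                  hotspots: pd.DataFrame | None = None,
                  reports: dict[str, pd.DataFrame] | None = None,
                  summary: str | None = None) -> None:
    """Write the standard output bundle (TSV tables, hotspot BED, summary)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if events is not None:
        write_events(events, out / "events.tsv")
    if intervals is not None:
        intervals.to_csv(out / "intervals.tsv", sep="\t", index=False)
    if hotspots is not None:
        hotspots.to_csv(out / "hotspots.tsv", sep="\t", index=False)
        name_col = "id" if "id" in hotspots.columns else None
        (out / "hotspots.bed").write_text(spans_to_bed(hotspots, name_col))
    for name, tab in (reports or {}).items():
        tab.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    if summary is not None:
        (out / "summary.txt").write_text(summary)


def load_published_ncogc_table() -> pd.DataFrame:
    """The published EM93 top-50 NCOGC polymorphism table (120 tetrads).

    Columns: rank, chrom, snp_pos, lsp_distance (bp to nearest LSP on the same
    chromosome, NA when the chromosome carries none), ncogc_total, n13 / n31
    (1:3 and 3:1 S:N conversion counts), flank_left / flank_right (coordinates
    of the markers flanking the polymorphism), co_total (crossovers between
    the flanks), ratio (NCOGC/CO; ">x" when no CO was seen), kb_per_cm, and a
    nonparity flag for the rows reported as significantly biased.
    """
    with resources.as_file(_data_path("em93_ncogc_top50.tsv")) as p:
        return pd.read_csv(p, sep="\t", na_values=["NA"],
                           dtype={"ratio": str, "kb_per_cm": str})
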