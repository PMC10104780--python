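"""Containers and text I/O for binned Hi-C matrices, tracks, site catalogs and
HTGTS junction tables.

All genomic coordinates are 0-based, half-open internally.  BED and bedGraph
are read as-is (they already use that convention); point sites coming from
1-based sources must be converted by the caller (each reader documents its
expectation).  The native contact-matrix format is the cooler-dump-compatible
pair of plain TSV files::

    bins.tsv    chrom <TAB> start <TAB> end            (one row per bin)
    pixels.tsv  bin1_id <TAB> bin2_id <TAB> count      (upper triangle only)

so text exports of real cooler files load unchanged.
"""

from __future__ import annotations

import io as _pyio
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinTable",
    "ContactMatrix",
    "ScalarTrack",
    "SiteCatalog",
    "JunctionTable",
    "FormatError",
    "ValidationError",
    "read_contact_matrix",
    "write_contact_matrix",
    "read_track",
    "write_track",
    "read_sites",
    "write_sites",
    "read_junctions",
    "write_junctions",
    "read_fasta",
    "write_fasta",
]


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """Contents parse but violate an invariant (coordinates, counts...)."""


# ---------------------------------------------------------------------------
# Bin table
# ---------------------------------------------------------------------------


class BinTable:
    """Uniform genomic bins tiling a set of chromosomes.

    Bins are dense and ordered by (chromosome, start); ``bin_id`` is the row
    index.  The terminal bin of each chromosome may be shorter than
    ``bin_size``.
    """

    def __init__(self, df: pd.DataFrame, bin_size: int):
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise FormatError(f"bin table needs columns {sorted(required)}")
        self.df = df.reset_index(drop=True)[["chrom", "start", "end"]].copy()
        self.df["chrom"] = self.df["chrom"].astype(str)
        self.bin_size = int(bin_size)
        self._validate()
        # per-chromosome offsets for O(1) position lookup
        self._offsets: dict[str, tuple[int, int]] = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            self._offsets[chrom] = (int(sub.index[0]), int(sub.index[-1]) + 1)

    def _validate(self) -> None:
        for chrom, sub in self.df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if starts[0] != 0:
                raise ValidationError(f"{chrom}: bins must start at 0")
            if not np.array_equal(starts[1:], ends[:-1]):
                raise ValidationError(f"{chrom}: bins have gaps or overlaps")
            widths = ends - starts
            if np.any(widths[:-1] != self.bin_size):
                raise ValidationError(f"{chrom}: non-terminal bin width != bin_size")
            if widths[-1] > self.bin_size or widths[-1] <= 0:
                raise ValidationError(f"{chrom}: bad terminal bin width")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_chromsizes(cls, chromsizes: Mapping[str, int], bin_size: int) -> "BinTable":
        rows = []
        for chrom, size in chromsizes.items():
            edges = list(range(0, int(size), int(bin_size))) + [int(size)]
            for s, e in zip(edges[:-1], edges[1:]):
                rows.append((str(chrom), s, e))
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end"]), bin_size)

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_bins(self) -> int:
        return len(self.df)

    @property
    def chromsizes(self) -> dict[str, int]:
        return {c: int(self.df.loc[hi - 1, "end"]) for c, (lo, hi) in self._offsets.items()}

    @property
    def chromosomes(self) -> list[str]:
        return list(self._offsets)

    def chrom_slice(self, chrom: str) -> slice:
        lo, hi = self._offsets[chrom]
        return slice(lo, hi)

    def n_bins_chrom(self, chrom: str) -> int:
        lo, hi = self._offsets[chrom]
        return hi - lo

    def bin_id(self, chrom: str, position: int) -> int:
        """Unique bin with ``start <= position < end``."""
        if chrom not in self._offsets:
            raise KeyError(f"unknown chromosome {chrom!r}")
        lo, hi = self._offsets[chrom]
        size = int(self.df.loc[hi - 1, "end"])
        if not 0 <= position < size:
            raise ValidationError(f"position {chrom}:{position} outside chromosome")
        return lo + min(int(position) // self.bin_size, hi - lo - 1)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BinTable)
            and self.bin_size == other.bin_size
            and self.df.equals(other.df)
        )


# ---------------------------------------------------------------------------
# Contact matrix
# ---------------------------------------------------------------------------


class ContactMatrix:
    """Sparse upper-triangle cis/trans contact matrix on a :class:`BinTable`.

    ``pixels`` holds one row per non-zero element with ``bin1_id <= bin2_id``.
    ``weights`` (set by balancing) is a per-bin multiplier with NaN marking
    filtered bins; the balanced value of a pixel is
    ``count * weights[bin1] * weights[bin2]``.
    """

    def __init__(
        self,
        bins: BinTable,
        pixels: pd.DataFrame,
        weights: np.ndarray | None = None,
    ):
        required = {"bin1_id", "bin2_id", "count"}
        if not required.issubset(pixels.columns):
            raise FormatError(f"pixels need columns {sorted(required)}")
        px = pixels.reset_index(drop=True)[["bin1_id", "bin2_id", "count"]].copy()
        px["bin1_id"] = px["bin1_id"].astype(np.int64)
        px["bin2_id"] = px["bin2_id"].astype(np.int64)
        px["count"] = px["count"].astype(np.int64)
        if len(px):
            if px["count"].min() < 0:
                raise ValidationError("negative pixel counts")
            if (px["bin1_id"] > px["bin2_id"]).any():
                raise ValidationError("pixels must satisfy bin1_id <= bin2_id")
            if px["bin2_id"].max() >= len(bins) or px["bin1_id"].min() < 0:
                raise FormatError("pixel bin ids outside the bin table")
            if px.duplicated(["bin1_id", "bin2_id"]).any():
                raise ValidationError("duplicate (bin1_id, bin2_id) pixels")
        self.bins = bins
        self.pixels = px
        if weights is not None:
            weights = np.asarray(weights, dtype=float)
            if weights.shape != (len(bins),):
                raise ValidationError("weights length must equal number of bins")
        self.weights = weights

    @property
    def total_valid_pairs(self) -> int:
        return int(self.pixels["count"].sum())

    # -- dense views -------------------------------------------------------

    def to_dense(self, chrom: str | None = None, balanced: bool = False) -> np.ndarray:
        """Dense symmetric matrix (one chromosome, or genome-wide).

        Balanced output has NaN on filtered rows/columns.
        """
        if chrom is None:
            lo, hi = 0, len(self.bins)
            px = self.pixels
        else:
            sl = self.bins.chrom_slice(chrom)
            lo, hi = sl.start, sl.stop
            m = (
                (self.pixels["bin1_id"] >= lo)
                & (self.pixels["bin2_id"] < hi)
                & (self.pixels["bin1_id"] < hi)
                & (self.pixels["bin2_id"] >= lo)
            )
            px = self.pixels[m]
        n = hi - lo
        out = np.zeros((n, n), dtype=float)
        i = px["bin1_id"].to_numpy() - lo
        j = px["bin2_id"].to_numpy() - lo
        v = px["count"].to_numpy().astype(float)
        out[i, j] = v
        out[j, i] = v
        if balanced:
            if self.weights is None:
                raise ValidationError("matrix has no balancing weights")
            w = self.weights[lo:hi]
            out = out * w[:, None] * w[None, :]
        return out

    # -- transforms --------------------------------------------------------

    def coarsen(self, factor: int) -> "ContactMatrix":
        """Aggregate ``factor`` adjacent bins into one by exact count summation."""
        if factor < 1:
            raise ValidationError("factor must be >= 1")
        if factor == 1:
            return ContactMatrix(self.bins, self.pixels.copy())
        new_bins = BinTable.from_chromsizes(self.bins.chromsizes, self.bins.bin_size * factor)
        # map old bin id -> new bin id chromosome by chromosome
        mapping = np.empty(len(self.bins), dtype=np.int64)
        for chrom in self.bins.chromosomes:
            sl = self.bins.chrom_slice(chrom)
            nl = new_bins.chrom_slice(chrom)
            idx = np.arange(sl.stop - sl.start) // factor
            mapping[sl] = nl.start + idx
        b1 = mapping[self.pixels["bin1_id"].to_numpy()]
        b2 = mapping[self.pixels["bin2_id"].to_numpy()]
        lo = np.minimum(b1, b2)
        hi = np.maximum(b1, b2)
        grouped = (
            pd.DataFrame({"bin1_id": lo, "bin2_id": hi, "count": self.pixels["count"].to_numpy()})
            .groupby(["bin1_id", "bin2_id"], as_index=False)["count"]
            .sum()
        )
        return ContactMatrix(new_bins, grouped)


# ---------------------------------------------------------------------------
# Scalar track
# ---------------------------------------------------------------------------


@dataclass
class ScalarTrack:
    """One real value (or NaN = missing) per bin of a :class:`BinTable`."""

    bins: BinTable
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.bins),):
            raise ValidationError("track length must equal number of bins")

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.values[self.bins.chrom_slice(chrom)]


# ---------------------------------------------------------------------------
# Site catalog
# ---------------------------------------------------------------------------


class SiteCatalog:
    """Genomic point features with optional orientation and rank score.

    Used for AsiSI cut sites (scored by cleavage frequency) and oriented CTCF
    anchors (strand = motif direction).
    """

    COLUMNS = ["chrom", "position", "strand", "score", "name"]

    def __init__(self, df: pd.DataFrame):
        d = df.copy()
        for col, default in [("strand", "."), ("score", np.nan), ("name", "")]:
            if col not in d.columns:
                d[col] = default
        self.df = d.reset_index(drop=True)[self.COLUMNS]
        self.df["chrom"] = self.df["chrom"].astype(str)
        self.df["position"] = self.df["position"].astype(np.int64)
        if self.df.duplicated(["chrom", "position", "strand"]).any():
            raise ValidationError("duplicate (chrom, position, strand) sites")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple]
    ) -> "SiteCatalog":
        """Records of (chrom, position[, strand[, score[, name]]])."""
        rows = []
        for rec in records:
            rec = tuple(rec) + (".", np.nan, "")[len(rec) - 2 :]
            rows.append(rec[:5])
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS))

    def top(self, n: int) -> "SiteCatalog":
        return SiteCatalog(self.df.sort_values("score", ascending=False).head(n))

    def positions(self, chrom: str) -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, "position"].to_numpy()


# ---------------------------------------------------------------------------
# Junction table
# ---------------------------------------------------------------------------


@dataclass
class JunctionTable:
    """HTGTS junction records plus the bait-only read count.

    ``records`` columns: prey_chrom, prey_pos, prey_strand, bait_end_on_read
    (1-based, last read base aligned to bait), prey_start_on_read (1-based,
    first read base aligned to prey), seq.  ``total_events`` counts junctions
    plus bait-only reads and is the denominator of the per-1,000-events
    normalization.
    """

    records: pd.DataFrame
    bait_chrom: str
    bait_pos: int
    bait_strand: str = "+"
    n_bait_only: int = 0

    RECORD_COLUMNS = [
        "prey_chrom",
        "prey_pos",
        "prey_strand",
        "bait_end_on_read",
        "prey_start_on_read",
        "seq",
    ]

    def __post_init__(self):
        missing = set(self.RECORD_COLUMNS) - set(self.records.columns)
        if missing:
            raise FormatError(f"junction records missing columns {sorted(missing)}")
        self.records = self.records.reset_index(drop=True)
        self.records["intra_chromosomal"] = self.records["prey_chrom"] == self.bait_chrom

    @property
    def n_junctions(self) -> int:
        return len(self.records)

    @property
    def total_events(self) -> int:
        return self.n_junctions + int(self.n_bait_only)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _infer_bin_size(bins_df: pd.DataFrame) -> int:
    widths = (bins_df["end"] - bins_df["start"]).to_numpy()
    return int(widths.max())


def read_contact_matrix(
    path: str | Path,
    bins_path: str | Path | None = None,
    resolution: int | None = None,
) -> ContactMatrix:
    """Load a contact matrix from a pixel TSV + companion bin-table TSV.

    ``path`` points at the pixel file (``bin1_id  bin2_id  count``);
    ``bins_path`` defaults to ``bins.tsv`` next to it.  If ``resolution`` is
    given and coarser than the stored bin size, counts are summed exactly into
    the coarser bins (the requested resolution must be a multiple).
    """
    path = Path(path)
    if bins_path is None:
        bins_path = path.with_name("bins.tsv")
    bins_df = pd.read_csv(bins_path, sep="\t", comment="#")
    if not {"chrom", "start", "end"}.issubset(bins_df.columns):
        bins_df = pd.read_csv(
            bins_path, sep="\t", comment="#", header=None, names=["chrom", "start", "end"]
        )
    bins = BinTable(bins_df, _infer_bin_size(bins_df))
    px = pd.read_csv(path, sep="\t", comment="#")
    if not {"bin1_id", "bin2_id", "count"}.issubset(px.columns):
        px = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=["bin1_id", "bin2_id", "count"]
        )
    if len(px) and (px["count"] < 0).any():
        raise ValidationError("negative counts in pixel file")
    mat = ContactMatrix(bins, px)
    if resolution is not None and resolution != bins.bin_size:
        if resolution % bins.bin_size:
            raise ValidationError("requested resolution not a multiple of stored bin size")
        mat = mat.coarsen(resolution // bins.bin_size)
    return mat


def write_contact_matrix(matrix: ContactMatrix, pixels_path: str | Path,
                         bins_path: str | Path | None = None) -> None:
    pixels_path = Path(pixels_path)
    if bins_path is None:
        bins_path = pixels_path.with_name("bins.tsv")
    matrix.bins.df.to_csv(bins_path, sep="\t", index=False)
    matrix.pixels.to_csv(pixels_path, sep="\t", index=False)


def read_track(path: str | Path, bins: BinTable, label: str = "") -> ScalarTrack:
    """Average a bedGraph into per-bin values (length-weighted).

    Bins not covered by any interval are NaN.  Intervals extending beyond the
    chromosome end raise :class:`ValidationError`.
    """
    bg = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    sizes = bins.chromsizes
    num = np.zeros(len(bins))
    cov = np.zeros(len(bins))
    for chrom, sub in bg.groupby("chrom", sort=False):
        chrom = str(chrom)
        if chrom not in sizes:
            continue
        if (sub["end"] > sizes[chrom]).any() or (sub["start"] < 0).any():
            raise ValidationError(f"bedGraph interval beyond {chrom} end")
        sl = bins.chrom_slice(chrom)
        for start, end, value in sub[["start", "end", "value"]].itertuples(index=False):
            b0 = int(start) // bins.bin_size
            b1 = (int(end) - 1) // bins.bin_size
            for b in range(b0, b1 + 1):
                lo = max(int(start), b * bins.bin_size)
                hi = min(int(end), (b + 1) * bins.bin_size)
                gid = sl.start + b
                num[gid] += value * (hi - lo)
                cov[gid] += hi - lo
    values = np.full(len(bins), np.nan)
    has = cov > 0
    values[has] = num[has] / cov[has]
    return ScalarTrack(bins, values, label=label or Path(path).stem)


def write_track(track: ScalarTrack, path: str | Path) -> None:
    """Write a track as bedGraph; missing bins are omitted."""
    df = track.bins.df.copy()
    df["value"] = track.values
    df.dropna().to_csv(path, sep="\t", index=False, header=False)


def read_sites(path: str | Path, one_based: bool = False) -> SiteCatalog:
    """Read point sites from BED (chrom, start, end[, name[, score[, strand]]]).

    Position = interval midpoint.  Set ``one_based=True`` for 1-based inputs
    (position column 2 used directly after subtracting 1).
    """
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = bed.shape[1]
    bed.columns = ["chrom", "start", "end", "name", "score", "strand"][:ncol]
    if one_based:
        pos = bed["start"].astype(int) - 1
    else:
        pos = (bed["start"].astype(int) + bed["end"].astype(int)) // 2
    return SiteCatalog(
        pd.DataFrame(
            {
                "chrom": bed["chrom"].astype(str),
                "position": pos,
                "strand": bed["strand"] if "strand" in bed else ".",
                "score": bed["score"] if "score" in bed else np.nan,
                "name": bed["name"] if "name" in bed else "",
            }
        )
    )


def write_sites(catalog: SiteCatalog, path: str | Path) -> None:
    """Write sites as 6-column BED (1-bp intervals)."""
    df = catalog.df
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["position"],
            "end": df["position"] + 1,
            "name": df["name"].replace("", "."),
            "score": df["score"].fillna(0),
            "strand": df["strand"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


# TLX-style dialect: the reader accepts either the minimal documented column
# set below or classic transloc_pipeline names (mapped case-insensitively).
_TLX_ALIASES = {
    "rname": "prey_chrom",
    "junction": "prey_pos",
    "strand": "prey_strand",
    "b_qend": "bait_end_on_read",
    "qstart": "prey_start_on_read",
    "seq": "seq",
}
_BAIT_ONLY_MARKERS = {"", "*", "nan", "none", "adapter"}


def read_junctions(path: str | Path, known_chromosomes: Sequence[str] | None = None
                   ) -> JunctionTable:
    """Read a TLX-style TSV of HTGTS junctions.

    Required columns (native names or transloc_pipeline aliases): prey_chrom
    (Rname), prey_pos (Junction), prey_strand (Strand), bait_end_on_read
    (B_Qend), prey_start_on_read (Qstart), seq (Seq).  Rows whose prey
    chromosome is empty/``*`` are bait-only reads and only contribute to
    ``total_events``.  A header comment ``# bait=chrom:pos:strand`` carries
    the bait locus.  Records on chromosomes outside ``known_chromosomes``
    (when given) are skipped with a warning.
    """
    path = Path(path)
    bait_chrom, bait_pos, bait_strand = "", 0, "+"
    with open(path) as fh:
        header_lines = []
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line)
                if "bait=" in line:
                    parts = line.split("bait=")[1].strip().split(":")
                    bait_chrom, bait_pos = parts[0], int(parts[1])
                    if len(parts) > 2:
                        bait_strand = parts[2]
            else:
                break
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    df.columns = [_TLX_ALIASES.get(c.lower(), c.lower()) for c in df.columns]
    if "prey_start_on_read" not in df.columns:
        raise FormatError("prey-start-on-read column missing (Qstart)")
    missing = set(JunctionTable.RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"junction file missing columns {sorted(missing)}")
    prey = df["prey_chrom"].astype(str).str.strip().str.lower()
    bait_only = prey.isin(_BAIT_ONLY_MARKERS)
    records = df[~bait_only].copy()
    n_skipped = 0
    if known_chromosomes is not None:
        known = set(map(str, known_chromosomes))
        keep = records["prey_chrom"].astype(str).isin(known)
        n_skipped = int((~keep).sum())
        if n_skipped:
            warnings.warn(f"skipped {n_skipped} junction(s) on unknown chromosomes")
        records = records[keep]
    records = records[JunctionTable.RECORD_COLUMNS].copy()
    records["prey_pos"] = records["prey_pos"].astype(np.int64)
    records["bait_end_on_read"] = records["bait_end_on_read"].astype(np.int64)
    records["prey_start_on_read"] = records["prey_start_on_read"].astype(np.int64)
    table = JunctionTable(
        records,
        bait_chrom=bait_chrom,
        bait_pos=bait_pos,
        bait_strand=bait_strand,
        n_bait_only=int(bait_only.sum()),
    )
    table.n_skipped = n_skipped
    return table


def write_junctions(table: JunctionTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bait={table.bait_chrom}:{table.bait_pos}:{table.bait_strand}\n")
        buf = _pyio.StringIO()
        out = table.records[JunctionTable.RECORD_COLUMNS].copy()
        bait_only = pd.DataFrame(
            {
                "prey_chrom": ["*"] * table.n_bait_only,
                "prey_pos": 0,
                "prey_strand": ".",
                "bait_end_on_read": 0,
                "prey_start_on_read": 0,
                "seq": "",
            }
        )
        pd.concat([out, bait_only], ignore_index=True).to_csv(buf, sep="\t", index=False)
        fh.write(buf.getvalue())


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
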