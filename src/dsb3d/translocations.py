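"""HTGTS translocation analytics.

Junction structure is read off the two alignment coordinates on the read:
with ``gap = prey_start_on_read - bait_end_on_read``,

* ``gap == 1``  — blunt ligation (bait and prey alignments are adjacent);
* ``gap <= 0``  — microhomology of ``1 - gap`` bases (the overlap aligned to
  both bait and prey);
* ``gap >= 2``  — an untemplated insertion of the intervening read bases.

Frequencies are binned in 100-kb windows genome-wide and normalized two
ways: per bait-only read (the HTGTS library-size control) and per 1,000
total events (junctions + bait-only reads).  Differential comparisons keep
bins with at least 10 combined events and test the genome-wide shift with a
paired Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import BinTable, JunctionTable, SiteCatalog, ValidationError

__all__ = [
    "JunctionClass",
    "JunctionClassCounts",
    "FrequencyTable",
    "DifferentialTable",
    "classify_junction",
    "classify_junctions",
    "junction_class_summary",
    "classify_prey_distance",
    "frequency_table",
    "differential_translocation",
    "map_insertion",
    "annotate_prey",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class JunctionClass:
    kind: str  # "blunt" | "mh" | "insertion"
    mh_length: int = 0
    insertion_seq: str = ""


@dataclass
class JunctionClassCounts:
    """Counts and fractions for {blunt, MH 1–5, MH ≥ 6, insertion}.

    The boundary between the two MH buckets is ``mh_split`` (default 6:
    lengths >= 6 go to the upper bucket so the buckets partition).
    Fractions are NaN when no junctions were classified.
    """

    counts: dict[str, int]
    fractions: dict[str, float]
    mh_split: int = 6

    @property
    def n_classified(self) -> int:
        return sum(self.counts.values())


def classify_junction(
    bait_end_on_read: int,
    prey_start_on_read: int,
    seq: str = "",
) -> JunctionClass:
    """Classify one junction from its read-alignment coordinates.

    Coordinates are 1-based; ``bait_end_on_read`` is the last read base
    aligned to the bait, ``prey_start_on_read`` the first aligned to the
    prey.
    """
    if bait_end_on_read < 1:
        raise ValidationError("bait_end_on_read must be >= 1")
    if seq and (prey_start_on_read > len(seq) or bait_end_on_read > len(seq)):
        raise ValidationError("alignment coordinates beyond read end")
    gap = prey_start_on_read - bait_end_on_read
    if gap == 1:
        return JunctionClass("blunt")
    if gap <= 0:
        return JunctionClass("mh", mh_length=1 - gap)
    ins = seq[bait_end_on_read : prey_start_on_read - 1] if seq else ""
    if seq and len(ins) != gap - 1:
        raise ValidationError("malformed record: insertion extends past read end")
    return JunctionClass("insertion", insertion_seq=ins)


def classify_junctions(table: JunctionTable) -> pd.DataFrame:
    """Classify every record; returns records with kind/mh_length/insertion_seq."""
    out = table.records.copy()
    kinds, mhs, inss = [], [], []
    for be, ps, seq in out[["bait_end_on_read", "prey_start_on_read", "seq"]].itertuples(
        index=False
    ):
        c = classify_junction(int(be), int(ps), str(seq))
        kinds.append(c.kind)
        mhs.append(c.mh_length)
        inss.append(c.insertion_seq)
    out["kind"] = kinds
    out["mh_length"] = mhs
    out["insertion_seq"] = inss
    return out


def junction_class_summary(classified: pd.DataFrame, mh_split: int = 6) -> JunctionClassCounts:
    """Counts/fractions of blunt, short-MH, long-MH and insertion junctions."""
    kinds = classified["kind"]
    mh = classified["mh_length"]
    counts = {
        "blunt": int((kinds == "blunt").sum()),
        "mh_1_5": int(((kinds == "mh") & (mh < mh_split)).sum()),
        "mh_ge_6": int(((kinds == "mh") & (mh >= mh_split)).sum()),
        "insertion": int((kinds == "insertion").sum()),
    }
    total = sum(counts.values())
    fractions = {k: (v / total if total else np.nan) for k, v in counts.items()}
    return JunctionClassCounts(counts=counts, fractions=fractions, mh_split=mh_split)


def classify_prey_distance(
    table: JunctionTable,
    asisi: SiteCatalog,
    proximal_max: int = 500,
    distal_min: int = 10_000,
) -> pd.DataFrame:
    """Distance of each prey to the nearest cut-site motif, in three classes.

    proximal (< 500 bp), distal (> 10 kb), intermediate otherwise
    (intermediate is reported but excluded from the two-class summary).
    Distances are motif-center to prey junction base; preys on chromosomes
    without any motif get distance NaN and class "undefined".
    """
    if len(asisi) == 0:
        raise ValidationError("empty motif catalog")
    out = table.records.copy()
    dist = np.full(len(out), np.nan)
    by_chrom = {c: np.sort(g["position"].to_numpy()) for c, g in asisi.df.groupby("chrom")}
    for idx, (chrom, pos) in enumerate(out[["prey_chrom", "prey_pos"]].itertuples(index=False)):
        sites = by_chrom.get(str(chrom))
        if sites is None or len(sites) == 0:
            continue
        k = np.searchsorted(sites, pos)
        best = np.inf
        if k > 0:
            best = min(best, abs(pos - sites[k - 1]))
        if k < len(sites):
            best = min(best, abs(sites[k] - pos))
        dist[idx] = best
    cls = np.where(
        np.isnan(dist),
        "undefined",
        np.where(dist < proximal_max, "proximal", np.where(dist > distal_min, "distal", "intermediate")),
    )
    out["asisi_distance"] = dist
    out["prey_class"] = cls
    return out


@dataclass
class FrequencyTable:
    """100-kb-binned junction counts with both normalizations."""

    table: pd.DataFrame  # chrom, start, end, raw, per_bait, per_1000
    bait_chrom: str
    bait_only_count: int
    total_events: int
    condition: str = ""

    @property
    def per_bait_defined(self) -> bool:
        return self.bait_only_count > 0


def frequency_table(
    junctions: JunctionTable,
    bins: BinTable | None = None,
    chromsizes: dict[str, int] | None = None,
    bin_size: int = 100_000,
    condition: str = "",
) -> FrequencyTable:
    """Bin junctions genome-wide and normalize.

    ``per_bait`` = raw / bait-only count (NaN-flagged when no bait-only
    reads); ``per_1000`` = 1000 × raw / total events.  Supply either a
    genome-wide :class:`BinTable` or chromosome sizes.
    """
    if bins is None:
        if chromsizes is None:
            raise ValidationError("need bins or chromsizes")
        bins = BinTable.from_chromsizes(chromsizes, bin_size)
    raw = np.zeros(len(bins), dtype=int)
    for chrom, pos in junctions.records[["prey_chrom", "prey_pos"]].itertuples(index=False):
        try:
            raw[bins.bin_id(str(chrom), int(pos))] += 1
        except (KeyError, ValidationError):
            continue
    total = junctions.total_events
    bait_only = junctions.n_bait_only
    df = bins.df.copy()
    df["raw"] = raw
    df["per_bait"] = raw / bait_only if bait_only else np.nan
    df["per_1000"] = 1000.0 * raw / total if total else np.nan
    return FrequencyTable(
        table=df,
        bait_chrom=junctions.bait_chrom,
        bait_only_count=bait_only,
        total_events=total,
        condition=condition,
    )


@dataclass
class DifferentialTable:
    """Per-bin log2 fold change between two conditions plus a global test."""

    table: pd.DataFrame  # chrom,start,end,raw_a,raw_b,norm_a,norm_b,log2fc
    wilcoxon_p: float
    min_events: int
    intra_log2fc: float
    inter_log2fc: float


def differential_translocation(
    table_a: FrequencyTable,
    table_b: FrequencyTable,
    min_events: int = 10,
    scale: str = "per_bait",
    pseudocount: float = 0.5,
    paired: bool = True,
) -> DifferentialTable:
    """Compare normalized translocation frequencies between two conditions.

    Bins with fewer than ``min_events`` combined raw events are dropped.
    log2 fold changes add ``pseudocount`` raw events to both conditions
    before normalizing (display only); the Wilcoxon signed-rank test uses the
    raw normalized differences across retained bins.  Intra/inter subtotals
    are log2 ratios of summed normalized frequencies relative to the bait
    chromosome.
    """
    a, b = table_a.table, table_b.table
    if not (a[["chrom", "start", "end"]].equals(b[["chrom", "start", "end"]])):
        raise ValidationError("frequency tables on different bin grids")
    if scale == "per_bait" and not (table_a.per_bait_defined and table_b.per_bait_defined):
        scale = "per_1000"
    denom_a = table_a.bait_only_count if scale == "per_bait" else table_a.total_events / 1000.0
    denom_b = table_b.bait_only_count if scale == "per_bait" else table_b.total_events / 1000.0

    combined = a["raw"] + b["raw"]
    keep = combined >= min_events
    if not keep.any():
        raise ValidationError("no bins pass the event filter")
    sub = a.loc[keep, ["chrom", "start", "end"]].copy()
    sub["raw_a"] = a.loc[keep, "raw"].to_numpy()
    sub["raw_b"] = b.loc[keep, "raw"].to_numpy()
    sub["norm_a"] = sub["raw_a"] / denom_a
    sub["norm_b"] = sub["raw_b"] / denom_b
    sub["log2fc"] = np.log2(
        ((sub["raw_a"] + pseudocount) / denom_a) / ((sub["raw_b"] + pseudocount) / denom_b)
    )

    diffs = (sub["norm_a"] - sub["norm_b"]).to_numpy()
    if np.allclose(diffs, 0):
        p = 1.0
    elif paired:
        p = float(stats.wilcoxon(sub["norm_a"], sub["norm_b"], zero_method="wilcox").pvalue)
    else:
        p = float(stats.mannwhitneyu(sub["norm_a"], sub["norm_b"]).pvalue)

    def subtotal(mask: pd.Series) -> float:
        if not mask.any():
            return np.nan
        sa = sub.loc[mask, "raw_a"].sum() + pseudocount
        sb = sub.loc[mask, "raw_b"].sum() + pseudocount
        if sa == 0 or sb == 0:
            return np.nan
        return float(np.log2((sa / denom_a) / (sb / denom_b)))

    intra = sub["chrom"] == table_a.bait_chrom
    return DifferentialTable(
        table=sub.reset_index(drop=True),
        wilcoxon_p=p,
        min_events=min_events,
        intra_log2fc=subtotal(intra),
        inter_log2fc=subtotal(~intra),
    )


@dataclass
class InsertionPlacement:
    matched: bool
    source: str = ""  # "prey" | "bait"
    strand: str = ""  # "+" sense, "-" antiparallel
    offset: int = -1  # 0-based offset within the searched flank


def map_insertion(
    insertion_seq: str,
    prey_flank: str,
    bait_flank: str = "",
    min_len: int = 20,
    max_len: int = 30,
) -> InsertionPlacement:
    """Locate an insert in the prey (then bait) flanking reference.

    Exact-match search of the insert and its reverse complement; the prey
    flank is searched first, sense strand before antiparallel.  Insert length
    must be 20–30 nt (the range the junction caller reports).
    """
    L = len(insertion_seq)
    if not min_len <= L <= max_len:
        raise ValidationError(f"insert length {L} outside [{min_len}, {max_len}]")
    rc = reverse_complement(insertion_seq)
    for source, flank in (("prey", prey_flank), ("bait", bait_flank)):
        if not flank:
            continue
        if len(flank) < L:
            raise ValidationError(f"{source} flank shorter than insert")
        k = flank.find(insertion_seq)
        if k >= 0:
            return InsertionPlacement(True, source, "+", k)
        k = flank.find(rc)
        if k >= 0:
            return InsertionPlacement(True, source, "-", k)
    return InsertionPlacement(False)


def annotate_prey(
    table: JunctionTable,
    genes: pd.DataFrame,
    promoter_margin: int = 3_000,
) -> pd.DataFrame:
    """Assign each prey to Promoter, Gene Body or Intergenic.

    ``genes`` columns: chrom, start, end, strand (TSS = start on +, end on −).
    Promoter = TSS ± promoter_margin and takes precedence over Gene Body.
    """
    out = table.records.copy()
    if genes is None or len(genes) == 0:
        import warnings

        warnings.warn("empty gene model; all preys Intergenic")
        out["region"] = "Intergenic"
        return out
    g = genes.copy()
    g["tss"] = np.where(g["strand"] == "-", g["end"], g["start"])
    regions = []
    by_chrom = {c: sub for c, sub in g.groupby("chrom")}
    for chrom, pos in out[["prey_chrom", "prey_pos"]].itertuples(index=False):
        sub = by_chrom.get(str(chrom))
        region = "Intergenic"
        if sub is not None:
            if (np.abs(sub["tss"].to_numpy() - pos) <= promoter_margin).any():
                region = "Promoter"
            elif ((sub["start"].to_numpy() <= pos) & (pos < sub["end"].to_numpy())).any():
                region = "Gene Body"
        regions.append(region)
    out["region"] = regions
    return out
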