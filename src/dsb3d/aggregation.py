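"""Aggregate (pileup) analysis of observed/expected Hi-C signal.

Pairwise pileups average O/E windows centered on all cis pairs of a site
catalog (double-strand-break clustering: 25-kb bins, ±1-Mb flank); the
cluster enrichment score is the mean O/E over the central 5×5-bin block
divided by the mean over the surrounding ring out to 1 Mb.  A constrained
resampling null re-draws matched control loci (distance-excluded around cut
motifs, per-chromosome counts and undamaged-control compartment identity
preserved) and recomputes the score, by default 100 times.  Oriented CTCF
pileups, convergent-loop aggregation and anchored differential tracks follow
the same snipping machinery.

Enrichment ratios are computed on linear O/E means; log2 is used for display
matrices only (``log_ratio=True`` switches the score to log space for
sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ScalarTrack, SiteCatalog, ValidationError
from .compartments import CompartmentResult, UNASSIGNED
from .matrix import OEMaps

__all__ = [
    "PileupResult",
    "ResampleNull",
    "cis_pairs",
    "pairwise_pileup",
    "cluster_enrichment_score",
    "matched_control_null",
    "ctcf_pileup",
    "convergent_loop_score",
    "anchored_differential",
]


@dataclass
class PileupResult:
    """Aggregate O/E sub-matrix around a set of snippets.

    ``linear_mean`` is the per-cell mean of O/E over snippets (missing cells
    skipped per cell); ``log2_mean`` is the per-cell mean of log2(O/E).  The
    matrix is square with odd dimension ``2*flank/resolution + 1``.
    """

    linear_mean: np.ndarray
    log2_mean: np.ndarray
    resolution: int
    flank: int
    n_used: int
    n_dropped: int

    @property
    def radius(self) -> int:
        return self.flank // self.resolution


@dataclass
class ResampleNull:
    """Constrained-resampling null distribution of an enrichment score."""

    scores: np.ndarray
    resampled_sites: list[SiteCatalog]
    seed: int

    @property
    def n_resamples(self) -> int:
        return len(self.scores)

    @property
    def mean(self) -> float:
        return float(np.mean(self.scores))

    @property
    def sd(self) -> float:
        return float(np.std(self.scores, ddof=1))


# ---------------------------------------------------------------------------
# Pair enumeration and snipping
# ---------------------------------------------------------------------------


def cis_pairs(sites: SiteCatalog) -> pd.DataFrame:
    """All unordered pairs of distinct sites on the same chromosome.

    Each pair is emitted once with the lower coordinate first.  97 sites
    distributed like the top cut-site table give 304 cis pairs.
    """
    rows = []
    for chrom, sub in sites.df.groupby("chrom", sort=False):
        pos = np.sort(sub["position"].to_numpy())
        for a in range(len(pos)):
            for b in range(a + 1, len(pos)):
                rows.append((chrom, int(pos[a]), int(pos[b])))
    return pd.DataFrame(rows, columns=["chrom", "pos1", "pos2"])


def _snip(mat: np.ndarray, ci: int, cj: int, r: int) -> np.ndarray | None:
    n = mat.shape[0]
    if ci - r < 0 or cj - r < 0 or ci + r >= n or cj + r >= n:
        return None
    return mat[ci - r : ci + r + 1, cj - r : cj + r + 1]


def _aggregate(snippets: list[np.ndarray], resolution: int, flank: int,
               n_dropped: int) -> PileupResult:
    if not snippets:
        raise ValidationError("zero usable snippets")
    stack = np.stack(snippets)
    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message="Mean of empty slice")
        linear = np.nanmean(stack, axis=0)
        logstack = np.where(stack > 0, np.log2(np.where(stack > 0, stack, 1.0)), np.nan)
        log2m = np.nanmean(logstack, axis=0)
    return PileupResult(
        linear_mean=linear,
        log2_mean=log2m,
        resolution=resolution,
        flank=flank,
        n_used=len(snippets),
        n_dropped=n_dropped,
    )


def pairwise_pileup(
    oe: OEMaps,
    pairs: pd.DataFrame,
    resolution: int = 25_000,
    flank: int = 1_000_000,
) -> PileupResult:
    """Average O/E windows centered on cis site pairs.

    Each pair contributes the window centered at (bin(pos1), bin(pos2)).
    Pairs closer than ``2*flank`` (window would cross the diagonal) or within
    ``flank`` of a chromosome end are dropped and counted; windows whose
    center cell is missing are dropped too.  Missing cells elsewhere are
    skipped per cell.
    """
    bins = oe.bins
    if bins.bin_size != resolution:
        raise ValidationError("O/E maps are not at the requested resolution")
    r = flank // resolution
    snippets, n_dropped = [], 0
    for chrom, pos1, pos2 in pairs[["chrom", "pos1", "pos2"]].itertuples(index=False):
        if chrom not in oe.data:
            n_dropped += 1
            continue
        sl = bins.chrom_slice(chrom)
        ci = bins.bin_id(chrom, pos1) - sl.start
        cj = bins.bin_id(chrom, pos2) - sl.start
        if abs(cj - ci) * resolution <= 2 * flank:
            n_dropped += 1
            continue
        snip = _snip(oe[chrom], ci, cj, r)
        if snip is None or not np.isfinite(snip[r, r]):
            n_dropped += 1
            continue
        snippets.append(snip)
    return _aggregate(snippets, resolution, flank, n_dropped)


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------


def _block_ring_score(
    pileup: PileupResult,
    center_bins: int,
    outer_radius: int,
    inner_radius_bins: int | None = None,
    log_ratio: bool = False,
) -> float:
    """Mean over the central block divided by mean over the surrounding ring.

    Ring membership is by cell-center Chebyshev distance from the pileup
    center: strictly beyond the central block, and at most
    ``outer_radius/resolution`` bins (ties at the radius included).
    """
    mat = pileup.log2_mean if log_ratio else pileup.linear_mean
    r = pileup.radius
    half = center_bins // 2
    inner = half if inner_radius_bins is None else inner_radius_bins
    outer = outer_radius // pileup.resolution
    if outer > r:
        raise ValidationError("outer radius exceeds pileup flank")
    idx = np.arange(-r, r + 1)
    cheb = np.maximum(np.abs(idx)[:, None], np.abs(idx)[None, :])
    center = cheb <= half
    ring = (cheb > inner) & (cheb <= outer)
    c = mat[center]
    g = mat[ring]
    if not np.isfinite(g).any():
        raise ValidationError("empty ring")
    num = np.nanmean(c)
    den = np.nanmean(g)
    return float(num - den) if log_ratio else float(num / den)


def cluster_enrichment_score(
    pileup: PileupResult,
    center_bins: int = 5,
    outer_radius: int = 1_000_000,
    log_ratio: bool = False,
) -> float:
    """DSB cluster enrichment: central 5×5-bin mean O/E over the 125 kb–1 Mb ring."""
    return _block_ring_score(pileup, center_bins, outer_radius, log_ratio=log_ratio)


# ---------------------------------------------------------------------------
# Constrained resampling null
# ---------------------------------------------------------------------------


def matched_control_null(
    sites: SiteCatalog,
    all_motifs: SiteCatalog,
    control_compartments: CompartmentResult,
    oe: OEMaps,
    n_resamples: int = 100,
    seed: int = 0,
    resolution: int = 25_000,
    flank: int = 1_000_000,
    min_distance: int = 125_000,
) -> ResampleNull:
    """Cluster-score null from matched random control loci.

    Each resample draws ``len(sites)`` loci under three constraints: (1) every
    locus is at least ``min_distance`` from every motif in ``all_motifs``;
    (2) per-chromosome counts equal those of ``sites``; (3) each locus'
    compartment label (undamaged-control EV1) matches the site it replaces.
    The enrichment score of each resample is computed through
    cis_pairs → pairwise_pileup → cluster_enrichment_score.  Resamples use
    independent RNG streams spawned from ``seed``.
    """
    bins = oe.bins
    labels = control_compartments.labels
    comp_bins = control_compartments.ev1.bins
    ratio = comp_bins.bin_size // bins.bin_size if comp_bins.bin_size >= bins.bin_size else 1

    def label_at(chrom: str, pos: int) -> str:
        return str(labels[comp_bins.bin_id(chrom, pos)])

    # candidate bins per (chrom, label): centers >= min_distance from any motif
    candidates: dict[tuple[str, str], np.ndarray] = {}
    for chrom in bins.chromosomes:
        sl = bins.chrom_slice(chrom)
        centers = (
            bins.df.loc[sl, "start"].to_numpy() + bins.df.loc[sl, "end"].to_numpy()
        ) // 2
        motif_pos = np.sort(all_motifs.positions(chrom))
        if len(motif_pos):
            k = np.searchsorted(motif_pos, centers)
            left = np.where(k > 0, centers - motif_pos[np.maximum(k - 1, 0)], np.inf)
            right = np.where(
                k < len(motif_pos), motif_pos[np.minimum(k, len(motif_pos) - 1)] - centers, np.inf
            )
            dist = np.minimum(np.abs(left), np.abs(right))
        else:
            dist = np.full(len(centers), np.inf)
        ok = dist >= min_distance
        for label in ("A", "B", UNASSIGNED):
            in_label = np.array([label_at(chrom, int(p)) == label for p in centers])
            candidates[(chrom, label)] = centers[ok & in_label]

    # strata required by the true sites
    site_strata = [
        (str(c), label_at(str(c), int(p)))
        for c, p in sites.df[["chrom", "position"]].itertuples(index=False)
    ]
    needed: dict[tuple[str, str], int] = {}
    for key in site_strata:
        needed[key] = needed.get(key, 0) + 1
    for key, cnt in needed.items():
        if len(candidates.get(key, ())) < cnt:
            raise ValidationError(f"too few candidate loci in stratum {key}")

    streams = np.random.SeedSequence(seed).spawn(n_resamples)
    scores = np.empty(n_resamples)
    resampled: list[SiteCatalog] = []
    for ri in range(n_resamples):
        rng = np.random.default_rng(streams[ri])
        rows = []
        for key, cnt in needed.items():
            pool_pos = candidates[key]
            chosen = rng.choice(pool_pos, size=cnt, replace=False)
            rows += [(key[0], int(p)) for p in chosen]
        cat = SiteCatalog(pd.DataFrame(rows, columns=["chrom", "position"]))
        pileup = pairwise_pileup(oe, cis_pairs(cat), resolution=resolution, flank=flank)
        scores[ri] = cluster_enrichment_score(pileup, outer_radius=flank)
        resampled.append(cat)
    return ResampleNull(scores=scores, resampled_sites=resampled, seed=seed)


# ---------------------------------------------------------------------------
# CTCF-oriented pileups and convergent loops
# ---------------------------------------------------------------------------


def ctcf_pileup(
    oe: OEMaps,
    anchors: SiteCatalog,
    resolution: int = 5_000,
    flank: int = 100_000,
) -> tuple[PileupResult, dict[str, float]]:
    """On-diagonal pileup at oriented CTCF anchors.

    Snippets of minus-strand anchors are rotated 180° so all motifs point
    rightward (downstream = increasing coordinate in the aggregate).  Returns
    the pileup and "flame" line scores: mean O/E along the row/column
    emanating from the center toward the motif-downstream and -upstream
    sides, minus the off-line background mean.
    """
    bins = oe.bins
    if bins.bin_size != resolution:
        raise ValidationError("O/E maps are not at the requested resolution")
    r = flank // resolution
    snippets, n_dropped = [], 0
    for chrom, pos, strand in anchors.df[["chrom", "position", "strand"]].itertuples(index=False):
        if chrom not in oe.data:
            n_dropped += 1
            continue
        sl = bins.chrom_slice(chrom)
        ci = bins.bin_id(str(chrom), int(pos)) - sl.start
        snip = _snip(oe[str(chrom)], ci, ci, r)
        if snip is None:
            n_dropped += 1
            continue
        if strand == "-":
            snip = snip[::-1, ::-1]
        snippets.append(snip)
    pileup = _aggregate(snippets, resolution, flank, n_dropped)
    m = pileup.linear_mean
    down = np.nanmean(np.concatenate([m[r, r + 1 :], m[r + 1 :, r]]))
    up = np.nanmean(np.concatenate([m[r, :r], m[:r, r]]))
    mask = np.ones_like(m, dtype=bool)
    mask[r, :] = False
    mask[:, r] = False
    background = np.nanmean(m[mask])
    lines = {
        "downstream": float(down - background),
        "upstream": float(up - background),
        "background": float(background),
    }
    return pileup, lines


def convergent_pairs(
    anchors: SiteCatalog, min_sep: int = 25_000, max_sep: int = 1_000_000
) -> pd.DataFrame:
    """Cis anchor pairs in convergent (+ upstream, − downstream) orientation."""
    rows = []
    for chrom, sub in anchors.df.groupby("chrom", sort=False):
        sub = sub.sort_values("position")
        pos = sub["position"].to_numpy()
        strand = sub["strand"].to_numpy()
        for a in range(len(pos)):
            if strand[a] != "+":
                continue
            for b in range(a + 1, len(pos)):
                sep = pos[b] - pos[a]
                if sep > max_sep:
                    break
                if strand[b] == "-" and min_sep <= sep <= max_sep:
                    rows.append((chrom, int(pos[a]), int(pos[b])))
    return pd.DataFrame(rows, columns=["chrom", "pos1", "pos2"])


def convergent_loop_score(
    oe: OEMaps,
    anchors: SiteCatalog,
    min_sep: int = 25_000,
    max_sep: int = 1_000_000,
    resolution: int = 25_000,
    flank: int = 100_000,
    log_ratio: bool = False,
) -> tuple[PileupResult, float, int]:
    """Aggregate convergent CTCF pairs and score the central loop dot.

    The loop score is the central 5×5-bin mean O/E over the mean of the
    remaining cells within a 100-kb Chebyshev radius (the 25–100 kb ring).
    Pairs at separations within ``2*flank`` of each other are still snipped
    (loops sit near the diagonal by construction); only windows leaving the
    chromosome or with a missing center are dropped.
    """
    pairs = convergent_pairs(anchors, min_sep=min_sep, max_sep=max_sep)
    if len(pairs) == 0:
        raise ValidationError("zero qualifying convergent pairs")
    bins = oe.bins
    if bins.bin_size != resolution:
        raise ValidationError("O/E maps are not at the requested resolution")
    r = flank // resolution
    snippets, n_dropped = [], 0
    for chrom, pos1, pos2 in pairs.itertuples(index=False):
        sl = bins.chrom_slice(chrom)
        ci = bins.bin_id(chrom, pos1) - sl.start
        cj = bins.bin_id(chrom, pos2) - sl.start
        snip = _snip(oe[chrom], ci, cj, r)
        if snip is None or not np.isfinite(snip[r, r]):
            n_dropped += 1
            continue
        snippets.append(snip)
    pileup = _aggregate(snippets, resolution, flank, n_dropped)
    score = _block_ring_score(pileup, 5, flank, log_ratio=log_ratio)
    return pileup, score, len(pairs)


# ---------------------------------------------------------------------------
# Anchored differential interactions
# ---------------------------------------------------------------------------


def anchored_differential(
    oe_damage: OEMaps,
    oe_control: OEMaps,
    anchor: tuple[str, int],
    mask_radius_bins: int = 0,
) -> ScalarTrack:
    """Per-bin cis O/E difference (damage − control) anchored at one locus.

    Bins within ``mask_radius_bins`` of the anchor can be masked (the local
    diagonal neighborhood is dominated by distance decay, not specific
    interactions).  Swapping conditions flips the sign.
    """
    chrom, pos = anchor
    bins = oe_damage.bins
    if bins != oe_control.bins:
        raise ValidationError("conditions are on different bin tables")
    sl = bins.chrom_slice(chrom)
    ai = bins.bin_id(chrom, pos) - sl.start
    row_d = oe_damage[chrom][ai]
    row_c = oe_control[chrom][ai]
    if not (np.isfinite(row_d).any() and np.isfinite(row_c).any()):
        raise ValidationError("anchor bin is filtered in one of the conditions")
    diff = row_d - row_c
    if mask_radius_bins > 0:
        lo = max(ai - mask_radius_bins, 0)
        diff[lo : ai + mask_radius_bins + 1] = np.nan
    values = np.full(len(bins), np.nan)
    values[sl] = diff
    return ScalarTrack(bins, values, label=f"diff_{chrom}:{pos}")
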