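"""Synthetic data with planted, recoverable structure.

The Hi-C generator builds a per-chromosome contact intensity

    p_ij  ∝  s^(−α) · (1 + κ·c_i·c_j) · loop(i,j; λ) · cluster(i,j; β)

where s = |i−j| is the bin separation, c is a ±1 plaid compartment profile
(κ = compartment contrast), ``loop`` plants focal boosts at convergent
CTCF-anchor pairs, and ``cluster`` (damage condition only) plants boosts at
cut-site pairs.  Counts are Poisson with genome-wide expected total N.  The
damage condition additionally switches the compartment sign of a configured
flip set (B bins becoming A), which is what the flip-detection pathway
recovers.

Focal boosts are flat (top-hat) over a square of configurable half-width
(default 2 bins, i.e. the 5×5 block the enrichment scores measure) so the
planted boost equals the score a perfect estimator reports; a Gaussian-edged
shape is available via ``focal_shape``.

The junction generator writes reads as bait prefix + (microhomology | nothing
| insertion) + prey suffix with alignment coordinates set accordingly, and
locally edits the reference flanks so that the maximal-overlap class of each
read is exactly the requested one.  Truth labels are returned for round-trip
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import BinTable, ContactMatrix, JunctionTable, ScalarTrack, SiteCatalog, ValidationError
from .translocations import reverse_complement

__all__ = [
    "SimulationConfig",
    "JunctionSimConfig",
    "simulate_contact_map",
    "simulate_replicates",
    "simulate_junction_library",
    "make_site_catalog",
    "make_gene_density",
    "mouse_like_cut_sites",
    "MOUSE_LIKE_CHROM_COUNTS",
]

# Synthetic stand-in for the per-chromosome distribution of the 97 most
# frequently cut AsiSI sites: 19 autosome counts chosen so that the number of
# same-chromosome pairs is exactly 304 (the published pairwise-cis count).
MOUSE_LIKE_CHROM_COUNTS = (12, 11, 11, 8, 8, 7, 5, 5, 4, 4, 4, 3, 3, 3, 2, 2, 2, 2, 1)

DEFAULT_CHROMSIZES = {f"chr{i}": 50_000_000 for i in range(1, 5)}


@dataclass
class SimulationConfig:
    """Parameters of the planted Hi-C structure.

    alpha       power-law distance-decay exponent (P(s) ∝ s^−α)
    kappa       compartment contrast; 0 disables the plaid
    block_bins  compartment block width, in bins (alternating A/B blocks)
    flip_bins   global bin ids whose compartment sign flips in the damage
                condition (drawn from B blocks)
    cut_sites   catalog of break sites; pairs get a ×beta boost under damage
    beta        cluster boost at cut-site pairs (>= 1)
    ctcf_anchors oriented anchors; convergent in-range pairs get ×lam
    lam         loop boost at convergent anchor pairs (>= 1)
    focal_halfwidth_bins  half-width of the flat focal boost square
    focal_shape "tophat" (default) or "gaussian" (sigma = half-width bins)
    n_pairs     expected genome-wide total count N
    """

    chromsizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROMSIZES))
    bin_size: int = 250_000
    alpha: float = 1.0
    kappa: float = 0.0
    block_bins: int = 10
    flip_bins: tuple[int, ...] = ()
    cut_sites: SiteCatalog | None = None
    beta: float = 1.0
    ctcf_anchors: SiteCatalog | None = None
    lam: float = 1.0
    loop_min_sep: int = 25_000
    loop_max_sep: int = 1_000_000
    focal_halfwidth_bins: int = 2
    focal_shape: str = "tophat"
    n_pairs: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        if self.beta < 1 or self.lam < 1:
            raise ValidationError("boosts must be >= 1")
        if self.n_pairs <= 0:
            raise ValidationError("n_pairs must be positive")

    def bins(self) -> BinTable:
        return BinTable.from_chromsizes(self.chromsizes, self.bin_size)


def compartment_profile(cfg: SimulationConfig, condition: str) -> np.ndarray:
    """±1 plaid profile per bin; damage flips the configured flip set."""
    bins = cfg.bins()
    c = np.empty(len(bins))
    for chrom in bins.chromosomes:
        sl = bins.chrom_slice(chrom)
        idx = np.arange(sl.stop - sl.start)
        c[sl] = np.where((idx // cfg.block_bins) % 2 == 0, 1.0, -1.0)
    if condition == "damage" and len(cfg.flip_bins):
        flips = np.asarray(cfg.flip_bins, dtype=int)
        c[flips] = -c[flips]
    return c


def _focal_boost(n: int, centers: Sequence[tuple[int, int]], boost: float,
                 halfwidth: int, shape: str) -> np.ndarray:
    """Multiplicative boost field over an n×n cis matrix (symmetric)."""
    f = np.ones((n, n))
    if boost == 1.0 or not centers:
        return f
    for ci, cj in centers:
        if shape == "tophat":
            i0, i1 = max(ci - halfwidth, 0), min(ci + halfwidth + 1, n)
            j0, j1 = max(cj - halfwidth, 0), min(cj + halfwidth + 1, n)
            f[i0:i1, j0:j1] = np.maximum(f[i0:i1, j0:j1], boost)
            f[j0:j1, i0:i1] = np.maximum(f[j0:j1, i0:i1], boost)
        elif shape == "gaussian":
            w = 4 * halfwidth
            ii = np.arange(max(ci - w, 0), min(ci + w + 1, n))
            jj = np.arange(max(cj - w, 0), min(cj + w + 1, n))
            d2 = ((ii[:, None] - ci) ** 2 + (jj[None, :] - cj) ** 2) / (2.0 * halfwidth**2)
            bump = 1.0 + (boost - 1.0) * np.exp(-d2)
            f[np.ix_(ii, jj)] = np.maximum(f[np.ix_(ii, jj)], bump)
            f[np.ix_(jj, ii)] = np.maximum(f[np.ix_(jj, ii)], bump.T)
        else:
            raise ValidationError(f"unknown focal shape {shape!r}")
    return f


def _intensities(cfg: SimulationConfig, condition: str) -> dict[str, np.ndarray]:
    from .aggregation import convergent_pairs

    bins = cfg.bins()
    c = compartment_profile(cfg, condition)
    out: dict[str, np.ndarray] = {}
    for chrom in bins.chromosomes:
        sl = bins.chrom_slice(chrom)
        n = sl.stop - sl.start
        idx = np.arange(n)
        s = np.abs(idx[:, None] - idx[None, :]).astype(float)
        decay = np.maximum(s, 1.0) ** (-cfg.alpha)
        cc = c[sl]
        plaid = 1.0 + cfg.kappa * np.outer(cc, cc)
        intensity = decay * plaid
        if cfg.ctcf_anchors is not None and cfg.lam > 1:
            pairs = convergent_pairs(cfg.ctcf_anchors, cfg.loop_min_sep, cfg.loop_max_sep)
            centers = [
                (bins.bin_id(chrom, p1) - sl.start, bins.bin_id(chrom, p2) - sl.start)
                for ch, p1, p2 in pairs.itertuples(index=False)
                if ch == chrom
            ]
            intensity *= _focal_boost(
                n, centers, cfg.lam, cfg.focal_halfwidth_bins, cfg.focal_shape
            )
        if condition == "damage" and cfg.cut_sites is not None and cfg.beta > 1:
            from .aggregation import cis_pairs

            pairs = cis_pairs(cfg.cut_sites)
            centers = [
                (bins.bin_id(chrom, p1) - sl.start, bins.bin_id(chrom, p2) - sl.start)
                for ch, p1, p2 in pairs.itertuples(index=False)
                if ch == chrom
            ]
            intensity *= _focal_boost(
                n, centers, cfg.beta, cfg.focal_halfwidth_bins, cfg.focal_shape
            )
        out[chrom] = intensity
    return out


def simulate_contact_map(
    cfg: SimulationConfig,
    condition: str = "control",
    seed: int | None = None,
) -> ContactMatrix:
    """Poisson-sampled cis contact matrix with the configured planted structure.

    The genome-wide expected total count is ``cfg.n_pairs`` (upper triangle,
    diagonal included).  Reproducible per seed (default ``cfg.seed``).
    """
    if condition not in ("control", "damage"):
        raise ValidationError("condition must be 'control' or 'damage'")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    bins = cfg.bins()
    intens = _intensities(cfg, condition)
    total = sum(np.triu(m).sum() for m in intens.values())
    scale = cfg.n_pairs / total
    frames = []
    for chrom in bins.chromosomes:
        sl = bins.chrom_slice(chrom)
        n = sl.stop - sl.start
        iu, ju = np.triu_indices(n)
        lam = intens[chrom][iu, ju] * scale
        counts = rng.poisson(lam)
        nz = counts > 0
        frames.append(
            pd.DataFrame(
                {
                    "bin1_id": iu[nz] + sl.start,
                    "bin2_id": ju[nz] + sl.start,
                    "count": counts[nz],
                }
            )
        )
    pixels = pd.concat(frames, ignore_index=True)
    return ContactMatrix(bins, pixels)


def simulate_replicates(
    cfg: SimulationConfig, condition: str = "control", n_reps: int = 2
) -> list[ContactMatrix]:
    """Independent Poisson draws from the same intensity (biological replicates)."""
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    seeds = np.random.SeedSequence(cfg.seed).spawn(n_reps)
    return [
        simulate_contact_map(cfg, condition, seed=int(s.generate_state(1)[0] % (2**31)))
        for s in seeds
    ]


def choose_flip_bins(cfg: SimulationConfig, fraction: float, seed: int = 0) -> tuple[int, ...]:
    """Draw ``fraction`` of all bins, uniformly from the B blocks, to flip B→A."""
    c = compartment_profile(cfg, "control")
    b_bins = np.flatnonzero(c < 0)
    n_flip = int(round(fraction * len(c)))
    if n_flip > len(b_bins):
        raise ValidationError("not enough B bins for the requested flip fraction")
    rng = np.random.default_rng(seed)
    return tuple(int(x) for x in rng.choice(b_bins, size=n_flip, replace=False))


def make_gene_density(cfg: SimulationConfig, noise_sd: float = 0.0, seed: int = 0
                      ) -> ScalarTrack:
    """Gene-density track correlated with the control A compartment (A ≈ 1, B ≈ 0)."""
    c = compartment_profile(cfg, "control")
    vals = (c > 0).astype(float)
    if noise_sd > 0:
        vals = vals + np.random.default_rng(seed).normal(0, noise_sd, len(vals))
    return ScalarTrack(cfg.bins(), vals, label="gene_density")


# ---------------------------------------------------------------------------
# Site catalogs
# ---------------------------------------------------------------------------

ASISI_MOTIF = "GCGATCGC"


def make_site_catalog(
    genome: dict[str, str] | dict[str, int],
    mode: str = "motif_scan",
    motif: str = ASISI_MOTIF,
    positions: Sequence[tuple] | None = None,
    seed: int = 0,
) -> SiteCatalog:
    """Motif-scan a sequence dict, or plant configured sites with rank scores.

    In scan mode the motif is matched exactly on the forward strand; if the
    motif is its own reverse complement (AsiSI's is) both strands collapse to
    one site per position, otherwise reverse-strand hits are added.  Site
    position = motif start offset.  In planted mode ``positions`` are
    (chrom, position[, strand]) tuples; END-seq-like rank scores are drawn
    decreasing with jitter.
    """
    if mode == "motif_scan":
        motif = motif.upper()
        if set(motif) - set("ACGT"):
            raise ValidationError("motif must be plain ACGT")
        rows = []
        for chrom, seq in genome.items():
            if not isinstance(seq, str):
                raise ValidationError("scan mode needs sequences, not sizes")
            seq = seq.upper()
            start = seq.find(motif)
            while start >= 0:
                rows.append((chrom, start, "+", np.nan, ""))
                start = seq.find(motif, start + 1)
            if reverse_complement(motif) != motif:
                rcm = reverse_complement(motif)
                start = seq.find(rcm)
                while start >= 0:
                    rows.append((chrom, start, "-", np.nan, ""))
                    start = seq.find(rcm, start + 1)
        return SiteCatalog(pd.DataFrame(rows, columns=SiteCatalog.COLUMNS))
    if mode == "planted":
        if positions is None:
            raise ValidationError("planted mode needs positions")
        rng = np.random.default_rng(seed)
        rows = []
        n = len(positions)
        scores = np.sort(rng.gamma(2.0, 50.0, n))[::-1]  # END-seq-like rank scores
        for k, rec in enumerate(positions):
            chrom, pos = rec[0], int(rec[1])
            strand = rec[2] if len(rec) > 2 else "."
            rows.append((chrom, pos, strand, float(scores[k]), f"site_{k+1}"))
        return SiteCatalog(pd.DataFrame(rows, columns=SiteCatalog.COLUMNS))
    raise ValidationError(f"unknown mode {mode!r}")


def mouse_like_cut_sites(
    chrom_length: int = 50_000_000,
    margin: int = 2_000_000,
    min_gap: int = 2_500_000,
    seed: int = 0,
) -> SiteCatalog:
    """Plant 97 cut sites over 19 synthetic chromosomes, 304 cis pairs total.

    Per-chromosome counts follow :data:`MOUSE_LIKE_CHROM_COUNTS` (a synthetic
    stand-in for the published frequently-cut-site table, chosen so that the
    same-chromosome pair count is exactly 304).  Sites keep ``margin`` from
    chromosome ends and ``min_gap`` from each other so every pair survives
    pileup flanking constraints.
    """
    rng = np.random.default_rng(seed)
    positions = []
    for ci, count in enumerate(MOUSE_LIKE_CHROM_COUNTS, start=1):
        chrom = f"chr{ci}"
        usable = chrom_length - 2 * margin - (count - 1) * min_gap
        if usable < 0:
            raise ValidationError("chromosome too short for the site layout")
        offsets = np.sort(rng.uniform(0, usable, count))
        pos = margin + offsets + np.arange(count) * min_gap
        positions += [(chrom, int(p)) for p in pos]
    return make_site_catalog({}, mode="planted", positions=positions, seed=seed)


# ---------------------------------------------------------------------------
# Junction libraries
# ---------------------------------------------------------------------------


@dataclass
class JunctionSimConfig:
    """Mixture and reference layout for a simulated HTGTS library.

    ``class_mixture`` = (blunt, MH, insertion) weights, summing to 1.
    MH lengths are drawn from ``mh_length_weights`` (index 0 ↔ length 1);
    insertion lengths uniform over ``insertion_length_range`` (max 30 — the
    junction caller does not report longer inserts).
    """

    bait_chrom: str = "chr2"
    bait_pos: int = 13_271_321
    n_junctions: int = 1000
    n_bait_only: int = 1000
    class_mixture: tuple[float, float, float] = (0.18, 0.69, 0.13)
    mh_length_weights: tuple[float, ...] = (0.30, 0.22, 0.16, 0.10, 0.07, 0.06, 0.05, 0.04)
    insertion_length_range: tuple[int, int] = (20, 30)
    prey_chromsizes: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 50_000_000 for i in range(1, 9)}
    )
    asisi_sites: SiteCatalog | None = None  # preys are drawn near these when given
    proximal_fraction: float = 0.85
    read_half: int = 60  # bases contributed by each side of the junction
    flank: int = 500  # reference flank kept around bait/prey
    seed: int = 7

    def __post_init__(self):
        if abs(sum(self.class_mixture) - 1.0) > 1e-9:
            raise ValidationError("class mixture must sum to 1")
        if self.insertion_length_range[1] > 30:
            raise ValidationError("insertions above 30 nt are never reported")


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, n))


def _mutate(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(3)]


def simulate_junction_library(
    cfg: JunctionSimConfig,
) -> tuple[JunctionTable, pd.DataFrame, dict]:
    """Simulate a junction library with known class labels.

    Returns (table, truth, refs) where ``truth`` carries the planted class
    and MH/insertion details per record and ``refs`` maps record index to the
    local (bait_flank, prey_flank) reference sequences used, so classifier
    and insertion-mapping round-trips can be asserted.

    Read construction: ``bait_ref[..break]`` + optional insertion +
    ``prey_ref[prey_pos..]``; for MH-k the k prey bases preceding the prey
    start are forced identical to the k bait bases before the break, and the
    bases flanking the shared stretch are forced different so the maximal
    overlap is exactly k.  Insertions are copied from the antiparallel prey
    flank so the insert mapper finds them.
    """
    rng = np.random.default_rng(cfg.seed)
    half, flank = cfg.read_half, cfg.flank
    kinds = rng.choice(
        ["blunt", "mh", "insertion"], size=cfg.n_junctions, p=list(cfg.class_mixture)
    )
    mh_w = np.asarray(cfg.mh_length_weights, dtype=float)
    mh_w = mh_w / mh_w.sum()
    chroms = list(cfg.prey_chromsizes)
    rows, truth_rows, refs = [], [], {}
    for ridx, kind in enumerate(kinds):
        # choose a prey locus: near a cut site with prob proximal_fraction
        if cfg.asisi_sites is not None and rng.random() < cfg.proximal_fraction:
            site = cfg.asisi_sites.df.iloc[rng.integers(len(cfg.asisi_sites))]
            prey_chrom = str(site["chrom"])
            prey_pos = int(site["position"]) + int(rng.integers(-400, 401))
        else:
            prey_chrom = chroms[rng.integers(len(chroms))]
            prey_pos = int(rng.integers(flank, cfg.prey_chromsizes[prey_chrom] - flank))
        prey_strand = "+" if rng.random() < 0.5 else "-"

        bait_flank = list(_random_seq(rng, 2 * flank))  # break at index `flank`
        prey_flank = list(_random_seq(rng, 2 * flank))  # prey starts at index `flank`

        if kind == "mh":
            k = 1 + int(rng.choice(len(mh_w), p=mh_w))
            # share the k bases upstream of the junction
            prey_flank[flank - k : flank] = bait_flank[flank - k : flank]
            # break accidental extension of the shared stretch
            if prey_flank[flank - k - 1] == bait_flank[flank - k - 1]:
                prey_flank[flank - k - 1] = _mutate(prey_flank[flank - k - 1], rng)
            if bait_flank[flank] == prey_flank[flank]:
                bait_flank[flank] = _mutate(bait_flank[flank], rng)
            insertion = ""
        else:
            k = 0
            # no accidental homology at the junction
            if prey_flank[flank - 1] == bait_flank[flank - 1]:
                prey_flank[flank - 1] = _mutate(prey_flank[flank - 1], rng)
            if bait_flank[flank] == prey_flank[flank]:
                bait_flank[flank] = _mutate(bait_flank[flank], rng)
            if kind == "insertion":
                ilen = int(rng.integers(cfg.insertion_length_range[0],
                                        cfg.insertion_length_range[1] + 1))
                # copy from the antiparallel prey flank, downstream of the junction
                src = int(rng.integers(flank + 20, 2 * flank - ilen))
                insertion = reverse_complement("".join(prey_flank[src : src + ilen]))
                if insertion[0] == bait_flank[flank]:
                    bait_flank[flank] = _mutate(bait_flank[flank], rng)
                if insertion[-1] == prey_flank[flank - 1]:
                    prey_flank[flank - 1] = _mutate(prey_flank[flank - 1], rng)
            else:
                insertion = ""

        bait_part = "".join(bait_flank[flank - half : flank])
        # the k MH bases appear once, at the end of the bait part; the prey
        # alignment covers them because prey_flank[flank-k:flank] was forced
        # identical to the bait tail
        prey_part = "".join(prey_flank[flank : flank + half])
        read = bait_part + insertion + prey_part
        bait_end = half  # 1-based: last bait-aligned base
        prey_start = half + len(insertion) + 1 - k
        rows.append(
            (prey_chrom, prey_pos, prey_strand, bait_end, prey_start, read)
        )
        truth_rows.append((kind, k, insertion))
        refs[ridx] = ("".join(bait_flank), "".join(prey_flank))

    records = pd.DataFrame(
        rows, columns=JunctionTable.RECORD_COLUMNS
    )
    truth = pd.DataFrame(truth_rows, columns=["kind", "mh_length", "insertion_seq"])
    table = JunctionTable(
        records,
        bait_chrom=cfg.bait_chrom,
        bait_pos=cfg.bait_pos,
        n_bait_only=cfg.n_bait_only,
    )
    return table, truth, refs
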