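"""A/B compartment analysis: per-chromosome eigenvectors phased by gene
density, compartment labels, condition-to-condition flip detection, saddle
plots and saddle strength.

The compartment signal is the leading eigenvector (EV1) of the centered
observed/expected cis matrix (O/E − 1), computed per chromosome at 250-kb
resolution, scaled by the square root of its eigenvalue, and sign-phased so
that it correlates non-negatively with gene density.  Bins with EV1 > 0 are
A (open, gene dense), EV1 < 0 are B (closed); EV1 exactly 0 or missing is
unassigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ScalarTrack, ValidationError
from .matrix import OEMaps

__all__ = [
    "CompartmentResult",
    "FlipTable",
    "SaddleResult",
    "compartment_eigenvector",
    "detect_flips",
    "saddle",
    "saddle_strength",
]

MIN_VALID_BINS = 10  # below this, a chromosome's EV1 is left missing

A, B, UNASSIGNED = "A", "B", "unassigned"


@dataclass
class CompartmentResult:
    """EV1 track, A/B labels, and the per-chromosome phasing correlation."""

    ev1: ScalarTrack
    labels: np.ndarray  # {"A", "B", "unassigned"} per bin
    phasing_correlation: dict[str, float]

    def chrom_labels(self, chrom: str) -> np.ndarray:
        return self.labels[self.ev1.bins.chrom_slice(chrom)]


@dataclass
class FlipTable:
    """Per-bin compartment transition between two conditions.

    ``transition`` entries are "A->A", "B->B", "A->B", "B->A" or
    "unassigned"; ``consistent`` is True where every replicate pair agrees on
    the transition.  ``summary`` maps transition class to its fraction of
    consistently assigned bins.
    """

    transition: np.ndarray
    consistent: np.ndarray
    summary: dict[str, float]
    n_consistent: int

    def to_frame(self, bins) -> pd.DataFrame:
        df = bins.df.copy()
        df["transition"] = self.transition
        df["consistent"] = self.consistent
        return df


@dataclass
class SaddleResult:
    """Mean O/E between EV1-quantile groups, low (B) to high (A)."""

    matrix: np.ndarray
    quantile_edges: np.ndarray
    n_quantiles: int


def _labels_from_ev1(ev1: np.ndarray) -> np.ndarray:
    labels = np.full(len(ev1), UNASSIGNED, dtype=object)
    labels[np.nan_to_num(ev1, nan=0.0) > 0] = A
    labels[np.nan_to_num(ev1, nan=0.0) < 0] = B
    return labels


def compartment_eigenvector(oe: OEMaps, gene_density: ScalarTrack) -> CompartmentResult:
    """Leading eigenvector of (O/E − 1) per chromosome, phased by gene density.

    Missing rows/columns are removed before the eigendecomposition and
    re-inserted as NaN.  The eigenvector with the largest eigenvalue is kept,
    scaled by sqrt(max(eigenvalue, 0)), and its sign flipped if it correlates
    negatively with gene density on that chromosome.  Chromosomes with fewer
    than 10 valid bins get a missing EV1 and a warning.
    """
    bins = oe.bins
    ev = np.full(len(bins), np.nan)
    phasing: dict[str, float] = {}
    for chrom in bins.chromosomes:
        mat = oe[chrom]
        valid = np.isfinite(mat).any(axis=0)
        if valid.sum() < MIN_VALID_BINS:
            warnings.warn(f"{chrom}: fewer than {MIN_VALID_BINS} valid bins; EV1 missing")
            phasing[chrom] = np.nan
            continue
        sub = mat[np.ix_(valid, valid)] - 1.0
        sub = np.nan_to_num(sub, nan=0.0)  # residual NaN (ignored diagonals) -> 0
        sub = (sub + sub.T) / 2.0
        evals, evecs = np.linalg.eigh(sub)
        k = int(np.argmax(evals))
        vec = evecs[:, k] * np.sqrt(max(evals[k], 0.0))
        gd = gene_density.chrom_values(chrom)[valid]
        ok = np.isfinite(gd) & np.isfinite(vec)
        if ok.sum() >= 2 and np.std(vec[ok]) > 0 and np.std(gd[ok]) > 0:
            corr = float(np.corrcoef(vec[ok], gd[ok])[0, 1])
        else:
            corr = 0.0
        if corr < 0:
            vec = -vec
            corr = -corr
        elif corr == 0:
            warnings.warn(f"{chrom}: zero gene-density correlation; keeping arithmetic sign")
        phasing[chrom] = corr
        sl = bins.chrom_slice(chrom)
        chrom_vec = np.full(sl.stop - sl.start, np.nan)
        chrom_vec[valid] = vec
        ev[sl] = chrom_vec
    track = ScalarTrack(bins, ev, label="EV1")
    return CompartmentResult(ev1=track, labels=_labels_from_ev1(ev), phasing_correlation=phasing)


def detect_flips(
    cond1_reps: list[CompartmentResult],
    cond2_reps: list[CompartmentResult],
    cond1_pooled: CompartmentResult | None = None,
    cond2_pooled: CompartmentResult | None = None,
) -> FlipTable:
    """Per-bin compartment transitions between two conditions.

    The consistency flag is True where every (condition-1 replicate,
    condition-2 replicate) pair shows the same assigned transition.  The
    headline transition class comes from pooled-condition labels when
    supplied, otherwise from the replicate consensus.  Summary fractions are
    computed over consistently assigned bins only and sum to 1 there.
    """
    if not cond1_reps or not cond2_reps:
        raise ValidationError("need at least one replicate per condition")
    bins = cond1_reps[0].ev1.bins
    for rep in cond1_reps + cond2_reps:
        if rep.ev1.bins != bins:
            raise ValidationError("replicate bin tables differ")
    n = len(bins)

    def pair_transition(l1: np.ndarray, l2: np.ndarray) -> np.ndarray:
        out = np.full(n, UNASSIGNED, dtype=object)
        assigned = (l1 != UNASSIGNED) & (l2 != UNASSIGNED)
        out[assigned] = np.char.add(
            np.char.add(l1[assigned].astype(str), "->"), l2[assigned].astype(str)
        )
        return out

    per_pair = [
        pair_transition(r1.labels, r2.labels) for r1 in cond1_reps for r2 in cond2_reps
    ]
    consistent = np.ones(n, dtype=bool)
    for t in per_pair[1:]:
        consistent &= t == per_pair[0]
    consistent &= per_pair[0] != UNASSIGNED

    if cond1_pooled is not None and cond2_pooled is not None:
        transition = pair_transition(cond1_pooled.labels, cond2_pooled.labels)
    else:
        transition = np.where(consistent, per_pair[0], UNASSIGNED).astype(object)

    classes = ["A->A", "A->B", "B->A", "B->B"]
    use = consistent & np.isin(transition.astype(str), classes)
    n_used = int(use.sum())
    summary = {
        c: (float((transition[use] == c).sum()) / n_used if n_used else np.nan)
        for c in classes
    }
    return FlipTable(
        transition=transition, consistent=consistent, summary=summary, n_consistent=n_used
    )


def saddle(
    oe: OEMaps,
    ev1: ScalarTrack,
    n_quantiles: int = 30,
    trim_percentile: float = 0.2,
    per_chromosome_trim: bool = False,
) -> SaddleResult:
    """Mean cis O/E between EV1-quantile groups.

    Bins are ranked by EV1 genome-wide, the outer ``trim_percentile`` of
    ranked values excluded at each end, and the remainder split into
    ``n_quantiles`` equal-count groups (sizes differing by at most one bin).
    Entry (i, j) is the mean O/E over all valid cis bin pairs with one bin in
    group i and the other in group j.  Trimming is genome-wide by default; set
    ``per_chromosome_trim`` to trim each chromosome's EV1 distribution
    separately.
    """
    bins = oe.bins
    vals = ev1.values
    group = np.full(len(bins), -1, dtype=int)

    def assign(idx: np.ndarray) -> None:
        v = vals[idx]
        lo, hi = np.percentile(v, [trim_percentile, 100 - trim_percentile])
        keep = idx[(v >= lo) & (v <= hi)]
        if len(keep) < n_quantiles:
            raise ValidationError("fewer valid bins than quantiles")
        order = keep[np.argsort(vals[keep], kind="stable")]
        group[order] = (np.arange(len(order)) * n_quantiles) // len(order)

    valid_idx = np.flatnonzero(np.isfinite(vals))
    if len(valid_idx) == 0:
        raise ValidationError("no valid EV1 bins")
    if per_chromosome_trim:
        for chrom in bins.chromosomes:
            sl = bins.chrom_slice(chrom)
            idx = valid_idx[(valid_idx >= sl.start) & (valid_idx < sl.stop)]
            if len(idx):
                assign(idx)
    else:
        assign(valid_idx)

    sums = np.zeros((n_quantiles, n_quantiles))
    counts = np.zeros((n_quantiles, n_quantiles))
    for chrom in bins.chromosomes:
        sl = bins.chrom_slice(chrom)
        g = group[sl]
        mat = oe[chrom]
        sel = g >= 0
        if not sel.any():
            continue
        sub = mat[np.ix_(sel, sel)]
        gs = g[sel]
        finite = np.isfinite(sub)
        sub0 = np.where(finite, sub, 0.0)
        for gi in range(n_quantiles):
            rows = gs == gi
            if not rows.any():
                continue
            sums[gi] += np.bincount(
                np.broadcast_to(gs, sub0[rows].shape)[finite[rows]],
                weights=sub0[rows][finite[rows]],
                minlength=n_quantiles,
            )
            counts[gi] += np.bincount(
                np.broadcast_to(gs, sub0[rows].shape)[finite[rows]], minlength=n_quantiles
            )
    with np.errstate(invalid="ignore"):
        mat = sums / counts
    edges = np.percentile(vals[group >= 0], np.linspace(0, 100, n_quantiles + 1))
    return SaddleResult(matrix=mat, quantile_edges=edges, n_quantiles=n_quantiles)


def saddle_strength(saddle_result: SaddleResult, extent: int | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative corner-ratio compartment strength curves.

    For k = 1..extent, A_strength[k-1] is the mean of the bottom-right k×k
    corner (A–A) divided by the mean of the two anti-diagonal k×k corners
    (A–B and B–A); B_strength uses the top-left (B–B) corner.  Invariant to
    uniform scaling of the O/E matrix.
    """
    m = saddle_result.matrix
    q = saddle_result.n_quantiles
    if extent is None:
        extent = q // 2
    if extent > q // 2:
        raise ValidationError("extent exceeds n_quantiles / 2")
    a_curve = np.empty(extent)
    b_curve = np.empty(extent)
    for k in range(1, extent + 1):
        aa = np.nanmean(m[q - k :, q - k :])
        bb = np.nanmean(m[:k, :k])
        ab = np.nanmean(np.concatenate([m[:k, q - k :].ravel(), m[q - k :, :k].ravel()]))
        a_curve[k - 1] = aa / ab
        b_curve[k - 1] = bb / ab
    return a_curve, b_curve
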