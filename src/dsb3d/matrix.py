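"""Core contact-matrix operations.

Balancing uses iterative correction (ICE): per-bin multiplicative weights are
iterated until every non-filtered bin has the same balanced marginal, with the
first ``ignore_diags`` diagonals masked from the marginals (short-range
ligation artifacts dominate there).  Weights are scaled so the mean balanced
marginal over non-filtered bins equals 1, which makes balanced values
comparable across matrices and makes the observed/expected transform
scale-free.

Expected models are cis-only: the mean balanced contact per diagonal,
per chromosome.  P(s) is the genome-wide average of those diagonal means in
log-spaced separation bins; its log-log derivative is taken by central finite
differences on the binned curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ContactMatrix, ScalarTrack, ValidationError

__all__ = [
    "BalanceError",
    "ExpectedProfile",
    "ScalingCurve",
    "OEMaps",
    "ice_balance",
    "expected_cis",
    "observed_over_expected",
    "contact_scaling",
    "insulation_profile",
    "downsample",
    "pool",
]


class BalanceError(RuntimeError):
    """Iterative correction failed to converge; carries the last residual."""

    def __init__(self, residual: float, n_iter: int):
        self.residual = residual
        self.n_iter = n_iter
        super().__init__(
            f"ICE did not converge after {n_iter} iterations (residual {residual:.3g})"
        )


# ---------------------------------------------------------------------------
# Balancing
# ---------------------------------------------------------------------------


def ice_balance(
    matrix: ContactMatrix,
    ignore_diags: int = 2,
    mad_max: float = 5.0,
    tol: float = 1e-5,
    max_iter: int = 1000,
    inplace: bool = True,
) -> np.ndarray:
    """Iterative correction of a cis+trans contact matrix.

    Returns per-bin weights (NaN for filtered bins) and, when ``inplace``,
    stores them on ``matrix.weights``.  Bins whose log10 marginal coverage
    (after masking the ignored diagonals) lies more than ``mad_max`` median
    absolute deviations below the median are filtered, as are zero-coverage
    bins.  Convergence: max relative deviation of non-filtered balanced
    marginals from their mean < ``tol``.
    """
    if ignore_diags < 0:
        raise ValidationError("ignore_diags must be >= 0")
    n = len(matrix.bins)
    i = matrix.pixels["bin1_id"].to_numpy()
    j = matrix.pixels["bin2_id"].to_numpy()
    v = matrix.pixels["count"].to_numpy().astype(float)
    keep = np.abs(i - j) >= ignore_diags
    i, j, v = i[keep], j[keep], v[keep]

    def marginals(values: np.ndarray) -> np.ndarray:
        m = np.bincount(i, weights=values, minlength=n)
        off = i != j
        m += np.bincount(j[off], weights=values[off], minlength=n)
        return m

    coverage = marginals(v)
    filtered = coverage <= 0
    nz = coverage > 0
    if nz.any() and mad_max is not None and np.isfinite(mad_max):
        logcov = np.log10(coverage[nz])
        med = np.median(logcov)
        mad = np.median(np.abs(logcov - med))
        if mad > 0:
            low = np.zeros(n, dtype=bool)
            low[nz] = logcov < med - mad_max * mad
            filtered |= low
    active = ~filtered
    if not active.any():
        raise ValidationError("all bins filtered; nothing to balance")

    bias = np.ones(n)
    bias[filtered] = np.nan
    vv = v.copy()
    vv[filtered[i] | filtered[j]] = 0.0
    residual = np.inf
    for it in range(max_iter):
        w = np.where(filtered, 0.0, bias)
        bal = vv * w[i] * w[j]
        m = marginals(bal)
        mean_m = m[active].mean()
        if mean_m == 0:
            raise ValidationError("zero total signal among active bins")
        residual = np.abs(m[active] / mean_m - 1.0).max()
        if residual < tol:
            break
        # sqrt damping avoids the period-2 oscillation of the raw update on
        # symmetric matrices
        adj = np.ones(n)
        adj[active] = np.sqrt(m[active] / mean_m)
        adj[adj == 0] = 1.0
        bias = bias / adj
    else:
        raise BalanceError(residual, max_iter)

    # scale weights so the mean balanced marginal over active bins is 1
    w = np.where(filtered, 0.0, bias)
    m = marginals(vv * w[i] * w[j])
    scale = np.sqrt(m[active].mean())
    weights = bias / scale
    weights[filtered] = np.nan
    if inplace:
        matrix.weights = weights
    return weights


# ---------------------------------------------------------------------------
# Expected / observed-over-expected
# ---------------------------------------------------------------------------


@dataclass
class ExpectedProfile:
    """Per-chromosome mean balanced contact per diagonal.

    ``table`` columns: chrom, diag (bin units), mean (NaN where no valid
    element), n_valid.
    """

    table: pd.DataFrame
    bin_size: int

    def profile(self, chrom: str) -> np.ndarray:
        sub = self.table[self.table["chrom"] == chrom].sort_values("diag")
        return sub["mean"].to_numpy()


@dataclass
class ScalingCurve:
    """Contact probability P(s) in log-spaced separation bins.

    ``s`` are geometric bin centers in base pairs; ``derivative`` is
    d log P / d log s by central differences (NaN at the ends).
    """

    s: np.ndarray
    p: np.ndarray
    derivative: np.ndarray
    n_valid: np.ndarray


@dataclass
class OEMaps:
    """Dense per-chromosome observed/expected cis matrices (NaN = missing)."""

    bins: "object"
    data: dict[str, np.ndarray]

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]


def _balanced_dense(matrix: ContactMatrix, chrom: str) -> np.ndarray:
    """Balanced dense cis matrix with NaN rows/cols for filtered bins."""
    if matrix.weights is None:
        raise ValidationError("matrix must be balanced first")
    dense = matrix.to_dense(chrom, balanced=True)
    w = matrix.weights[matrix.bins.chrom_slice(chrom)]
    bad = ~np.isfinite(w)
    dense[bad, :] = np.nan
    dense[:, bad] = np.nan
    return dense


def expected_cis(matrix: ContactMatrix, ignore_diags: int = 2) -> ExpectedProfile:
    """Mean balanced contact per diagonal, per chromosome.

    Diagonals with no valid (non-filtered) element are NaN, and the first
    ``ignore_diags`` diagonals are excluded (NaN) to mirror balancing.
    """
    rows = []
    for chrom in matrix.bins.chromosomes:
        dense = _balanced_dense(matrix, chrom)
        n = dense.shape[0]
        for d in range(n):
            diag = np.diagonal(dense, d)
            valid = np.isfinite(diag)
            nv = int(valid.sum())
            if d < ignore_diags or nv == 0:
                rows.append((chrom, d, np.nan, 0 if nv == 0 else nv))
            else:
                rows.append((chrom, d, float(diag[valid].mean()), nv))
    table = pd.DataFrame(rows, columns=["chrom", "diag", "mean", "n_valid"])
    return ExpectedProfile(table, matrix.bins.bin_size)


def observed_over_expected(
    matrix: ContactMatrix, expected: ExpectedProfile | None = None, ignore_diags: int = 2
) -> OEMaps:
    """Balanced value divided by the same-chromosome expected at that diagonal.

    By construction the mean O/E over valid entries of every diagonal is 1.
    Diagonals whose expected is NaN (ignored or fully filtered) are NaN.
    """
    if expected is None:
        expected = expected_cis(matrix, ignore_diags=ignore_diags)
    data = {}
    for chrom in matrix.bins.chromosomes:
        dense = _balanced_dense(matrix, chrom)
        n = dense.shape[0]
        exp = expected.profile(chrom)
        if len(exp) < n:
            raise ValidationError(f"expected profile too short for {chrom}")
        idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        denom = exp[idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            oe = dense / denom
        zero_exp = (denom == 0) & np.isfinite(dense) & (dense > 0)
        if zero_exp.any():
            raise ValidationError(f"zero expected with observations on {chrom}")
        data[chrom] = oe
    return OEMaps(matrix.bins, data)


# ---------------------------------------------------------------------------
# P(s) scaling
# ---------------------------------------------------------------------------


def contact_scaling(
    matrix: ContactMatrix,
    bins_per_decade: int = 8,
    min_separation: int | None = None,
    ignore_diags: int = 2,
) -> ScalingCurve:
    """Genome-average contact probability vs separation, log-binned.

    Diagonal means are pooled across chromosomes (weighted by valid element
    count), averaged within geometric separation bins of ``bins_per_decade``
    per decade starting at ``min_separation`` (default: ``ignore_diags`` bins),
    and normalized to unit sum so the curve is invariant to sequencing depth.
    """
    expected = expected_cis(matrix, ignore_diags=ignore_diags)
    bs = matrix.bins.bin_size
    tab = expected.table.dropna(subset=["mean"])
    if min_separation is None:
        min_separation = max(ignore_diags, 1) * bs
    sep = tab["diag"].to_numpy() * bs
    keep = sep >= min_separation
    sep = sep[keep]
    val = tab["mean"].to_numpy()[keep]
    nv = tab["n_valid"].to_numpy()[keep]
    if len(sep) == 0:
        raise ValidationError("no separations above min_separation")
    lo = np.log10(sep.min())
    hi = np.log10(sep.max())
    n_edges = max(int(np.ceil((hi - lo) * bins_per_decade)) + 1, 2)
    edges = np.logspace(lo, hi + 1e-9, n_edges + 1)
    which = np.clip(np.searchsorted(edges, sep, side="right") - 1, 0, n_edges - 1)
    p = np.full(n_edges, np.nan)
    centers = np.sqrt(edges[:-1] * edges[1:])
    counts = np.zeros(n_edges, dtype=int)
    for b in range(n_edges):
        m = which == b
        if m.any():
            p[b] = np.average(val[m], weights=nv[m])
            counts[b] = int(nv[m].sum())
    valid = np.isfinite(p) & (p > 0)
    if valid.sum() < 3:
        raise ValidationError("fewer than 3 log bins with data")
    s = centers[valid]
    pv = p[valid]
    pv = pv / pv.sum()  # depth invariance
    logs, logp = np.log(s), np.log(pv)
    deriv = np.full(len(s), np.nan)
    deriv[1:-1] = (logp[2:] - logp[:-2]) / (logs[2:] - logs[:-2])
    return ScalingCurve(s=s, p=pv, derivative=deriv, n_valid=counts[valid])


# ---------------------------------------------------------------------------
# Insulation
# ---------------------------------------------------------------------------


def insulation_profile(matrix: ContactMatrix, window: int = 100_000) -> ScalarTrack:
    """Sliding-diamond insulation, log2-normalized to the chromosome mean.

    For each bin b, the diamond is the ``w×w`` block of balanced contacts
    between the ``w`` bins upstream and ``w`` bins downstream of b
    (``w = window / bin_size``).  Scores are log2(diamond mean / chromosome
    mean of diamond means); bins within ``w`` of a chromosome end, or with an
    empty diamond, are NaN.  The method is a standard-toolkit reconstruction:
    no single convention is canonical.
    """
    bs = matrix.bins.bin_size
    if window % bs:
        raise ValidationError("window must be a multiple of bin_size")
    w = window // bs
    if w < 2:
        raise ValidationError("window must span at least 2 bins")
    values = np.full(len(matrix.bins), np.nan)
    for chrom in matrix.bins.chromosomes:
        dense = _balanced_dense(matrix, chrom)
        n = dense.shape[0]
        sl = matrix.bins.chrom_slice(chrom)
        raw = np.full(n, np.nan)
        for b in range(w, n - w):
            block = dense[b - w : b, b + 1 : b + w + 1]
            if np.isfinite(block).any():
                raw[b] = np.nanmean(block)
        finite = np.isfinite(raw) & (raw > 0)
        if finite.any():
            mean = raw[finite].mean()
            out = np.full(n, np.nan)
            out[finite] = np.log2(raw[finite] / mean)
            values[sl] = out
    return ScalarTrack(matrix.bins, values, label="insulation")


# ---------------------------------------------------------------------------
# Downsampling / pooling
# ---------------------------------------------------------------------------


def downsample(matrix: ContactMatrix, target_pairs: int, seed: int) -> ContactMatrix:
    """Thin pixel counts to exactly ``target_pairs`` total.

    Draws are multivariate hypergeometric (without replacement across the
    pixel multiset), so the target is hit exactly — mirroring subsampling of
    unique valid pairs.
    """
    total = matrix.total_valid_pairs
    if target_pairs > total:
        raise ValidationError("target exceeds total_valid_pairs")
    rng = np.random.default_rng(seed)
    counts = matrix.pixels["count"].to_numpy()
    new_counts = rng.multivariate_hypergeometric(counts, int(target_pairs), method="marginals")
    px = matrix.pixels.copy()
    px["count"] = new_counts
    px = px[px["count"] > 0]
    return ContactMatrix(matrix.bins, px)


def pool(matrices: list[ContactMatrix]) -> ContactMatrix:
    """Pixelwise sum of replicate matrices on identical bin tables."""
    if not matrices:
        raise ValidationError("nothing to pool")
    bins = matrices[0].bins
    for m in matrices[1:]:
        if m.bins != bins:
            raise ValidationError("bin tables differ between replicates")
    px = (
        pd.concat([m.pixels for m in matrices], ignore_index=True)
        .groupby(["bin1_id", "bin2_id"], as_index=False)["count"]
        .sum()
    )
    return ContactMatrix(bins, px)
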