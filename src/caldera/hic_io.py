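"""Reading, balancing, filtering and resampling binned Hi-C contact matrices.

All operations act on intrachromosomal matrices only.  A :class:`ContactMatrix`
keeps, next to the (symmetric) matrix of retained bins, a boolean mask over the
*original* bin grid so genomic coordinates stay recoverable after sparse bins
have been dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ContactMatrix",
    "AggregatedMatrix",
    "OEMatrix",
    "KRConvergenceError",
    "read_contact_map",
    "kr_balance",
    "vc_balance",
    "filter_sparse_bins",
    "contact_density",
    "downsample",
    "aggregate_columns",
    "observed_over_expected",
]

_SYM_TOL = 1e-9

NON_AUTOSOMES = {"chrX", "chrY", "chrM", "chrMT", "X", "Y", "M", "MT"}


def is_autosome(chrom: str) -> bool:
    return chrom not in NON_AUTOSOMES


class KRConvergenceError(RuntimeError):
    """Knight-Ruiz balancing failed to converge; callers may fall back to VC."""


@dataclass
class ContactMatrix:
    """Symmetric binned intrachromosomal contact matrix.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    bin_size : int
        Bin width in base pairs.
    values : ndarray
        ``(n, n)`` symmetric matrix of non-negative contact values over the
        *retained* bins (raw counts or balanced values).
    retained : ndarray of bool
        Mask over the original bin grid; ``retained.sum() == n``.
    normalization : str
        One of ``{"raw", "KR", "VC"}``.
    """

    chrom: str
    bin_size: int
    values: np.ndarray
    retained: np.ndarray = None
    normalization: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("contact matrix must be symmetric")
        finite = self.values[np.isfinite(self.values)]
        if (finite < 0).any():
            raise ValueError("contact values must be non-negative")
        if self.retained is None:
            self.retained = np.ones(self.values.shape[0], dtype=bool)
        self.retained = np.asarray(self.retained, dtype=bool)
        if int(self.retained.sum()) != self.values.shape[0]:
            raise ValueError("retained mask inconsistent with matrix dimension")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def bin_starts(self) -> np.ndarray:
        """Genomic start (bp) of each retained bin, 0-based."""
        return np.flatnonzero(self.retained) * self.bin_size


@dataclass
class AggregatedMatrix:
    """Column-block-summed contact matrix (rows keep bin resolution)."""

    values: np.ndarray
    factor: int
    source_bin_size: int


@dataclass
class OEMatrix:
    """Observed/expected contact ratios with the per-diagonal expectation."""

    values: np.ndarray
    expected_by_distance: np.ndarray


# ---------------------------------------------------------------------------
# Reading


def read_contact_map(path, format: str, chrom: str, bin_size: int,
                     n_bins: int | None = None) -> ContactMatrix:
    """Read an intrachromosomal contact map from a text file.

    ``format="dense"``: whitespace-delimited ``n x n`` matrix, no header.
    ``format="triplet"``: tab/whitespace-delimited ``bin_i bin_j count`` lines
    with 0-based bin indices; either triangle accepted, mirrored on read.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if format == "dense":
        try:
            mat = np.loadtxt(path, ndmin=2)
        except ValueError as e:
            raise ValueError(f"malformed dense matrix in {path}: {e}") from e
        if mat.shape[0] != mat.shape[1]:
            raise ValueError(
                f"dense matrix must be square, got {mat.shape[0]}x{mat.shape[1]}")
        return ContactMatrix(chrom, bin_size, mat)
    if format == "triplet":
        rows, cols, vals = [], [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                parts = line.split()
                if len(parts) != 3:
                    raise ValueError(
                        f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
                try:
                    i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
                except ValueError as e:
                    raise ValueError(f"{path}:{lineno}: {e}") from e
                if i < 0 or j < 0:
                    raise ValueError(f"{path}:{lineno}: negative bin index")
                rows.append(i)
                cols.append(j)
                vals.append(v)
        if not rows:
            raise ValueError(f"{path}: no data lines")
        n = n_bins if n_bins is not None else max(max(rows), max(cols)) + 1
        rows, cols = np.array(rows), np.array(cols)
        if rows.max() >= n or cols.max() >= n:
            raise ValueError(
                f"{path}: bin index {max(rows.max(), cols.max())} out of range "
                f"for n_bins={n}")
        mat = np.zeros((n, n))
        # additive fill then symmetrize; diagonal counted once
        np.add.at(mat, (rows, cols), vals)
        mat = np.maximum(mat, mat.T)
        return ContactMatrix(chrom, bin_size, mat)
    if format == "cool":
        raise NotImplementedError(
            "cooler-format input requires the 'cooler' package; supply a dense "
            "or triplet text dump instead")
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Balancing


def kr_balance(m: ContactMatrix, tol: float = 1e-6,
               max_iter: int = 3000) -> ContactMatrix:
    """Knight-Ruiz balancing: find x > 0 with diag(x) A diag(x) row sums 1.

    Uses the inner-outer Newton iteration of Knight & Ruiz (2013).  Raises
    :class:`KRConvergenceError` when the row-sum coefficient of variation does
    not reach ``tol`` within ``max_iter`` inner iterations, so callers can fall
    back to vanilla-coverage normalization.
    """
    A = m.values
    n = A.shape[0]
    if (A.sum(axis=1) == 0).any():
        raise ValueError("zero rows must be filtered before balancing")
    x = _kr_vector(A, tol=tol, max_iter=max_iter)
    bal = A * np.outer(x, x)
    bal = (bal + bal.T) / 2.0
    rs = bal.sum(axis=1)
    if rs.std() / rs.mean() > max(tol, 1e-5):
        raise KRConvergenceError("KR balancing did not converge")
    return replace(m, values=bal, normalization="KR")


def _kr_vector(A, tol, max_iter):
    # Newton inner-outer iteration (bnewt); target row sums e = 1.
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g = 0.9
    etamax = 0.1
    eta = etamax
    rt = tol ** 2
    v = x * (A @ x)
    rk = 1 - v
    rho_km1 = rk @ rk
    rout = rho_km1
    rold = rout
    it = 0
    while rout > rt and it < max_iter:
        it += 1
        k = 0
        y = e.copy()
        innertol = max(eta ** 2 * rout, rt)
        rho_km2 = rho_km1
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                gamma = np.min((delta - y[ap < 0]) / ap[ap < 0])
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ap > 0
                gamma = np.min((Delta - y[ind]) / ap[ind])
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            if k > 50:
                break
        x = x * y
        v = x * (A @ x)
        rk = 1 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold
        rold = rout
        eta = max(min(g * rat, etamax), 0.5 * rt / rout if rout > 0 else 0)
    if rout > rt:
        raise KRConvergenceError(
            f"KR did not reach tol={tol} after {it} outer iterations")
    return x


def vc_balance(m: ContactMatrix) -> ContactMatrix:
    """Vanilla-coverage normalization: A_ij / (r_i r_j), rescaled so the mean
    row sum is 1."""
    A = m.values
    r = A.sum(axis=1)
    if (r == 0).any():
        raise ValueError("zero row sums; filter sparse bins first")
    bal = A / np.outer(r, r)
    bal *= 1.0 / bal.sum(axis=1).mean()
    bal = (bal + bal.T) / 2.0
    return replace(m, values=bal, normalization="VC")


# ---------------------------------------------------------------------------
# Filtering / summary


def filter_sparse_bins(m: ContactMatrix, zero_fraction: float = 0.99) -> ContactMatrix:
    """Drop matched rows/columns whose fraction of zero entries strictly
    exceeds ``zero_fraction`` (low-mappability bins)."""
    if not 0 < zero_fraction <= 1:
        raise ValueError("zero_fraction must be in (0, 1]")
    n = m.n_bins
    zero_frac = (m.values == 0).sum(axis=1) / n
    keep = zero_frac <= zero_fraction
    if not keep.any():
        raise ValueError(f"empty chromosome {m.chrom}: all bins filtered")
    retained = m.retained.copy()
    retained[np.flatnonzero(m.retained)[~keep]] = False
    return replace(m, values=m.values[np.ix_(keep, keep)], retained=retained)


def contact_density(m: ContactMatrix) -> float:
    """Fraction of non-zero entries in the upper triangle (diagonal included)."""
    n = m.n_bins
    if n == 0:
        raise ValueError("empty matrix")
    iu = np.triu_indices(n)
    vals = m.values[iu]
    return float((vals != 0).sum() / vals.size)


def downsample(m: ContactMatrix, fraction: float, seed: int) -> ContactMatrix:
    """Binomially thin raw counts, keeping each read with probability
    ``fraction``; symmetric and deterministic given ``seed``."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if m.normalization != "raw":
        raise ValueError("downsampling applies to raw counts only")
    counts = m.values
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("downsampling requires integer raw counts")
    if fraction == 1.0:
        return replace(m, values=counts.copy())
    rng = np.random.default_rng(seed)
    n = m.n_bins
    iu = np.triu_indices(n)
    thinned = rng.binomial(counts[iu].astype(np.int64), fraction).astype(float)
    out = np.zeros_like(counts)
    out[iu] = thinned
    out = out + np.triu(out, 1).T
    return replace(m, values=out)


def aggregate_columns(m: ContactMatrix, factor: int = 10) -> AggregatedMatrix:
    """Sum consecutive blocks of ``factor`` columns to reduce sparsity; row i
    then holds bin i's total contacts with each block of bins."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    A = m.values
    n = A.shape[0]
    n_blocks = -(-n // factor)
    out = np.zeros((n, n_blocks))
    for b in range(n_blocks):
        out[:, b] = A[:, b * factor:min((b + 1) * factor, n)].sum(axis=1)
    return AggregatedMatrix(values=out, factor=factor, source_bin_size=m.bin_size)


def observed_over_expected(m: ContactMatrix) -> OEMatrix:
    """Divide each entry by the mean contact at its genomic distance.

    Cells on diagonals with zero expected value are set to NaN.
    """
    A = m.values
    n = A.shape[0]
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    expected = np.array([A.diagonal(d).mean() for d in range(n)])
    E = expected[dist]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(E > 0, A / np.where(E > 0, E, 1.0), np.nan)
    return OEMatrix(values=oe, expected_by_distance=expected)
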