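"""Compartment-domain calling from whole-chromosome contact similarity.

The chromosome-wide interaction profile of each bin is turned into a
correlation-of-correlation similarity matrix (Fisher z-transformed), and the
chromosome is segmented at statistically supported local minima of a
TopDom-style diamond bin-signal computed on that similarity matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .hic_io import AggregatedMatrix

__all__ = [
    "SimilarityMatrix",
    "DomainSegmentation",
    "contact_correlation",
    "second_order_correlation",
    "fisher_z",
    "call_compartment_domains",
    "similarity_from_contacts",
]

R_MAX = 1.0 - 1e-6  # correlation clip before arctanh keeps scores finite


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of Fisher-z transformed correlation scores."""

    values: np.ndarray
    source: str = "contacts"  # or "trend"

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class DomainSegmentation:
    """Ordered, non-overlapping compartment domains as half-open bin intervals."""

    domains: list  # list of (start, end) bin intervals, half-open
    chrom: str
    bin_size: int

    @property
    def k(self) -> int:
        return len(self.domains)

    @property
    def boundaries(self) -> np.ndarray:
        """Internal boundary positions (bin index of the gap's right bin)."""
        return np.array([s for s, _ in self.domains[1:]], dtype=int)


def contact_correlation(a: AggregatedMatrix | np.ndarray) -> np.ndarray:
    """Pearson correlations between the rows of the (aggregated) contact
    matrix; zero-variance rows give NaN entries."""
    vals = a.values if isinstance(a, AggregatedMatrix) else np.asarray(a, float)
    if vals.shape[0] < 3:
        raise ValueError("need at least 3 rows to correlate")
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(vals)
    return rho


def second_order_correlation(rho: np.ndarray) -> np.ndarray:
    """Correlations between the columns of a correlation matrix, sharpening
    the plaid pattern.  NaN entries (zero-variance bins) are treated as 0."""
    rho = np.asarray(rho, float)
    if rho.ndim != 2 or rho.shape[0] != rho.shape[1]:
        raise ValueError("input must be a square correlation matrix")
    clean = np.nan_to_num(rho, nan=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho2 = np.corrcoef(clean.T)
    return rho2


def fisher_z(r, r_max: float = R_MAX):
    """Fisher z-transform (arctanh) with |r| clipped to ``r_max``.

    Variance-stabilizing and monotone; correlations of large magnitude are
    amplified much more strongly than weak ones.
    """
    arr = np.asarray(r, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and np.abs(finite).max() > 1 + 1e-9:
        raise ValueError("correlations must lie in [-1, 1]")
    clipped = np.clip(arr, -r_max, r_max)
    out = np.arctanh(clipped)
    if np.isscalar(r) or np.ndim(r) == 0:
        return float(out)
    return out


def similarity_from_contacts(a: AggregatedMatrix | np.ndarray) -> SimilarityMatrix:
    """rho -> rho2 -> arctanh pipeline producing the segmentation substrate."""
    rho = contact_correlation(a)
    rho2 = second_order_correlation(rho)
    s = fisher_z(np.nan_to_num(rho2, nan=0.0))
    s = (s + s.T) / 2.0
    return SimilarityMatrix(values=s, source="contacts")


# ---------------------------------------------------------------------------
# TopDom-style boundary calling on the similarity matrix


def _diamond(values: np.ndarray, gap: int, w: int) -> np.ndarray:
    """Similarity entries between the w bins upstream and w bins downstream of
    the gap before bin ``gap`` (clipped at chromosome ends)."""
    n = values.shape[0]
    lo = max(0, gap - w)
    hi = min(n, gap + w)
    return values[lo:gap, gap:hi].ravel()


def _flank_within(values: np.ndarray, gap: int, w: int) -> np.ndarray:
    """Off-diagonal within-block entries of the two w-bin flanks."""
    n = values.shape[0]
    lo = max(0, gap - w)
    hi = min(n, gap + w)
    up = values[lo:gap, lo:gap]
    down = values[gap:hi, gap:hi]
    out = []
    for block in (up, down):
        if block.shape[0] > 1:
            iu = np.triu_indices(block.shape[0], k=1)
            out.append(block[iu])
    return np.concatenate(out) if out else np.empty(0)


def binsignal(s: SimilarityMatrix, window_bins: int = 5) -> np.ndarray:
    """Mean diamond similarity for every internal gap (index = right bin)."""
    n = s.n
    sig = np.full(n, np.nan)
    for gap in range(1, n):
        d = _diamond(s.values, gap, window_bins)
        sig[gap] = d.mean() if d.size else np.nan
    return sig


def distance_centered(values: np.ndarray) -> np.ndarray:
    """Subtract the per-diagonal mean, removing the genomic-distance trend of
    the similarity scores (the analogue of an observed-minus-expected map)."""
    n = values.shape[0]
    idx = np.arange(n)
    means = np.array([values.diagonal(d).mean() for d in range(n)])
    return values - means[np.abs(idx[:, None] - idx[None, :])]


def boundary_support_test(C: np.ndarray, gap: int, flank_bins: int,
                          min_flank: int) -> float:
    """Domain-level support p-value for a candidate boundary.

    On the distance-centered similarity, each bin of the two ``flank_bins``
    flanks contributes one paired difference: its mean similarity to its own
    side minus its mean similarity across the gap.  A one-sided Wilcoxon
    signed-rank test asks whether these per-bin differences are positive.
    Pairing per bin makes the test robust to the correlated, distance-
    structured noise of the similarity matrix that cell-level rank-sum tests
    mistake for boundaries.  Returns 1.0 when either flank is shorter than
    ``min_flank`` (chromosome ends; the centering is unreliable there).
    """
    n = C.shape[0]
    lo, hi = max(0, gap - flank_bins), min(n, gap + flank_bins)
    if gap - lo < min_flank or hi - gap < min_flank:
        return 1.0
    diffs = []
    for i in range(lo, gap):
        w = np.concatenate([C[i, lo:i], C[i, i + 1:gap]])
        diffs.append(w.mean() - C[i, gap:hi].mean())
    for j in range(gap, hi):
        w = np.concatenate([C[j, gap:j], C[j, j + 1:hi]])
        diffs.append(w.mean() - C[j, lo:gap].mean())
    diffs = np.asarray(diffs)
    if np.allclose(diffs, 0):
        return 1.0
    return float(stats.wilcoxon(diffs, alternative="greater").pvalue)


def call_compartment_domains(s: SimilarityMatrix, window_bins: int = 5,
                             min_domain_bins: int = 2, p_cut: float = 0.05,
                             flank_bins: int | None = None,
                             chrom: str = "chr?", bin_size: int = 1,
                             ) -> DomainSegmentation:
    """Segment the chromosome at supported local minima of the bin-signal.

    Stage 1 (TopDom-style): a gap is a candidate boundary when its diamond
    mean is a local minimum within ``window_bins``, and is kept when a
    one-sided Wilcoxon rank-sum test finds the diamond values significantly
    lower than the flanking within-block values (p < ``p_cut``).  Candidates
    are admitted in order of increasing bin-signal, skipping any that would
    create a domain shorter than ``min_domain_bins``.

    Stage 2: each surviving candidate must additionally pass the paired
    domain-level support test (:func:`boundary_support_test`, p < ``p_cut``)
    on the distance-centered similarity over ``flank_bins`` flanks
    (default ``4 * window_bins``); this controls the false boundaries that
    cell-level statistics admit on correlated similarity noise.
    """
    if window_bins < 2:
        raise ValueError("window_bins must be >= 2")
    n = s.n
    if n <= 2 * window_bins:
        raise ValueError("matrix too small for the requested window")
    sig = binsignal(s, window_bins)
    if np.nanstd(sig) == 0:
        warnings.warn("degenerate (constant) similarity matrix: single domain")
        return DomainSegmentation([(0, n)], chrom, bin_size)

    candidates = []
    for gap in range(1, n):
        lo = max(1, gap - window_bins)
        hi = min(n, gap + window_bins + 1)
        window = sig[lo:hi]
        if not np.isfinite(sig[gap]):
            continue
        wmin = np.nanmin(window)
        if sig[gap] > wmin:
            continue
        if np.nanmax(window) == wmin:
            continue  # flat neighbourhood carries no boundary information
        left = sig[lo:gap]
        if left.size and np.nanmin(left) == wmin:
            continue  # keep only the leftmost gap of a minimum plateau
        candidates.append(gap)

    accepted = []
    for gap in sorted(candidates, key=lambda g: sig[g]):
        diamond = _diamond(s.values, gap, window_bins)
        flank = _flank_within(s.values, gap, window_bins)
        if diamond.size < 3 or flank.size < 3:
            continue
        p = stats.mannwhitneyu(diamond, flank, alternative="less").pvalue
        if p >= p_cut:
            continue
        edges = [0, n] + accepted
        if min(abs(gap - e) for e in edges) < min_domain_bins:
            continue
        accepted.append(gap)

    if flank_bins is None:
        flank_bins = 4 * window_bins
    C = distance_centered(s.values)
    accepted = [g for g in accepted
                if boundary_support_test(C, g, flank_bins, 2 * window_bins)
                < p_cut]
    accepted.sort()
    edges = [0] + accepted + [n]
    domains = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    return DomainSegmentation(domains, chrom, bin_size)
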