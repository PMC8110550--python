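"""Nested subdomains within compartment domains.

Within one compartment domain, short-range contacts between candidate sibling
subdomains are modelled with a zero-inflated (mixture) log-normal
distribution.  Dynamic programming finds the genome-anchored binary
dendrogram maximizing the total log-likelihood over all sibling pairs in
O(n^3); the dendrogram is then trimmed top-down against the
observed/expected matrix with one-tailed Wilcoxon rank-sum tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .hic_io import ContactMatrix, OEMatrix, observed_over_expected
from .segmentation import DomainSegmentation

__all__ = [
    "SIGMA_MIN",
    "MixtureLogNormalParams",
    "NestedNode",
    "NestedDomainTree",
    "mixture_mle",
    "mixture_loglik",
    "best_dendrogram",
    "trim_tree",
    "call_nested_domains",
]

SIGMA_MIN = 1e-3  # keeps the log-normal density proper for constant samples
_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class MixtureLogNormalParams:
    """Zero-mass weight plus log-normal location/scale of positive contacts."""

    alpha: float
    mu: float
    sigma: float

    def __post_init__(self):
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if np.isfinite(self.sigma) and self.sigma < SIGMA_MIN:
            raise ValueError(f"sigma must be >= {SIGMA_MIN}")


class NestedNode:
    """Node of a genome-anchored subdomain dendrogram ([start, end) bins,
    relative to the parent compartment domain)."""

    __slots__ = ("start", "end", "split", "left", "right", "params",
                 "loglik", "accepted", "stats")

    def __init__(self, start, end, split=None, left=None, right=None,
                 params=None, loglik=0.0):
        self.start = start
        self.end = end
        self.split = split
        self.left = left
        self.right = right
        self.params = params
        self.loglik = loglik
        self.accepted = None
        self.stats = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None


@dataclass
class NestedDomainTree:
    """Best-fitting subdomain dendrogram of one compartment domain."""

    domain_start: int           # chromosome bin offset of the parent domain
    domain_end: int
    root: NestedNode
    total_loglik: float

    def accepted_leaves(self):
        """Maximal intervals after trimming, as chromosome bin intervals."""
        out = []

        def walk(node):
            if node.is_leaf or not node.accepted:
                out.append((self.domain_start + node.start,
                            self.domain_start + node.end))
                return
            walk(node.left)
            walk(node.right)

        walk(self.root)
        return out


# ---------------------------------------------------------------------------
# Mixture log-normal likelihood


def mixture_mle(x) -> MixtureLogNormalParams:
    """Closed-form MLE: alpha = zero fraction; mu, sigma = mean and population
    sd of ln of the positive values (sigma floored at ``SIGMA_MIN``)."""
    x = np.asarray(x, float).ravel()
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("empty sample")
    if (x < 0).any():
        raise ValueError("contact values must be non-negative")
    n0 = int((x == 0).sum())
    alpha = n0 / x.size
    pos = x[x > 0]
    if pos.size == 0:
        return MixtureLogNormalParams(alpha=1.0, mu=float("nan"),
                                      sigma=float("nan"))
    logs = np.log(pos)
    mu = float(logs.mean())
    sigma = max(float(logs.std()), SIGMA_MIN)  # population sd
    return MixtureLogNormalParams(alpha=alpha, mu=mu, sigma=sigma)


def mixture_loglik(x, p: MixtureLogNormalParams) -> float:
    """Total log-likelihood of a sample under the mixture log-normal model.

    Zeros contribute ln(alpha); positives ln((1-alpha) * logN(mu, sigma)).
    Returns -inf when the parameters give a zero-probability observation.
    """
    x = np.asarray(x, float).ravel()
    n0 = int((x == 0).sum())
    pos = x[x > 0]
    ll = 0.0
    if n0:
        if p.alpha == 0:
            return float("-inf")
        ll += n0 * math.log(p.alpha)
    if pos.size:
        if p.alpha == 1 or not np.isfinite(p.mu):
            return float("-inf")
        logs = np.log(pos)
        ll += pos.size * math.log(1 - p.alpha)
        ll += float(-logs.sum()
                    - pos.size * (math.log(p.sigma) + 0.5 * _LOG_2PI)
                    - ((logs - p.mu) ** 2).sum() / (2 * p.sigma ** 2))
    return ll


# ---------------------------------------------------------------------------
# Dynamic-programming dendrogram fit


def _prefix_sums(S: np.ndarray):
    pos = S > 0
    logs = np.where(pos, np.log(np.where(pos, S, 1.0)), 0.0)
    pad = lambda M: np.pad(np.cumsum(np.cumsum(M, axis=0), axis=1),
                           ((1, 0), (1, 0)))
    return pad((S == 0).astype(float)), pad(logs), pad(logs ** 2)


def _rect(P, i, s, j):
    """Sum over rows i..s, cols s+1..j (inclusive); s may be a vector."""
    return P[s + 1, j + 1] - P[i, j + 1] - P[s + 1, s + 1] + P[i, s + 1]


def _node_loglik_vec(P0, P1, P2, i, s, j):
    """MLE log-likelihood of the between-children rectangle, vectorized over
    split positions ``s`` (identical to mixture_loglik at mixture_mle)."""
    ncells = (s - i + 1.0) * (j - s + 0.0)
    n0 = _rect(P0, i, s, j)
    S1 = _rect(P1, i, s, j)
    S2 = _rect(P2, i, s, j)
    n1 = ncells - n0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(n1 > 0, S1 / np.maximum(n1, 1), 0.0)
        ss = np.maximum(S2 - n1 * mu ** 2, 0.0)
        sigma2 = np.maximum(np.where(n1 > 0, ss / np.maximum(n1, 1), 1.0),
                            SIGMA_MIN ** 2)
        ll = np.where(n0 > 0, n0 * np.log(np.maximum(n0, 1) / ncells), 0.0)
        ll += np.where(n1 > 0,
                       n1 * np.log(np.maximum(n1, 1) / ncells)
                       - S1 - 0.5 * n1 * (np.log(sigma2) + _LOG_2PI)
                       - ss / (2 * sigma2),
                       0.0)
    return ll


def best_dendrogram(sub, min_bins: int = 2) -> NestedDomainTree:
    """Maximum-likelihood genome-anchored dendrogram of one domain.

    Every interval of at least ``2 * min_bins`` bins is split; the split
    position maximizes the summed sibling-pair log-likelihood (DP over
    intervals, O(n^3)).  Likelihood ties are broken toward the more balanced
    split, then leftmost.
    """
    S = sub.values if isinstance(sub, ContactMatrix) else np.asarray(sub, float)
    n = S.shape[0]
    if n == 0:
        raise ValueError("empty domain")
    if min_bins < 1:
        raise ValueError("min_bins must be >= 1")
    if n < 2 * min_bins:
        return NestedDomainTree(0, n, NestedNode(0, n), 0.0)
    P0, P1, P2 = _prefix_sums(S)
    best = np.zeros((n, n))      # best[i, j]: interval i..j inclusive
    split = np.full((n, n), -1, dtype=int)
    for length in range(2 * min_bins, n + 1):
        for i in range(0, n - length + 1):
            j = i + length - 1
            s = np.arange(i + min_bins - 1, j - min_bins + 1)
            total = best[i, s] + best[s + 1, j] + \
                _node_loglik_vec(P0, P1, P2, i, s, j)
            mx = total.max()
            tol = 1e-9 * max(1.0, abs(mx))
            cand = s[total >= mx - tol]
            balance = np.abs((cand - i + 1) - (j - cand))
            pick = cand[np.lexsort((cand, balance))[0]]
            best[i, j] = total[np.searchsorted(s, pick)]
            split[i, j] = pick

    def build(i, j):
        if split[i, j] < 0 or j - i + 1 < 2 * min_bins:
            return NestedNode(i, j + 1)
        sp = split[i, j]
        block = S[i:sp + 1, sp + 1:j + 1]
        params = mixture_mle(block)
        node = NestedNode(i, j + 1, split=sp + 1,
                          left=build(i, sp), right=build(sp + 1, j),
                          params=params,
                          loglik=float(mixture_loglik(block, params)))
        return node

    root = build(0, n - 1)
    return NestedDomainTree(0, n, root, float(best[0, n - 1]))


# ---------------------------------------------------------------------------
# Trimming


def _split_regions(oe_sub: np.ndarray, node: NestedNode):
    """Index the four O/E regions of a candidate split.

    A: triangle at the parent's off-diagonal corner, delimited by the
    children's off-diagonal corners; B: remaining between-children cells;
    C, D: within-children upper triangles (diagonal excluded).
    """
    i, e, sp = node.start, node.end, node.split
    s, j = sp - 1, e - 1               # inclusive child1 end / parent end
    rows = np.arange(i, sp)
    cols = np.arange(sp, e)
    a_r = (rows - i) / max(s - i, 1)
    a_c = (cols - sp) / max(j - sp, 1)
    in_A = a_c[None, :] >= a_r[:, None]
    rect = oe_sub[i:sp, sp:e]
    A = rect[in_A]
    B = rect[~in_A]
    c1 = oe_sub[i:sp, i:sp]
    c2 = oe_sub[sp:e, sp:e]
    C = c1[np.triu_indices(c1.shape[0], k=1)]
    D = c2[np.triu_indices(c2.shape[0], k=1)]
    drop = lambda v: v[np.isfinite(v)]
    return drop(A), drop(B), drop(C), drop(D)


def _one_tailed_greater(x, y, p_cut, delta_mean):
    if x.size < 3 or y.size < 3:
        return False, float("nan"), float("nan")
    p = stats.mannwhitneyu(x, y, alternative="greater").pvalue
    dm = float(x.mean() - y.mean())
    return (p < p_cut) and (dm > delta_mean), float(p), dm


def trim_tree(t: NestedDomainTree, oe, p_cut: float = 0.05,
              delta_mean: float = 0.1) -> NestedDomainTree:
    """Accept splits top-down; a split survives iff corner contacts (A) exceed
    between-children contacts (B) and both within-child regions (C, D) exceed
    B, each by a one-tailed Wilcoxon rank-sum test (p < ``p_cut``) with mean
    difference above ``delta_mean``.  Rejected splits prune their subtree."""
    oe_vals = oe.values if isinstance(oe, OEMatrix) else np.asarray(oe, float)
    n = t.domain_end - t.domain_start
    sub = oe_vals[:n, :n] if oe_vals.shape[0] == n else \
        oe_vals[t.domain_start:t.domain_end, t.domain_start:t.domain_end]

    def walk(node: NestedNode):
        if node.is_leaf:
            return
        A, B, C, D = _split_regions(sub, node)
        okA, pA, dA = _one_tailed_greater(A, B, p_cut, delta_mean)
        okC, pC, dC = _one_tailed_greater(C, B, p_cut, delta_mean)
        okD, pD, dD = _one_tailed_greater(D, B, p_cut, delta_mean)
        node.stats = {"p_corner": pA, "dmean_corner": dA,
                      "p_left": pC, "dmean_left": dC,
                      "p_right": pD, "dmean_right": dD}
        node.accepted = bool(okA and okC and okD)
        if node.accepted:
            walk(node.left)
            walk(node.right)

    walk(t.root)
    return t


def call_nested_domains(m: ContactMatrix, seg: DomainSegmentation,
                        min_bins: int = 2, p_cut: float = 0.05,
                        delta_mean: float = 0.1,
                        oe: OEMatrix | None = None) -> list:
    """Fit and trim a subdomain dendrogram inside every compartment domain of
    at least 4 bins; shorter domains are returned as bare leaves."""
    if oe is None:
        oe = observed_over_expected(m)
    trees = []
    for (s, e) in seg.domains:
        if e - s < 4:
            trees.append(NestedDomainTree(s, e, NestedNode(0, e - s), 0.0))
            continue
        t = best_dendrogram(m.values[s:e, s:e], min_bins=min_bins)
        t = NestedDomainTree(s, e, t.root, t.total_loglik)
        trim_tree(t, oe.values[s:e, s:e], p_cut=p_cut, delta_mean=delta_mean)
        trees.append(t)
    return trees
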