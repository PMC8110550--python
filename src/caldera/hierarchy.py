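"""Divisive clustering of compartment domains and consistent dendrogram
ordering.

Compartment domains are clustered purely by 3D proximity: binary trend
fingerprints of their interdomain contacts are correlated, embedded with
weighted principal components, and split recursively with 2-means.  The
dendrogram is then reordered (branch flips only) along the LOESS major axis
of the PC1/PC2 cloud so that the rightmost leaf is the most active domain,
yielding depth-3 sub-compartment labels (A.1.1 ... B.2.2) and normalized
ranks in (0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .hic_io import ContactMatrix
from .segmentation import DomainSegmentation, fisher_z

__all__ = [
    "TrendMatrix",
    "DomainEmbedding",
    "TreeNode",
    "DomainHierarchy",
    "domain_mean_contacts",
    "build_trend_matrix",
    "trend_similarity",
    "pc_embedding",
    "orient_pc1",
    "divisive_clustering",
    "order_dendrogram",
    "label_compartments",
    "assign_ranks",
    "gene_density_per_domain",
    "read_genes",
]

LABELS_8 = ["B.2.2", "B.2.1", "B.1.2", "B.1.1", "A.2.2", "A.2.1", "A.1.2", "A.1.1"]


@dataclass
class TrendMatrix:
    """Stacked binary contact-trend fingerprints; one column per domain."""

    values: np.ndarray
    m_max: int


@dataclass
class DomainEmbedding:
    """Principal-component scores of the trend-similarity matrix.

    ``scores`` are unweighted PC scores (k x n_pcs); ``weights`` rescale them
    for clustering (PC1 carries the compartment signal and keeps full weight).
    """

    scores: np.ndarray
    weights: np.ndarray
    pc1_oriented: bool = False

    @property
    def coords(self) -> np.ndarray:
        return self.scores * self.weights

    @property
    def k(self) -> int:
        return self.scores.shape[0]


class TreeNode:
    """Binary dendrogram node over domain indices."""

    __slots__ = ("members", "left", "right")

    def __init__(self, members, left=None, right=None):
        self.members = list(members)
        self.left = left
        self.right = right

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def leaves(self):
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def clades(self, out=None):
        if out is None:
            out = set()
        out.add(frozenset(self.members))
        if not self.is_leaf:
            self.left.clades(out)
            self.right.clades(out)
        return out

    def newick(self, names=None) -> str:
        def fmt(node):
            if node.is_leaf:
                i = node.members[0]
                return str(names[i]) if names is not None else f"D{i}"
            return f"({fmt(node.left)},{fmt(node.right)})"
        return fmt(self) + ";"


@dataclass
class DomainHierarchy:
    """Ordered dendrogram over compartment domains with labels and ranks."""

    tree: TreeNode
    leaf_order: np.ndarray          # domain indices, B end -> A end
    labels: list = None             # per domain index
    ranks: np.ndarray = None        # per domain index, in (0, 1]
    z: np.ndarray = None            # per domain projection score

    @property
    def k(self) -> int:
        return len(self.leaf_order)


# ---------------------------------------------------------------------------
# Trend matrix and its similarity


def domain_mean_contacts(m: ContactMatrix, seg: DomainSegmentation,
                         distance_normalized: bool = True) -> np.ndarray:
    """k x k matrix of mean contact values between bins of each domain pair.

    With ``distance_normalized`` (default) the means are taken on the
    observed/expected map, so that an entry above/below its partner reflects
    contact enrichment rather than genomic proximity.
    """
    from .hic_io import observed_over_expected

    vals = m.values
    if distance_normalized:
        vals = np.nan_to_num(observed_over_expected(m).values, nan=1.0)
    k = seg.k
    M = np.zeros((k, k))
    for a, (sa, ea) in enumerate(seg.domains):
        for b, (sb, eb) in enumerate(seg.domains[a:], start=a):
            M[a, b] = M[b, a] = vals[sa:ea, sb:eb].mean()
    return M


def build_trend_matrix(m: ContactMatrix | np.ndarray, seg: DomainSegmentation = None,
                       m_max: int | None = 4) -> TrendMatrix:
    """Binary contact-trend fingerprints summarizing the plaid pattern.

    For each lag ``m`` and sliding pair (j, j+m), column i records whether
    domain i contacts domain j+m more than domain j (1) or not (0); the lag
    blocks are stacked by rows.  Accepts either a contact matrix plus
    segmentation or a precomputed k x k mean-contact matrix.
    ``m_max=None`` uses every available lag for small k (<= 32 domains),
    where the extra comparisons carry real signal, and 4 otherwise.
    """
    M = m if isinstance(m, np.ndarray) else domain_mean_contacts(m, seg)
    k = M.shape[0]
    if m_max is None:
        m_max = k - 1 if k <= 32 else 4
    if k <= m_max:
        m_max = max(1, k - 1)
        warnings.warn(f"few domains: reducing m_max to {m_max}")
    blocks = []
    for lag in range(1, m_max + 1):
        block = np.zeros((k - lag, k))
        for j in range(k - lag):
            block[j] = (M[:, j + lag] > M[:, j]).astype(float)
        blocks.append(block)
    return TrendMatrix(values=np.vstack(blocks), m_max=m_max)


def trend_similarity(t: TrendMatrix) -> "SimilarityMatrix":
    """Fisher-z scores of the pairwise column correlations of the trend matrix."""
    from .segmentation import SimilarityMatrix

    T = t.values
    if T.shape[0] < 2 or T.shape[1] < 2:
        raise ValueError("trend matrix too small")
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(T.T)
    s = fisher_z(np.nan_to_num(rho, nan=0.0))
    s = (s + s.T) / 2.0
    return SimilarityMatrix(values=s, source="trend")


# ---------------------------------------------------------------------------
# Embedding, orientation, clustering


def pc_embedding(s, n_pcs: int = 10, w1: float = 1.0,
                 w_rest: float = 0.25,
                 z_cap: float = np.arctanh(0.95)) -> DomainEmbedding:
    """Weighted principal components of the trend-similarity matrix rows.

    Scores are winsorized at ``|z| = z_cap`` first: numerically saturated
    correlations (identical binary fingerprints reach the arctanh clip) would
    otherwise dominate the component directions.
    """
    X = s.values if hasattr(s, "values") else np.asarray(s, float)
    if z_cap is not None:
        X = np.clip(X, -z_cap, z_cap)
    k = X.shape[0]
    if k < 2:
        raise ValueError("need at least 2 domains")
    if n_pcs > k:
        warnings.warn(f"n_pcs reduced from {n_pcs} to {k}")
        n_pcs = k
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = (U * S)[:, :n_pcs]
    # deterministic sign: largest-|loading| coordinate of each PC positive
    for j in range(scores.shape[1]):
        col = Vt[j]
        i = np.argmax(np.abs(col))
        if col[i] < 0:
            scores[:, j] *= -1
    weights = np.full(scores.shape[1], w_rest)
    weights[0] = w1
    return DomainEmbedding(scores=scores, weights=weights)


def orient_pc1(e: DomainEmbedding, gene_density) -> DomainEmbedding:
    """Fix the arbitrary PC1 sign so that PC1 correlates positively with gene
    density (gene-dense = A side)."""
    if gene_density is None:
        raise ValueError(
            "gene density required to orient PC1; supply a gene annotation "
            "(per-domain gene density vector)")
    gd = np.asarray(gene_density, float)
    if gd.size != e.k:
        raise ValueError("gene_density length must equal the number of domains")
    scores = e.scores.copy()
    if np.std(gd) == 0 or np.std(scores[:, 0]) == 0:
        r = 0.0
    else:
        r = np.corrcoef(scores[:, 0], gd)[0, 1]
    if r < 0:
        scores[:, 0] *= -1
    elif r == 0:
        warnings.warn("PC1 uncorrelated with gene density; sign left unchanged")
    return DomainEmbedding(scores=scores, weights=e.weights.copy(),
                           pc1_oriented=True)


def _two_means(X: np.ndarray, seed: int, n_restarts: int):
    """Deterministic 2-means (Lloyd, multiple seeded restarts).

    Returns a boolean assignment; ties broken toward the partition whose
    first member index is lowest.
    """
    n = X.shape[0]
    if n == 2:
        return np.array([False, True])
    if np.allclose(X, X[0]):
        out = np.zeros(n, bool)
        out[0] = True
        return out
    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng((seed * 1009 + r * 9176) % (2**31))
        c_idx = rng.choice(n, size=2, replace=False)
        centers = X[c_idx].astype(float)
        lab = None
        for _ in range(100):
            d = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2)
            new_lab = d.argmin(axis=1)
            for c in (0, 1):  # re-seed an emptied cluster with the farthest point
                if not (new_lab == c).any():
                    far = d[:, 1 - c].argmax()
                    new_lab[far] = c
            if lab is not None and (new_lab == lab).all():
                break
            lab = new_lab
            for c in (0, 1):
                centers[c] = X[lab == c].mean(axis=0)
        wcss = sum(((X[lab == c] - centers[c]) ** 2).sum() for c in (0, 1))
        assign = lab == lab[0]  # cluster containing the first point = True
        key = (wcss, tuple(np.flatnonzero(~assign)))
        if best is None or key < best[0]:
            best = (key, assign)
    return best[1]


def divisive_clustering(e: DomainEmbedding, seed: int,
                        n_restarts: int = 10) -> TreeNode:
    """Top-down 2-means clustering of the weighted PC coordinates until every
    domain sits in its own leaf.  Deterministic given ``seed``."""
    X = e.coords
    counter = [0]

    def split(members):
        node_id = counter[0]
        counter[0] += 1
        if len(members) == 1:
            return TreeNode(members)
        sub = X[members]
        in_first = _two_means(sub, seed * 100003 + node_id, n_restarts)
        g1 = [m for m, f in zip(members, in_first) if f]
        g2 = [m for m, f in zip(members, in_first) if not f]
        return TreeNode(members, split(g1), split(g2))

    return split(list(range(e.k)))


# ---------------------------------------------------------------------------
# Ordering, labels, ranks


def _projection_z(e: DomainEmbedding, loess_span: float = 0.75) -> np.ndarray:
    """Per-domain score z: cumulative arc length of the domain projections
    along the LOESS major axis of the (weighted) PC1/PC2 cloud."""
    k = e.k
    coords = e.coords
    x = coords[:, 0]
    if k < 3 or e.scores.shape[1] < 2 or np.std(x) == 0:
        order = np.argsort(x, kind="stable")
        z = np.zeros(k)
        xs = x[order]
        z[order[1:]] = np.cumsum(np.abs(np.diff(xs)))
        return z
    y = coords[:, 1] if coords.shape[1] > 1 else np.zeros(k)
    fit = lowess(y, x, frac=loess_span, return_sorted=True)
    fx, fy = fit[:, 0], fit[:, 1]
    # drop duplicate x before interpolating the curve densely
    ux, uidx = np.unique(fx, return_index=True)
    vx = np.linspace(ux[0], ux[-1], max(50 * k, 200))
    vy = np.interp(vx, ux, fy[uidx])
    # project each domain to the nearest vertex of the densified curve
    d2 = (x[:, None] - vx[None]) ** 2 + (y[:, None] - vy[None]) ** 2
    vert = d2.argmin(axis=1)
    order = np.lexsort((np.arange(k), x, vert))
    # arc length along the curve up to each projection
    seglen = np.hypot(np.diff(vx), np.diff(vy))
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    pos = arc[vert]
    z = np.zeros(k)
    acc = 0.0
    for prev, cur in zip(order[:-1], order[1:]):
        acc += abs(pos[cur] - pos[prev])
        z[cur] = acc
    return z


def order_dendrogram(tree: TreeNode, e: DomainEmbedding,
                     loess_span: float = 0.75) -> DomainHierarchy:
    """Flip sibling branches so the right branch always has the greater mean
    projection score z; topology (clade set) is unchanged."""
    if not e.pc1_oriented:
        raise ValueError("orient PC1 against gene density before ordering")
    z = _projection_z(e, loess_span)

    def flip(node: TreeNode) -> TreeNode:
        if node.is_leaf:
            return TreeNode(node.members)
        left, right = flip(node.left), flip(node.right)
        if np.mean(z[left.members]) > np.mean(z[right.members]):
            left, right = right, left
        return TreeNode(left.members + right.members, left, right)

    ordered = flip(tree)
    leaf_order = np.array([lf.members[0] for lf in ordered.leaves()], dtype=int)
    h = DomainHierarchy(tree=ordered, leaf_order=leaf_order, z=z)
    h.labels = label_compartments(h)
    h.ranks = assign_ranks(h)
    return h


def label_compartments(h: DomainHierarchy, depth: int = 3) -> list:
    """Depth-``depth`` compartment labels from the top splits of the ordered
    tree: B/A at the root, then X.2 (left) / X.1 (right) at each level.

    Leaves reached above the requested depth repeat their extreme side
    ('1' on a right/A path, '2' on a left/B path).
    """
    k = h.k
    labels = [None] * k

    def assign(node: TreeNode, parts: list, last_right: bool):
        if len(parts) == depth or node.is_leaf:
            if node.is_leaf and len(parts) < depth:
                pad = ("1" if last_right else "2") if parts else "1"
                if not parts:
                    warnings.warn("single-leaf hierarchy labelled A.1.1")
                    parts = ["A"]
                parts = parts + [pad] * (depth - len(parts))
            label = parts[0] + "." + ".".join(parts[1:]) if depth > 1 else parts[0]
            for i in node.members:
                labels[i] = label
            return
        if not parts:
            assign(node.left, ["B"], False)
            assign(node.right, ["A"], True)
        else:
            assign(node.left, parts + ["2"], False)
            assign(node.right, parts + ["1"], True)

    assign(h.tree, [], True)
    return labels


def assign_ranks(h: DomainHierarchy) -> np.ndarray:
    """Normalized ranks o/k along the leaf order (1-based ordinal o from the
    inactive B end); the most active domain has rank 1."""
    k = h.k
    ranks = np.zeros(k)
    ranks[h.leaf_order] = np.arange(1, k + 1) / k
    return ranks


# ---------------------------------------------------------------------------
# Gene density


def read_genes(path) -> pd.DataFrame:
    """Read gene intervals from BED (3+ columns) or GTF ('gene' features)."""
    p = str(path)
    if p.endswith((".gtf", ".gff", ".gff3")):
        df = pd.read_csv(p, sep="\t", comment="#", header=None,
                         usecols=[0, 2, 3, 4],
                         names=["chrom", "feature", "start", "end"],
                         dtype={0: str})
        df = df[df["feature"] == "gene"]
        df["start"] = df["start"] - 1  # GTF is 1-based closed
        return df[["chrom", "start", "end"]].reset_index(drop=True)
    df = pd.read_csv(p, sep=r"\s+", comment="#", header=None, dtype={0: str})
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


def gene_density_per_domain(genes: pd.DataFrame, seg: DomainSegmentation,
                            m: ContactMatrix) -> np.ndarray:
    """Genes (TSS) per bin for each domain, on the retained-bin grid."""
    genes = genes[genes["chrom"].astype(str) == str(m.chrom)]
    starts = m.bin_starts
    counts = np.zeros(m.n_bins)
    if len(genes):
        tss = genes["start"].to_numpy()
        idx = np.searchsorted(starts, tss, side="right") - 1
        ok = (idx >= 0) & (tss < starts[np.clip(idx, 0, None)] + m.bin_size)
        np.add.at(counts, idx[ok], 1)
    return np.array([counts[s:e].mean() for s, e in seg.domains])
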