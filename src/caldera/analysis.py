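"""Cross-sample and annotation analytics for compartment hierarchies.

Covers compartment entropy (with a permutation null), boundary-level
classification, boundary overlap, A-B index boundaries, histone-mark and
region-state enrichment, the minimum-sufficient-compartment test, panel
clustering of samples, and interdomain contact shifts between conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy as sch

from .hic_io import OEMatrix
from .hierarchy import LABELS_8, TreeNode
from .segmentation import DomainSegmentation

__all__ = [
    "CompartmentPanel",
    "EntropyProfile",
    "compartment_entropy",
    "entropy_null",
    "classify_boundary_level",
    "boundary_overlap",
    "ab_index_boundaries",
    "marker_enrichment",
    "region_state_enrichment",
    "delta_mu",
    "min_sufficient_compartments",
    "cluster_samples",
    "interdomain_contact_shift",
]

_LABEL_RANK = {lab: i for i, lab in enumerate(LABELS_8)}  # B.2.2 = 0 (least active)


@dataclass
class CompartmentPanel:
    """Bins x samples matrix of 8-class compartment labels (and ranks)."""

    bins: pd.DataFrame              # chrom, start, end
    labels: pd.DataFrame            # bins x samples, entries in LABELS_8 or NaN
    ranks: pd.DataFrame = None      # bins x samples, reals in (0, 1]

    @property
    def n_samples(self) -> int:
        return self.labels.shape[1]


@dataclass
class EntropyProfile:
    entropy: np.ndarray             # per-bin S in [0, 1], NaN where no labels
    n_samples: np.ndarray           # labels used per bin


# ---------------------------------------------------------------------------
# Entropy


def _entropy_from_labels(lab_matrix: np.ndarray) -> tuple:
    """Row-wise normalized Shannon entropy of categorical labels (NaN-aware)."""
    n_bins = lab_matrix.shape[0]
    S = np.full(n_bins, np.nan)
    used = np.zeros(n_bins, dtype=int)
    log8 = np.log(8.0)
    for b in range(n_bins):
        row = lab_matrix[b]
        row = row[~pd.isna(row)]
        used[b] = row.size
        if row.size == 0:
            continue
        _, counts = np.unique(row, return_counts=True)
        p = counts / counts.sum()
        S[b] = float(-(p * np.log(p)).sum() / log8)
    return S, used


def compartment_entropy(p: CompartmentPanel) -> EntropyProfile:
    """Per-bin normalized Shannon entropy S_b = -(1/ln 8) sum_j P_j ln P_j of
    the 8-class label frequencies across samples (0*ln 0 := 0)."""
    if p.n_samples < 2:
        raise ValueError("entropy needs at least 2 samples")
    S, used = _entropy_from_labels(p.labels.to_numpy())
    return EntropyProfile(entropy=S, n_samples=used)


def entropy_null(p: CompartmentPanel, n_perm: int = 1000, seed: int = 0,
                 per_permutation: bool = False) -> np.ndarray:
    """Null chromatin-entropy distribution: each sample's label vector is
    permuted across bins independently, per permutation; per-bin entropies of
    all permutations are pooled.  With ``per_permutation`` the per-permutation
    mean entropies are returned instead (for empirical p-values)."""
    rng = np.random.default_rng(seed)
    lab = p.labels.to_numpy()
    n_bins, n_samples = lab.shape
    pooled, means = [], []
    for _ in range(n_perm):
        perm = np.empty_like(lab)
        for s in range(n_samples):
            perm[:, s] = lab[rng.permutation(n_bins), s]
        S, _ = _entropy_from_labels(perm)
        S = S[np.isfinite(S)]
        pooled.append(S)
        means.append(S.mean() if S.size else np.nan)
    return np.asarray(means) if per_permutation else np.concatenate(pooled)


# ---------------------------------------------------------------------------
# Boundaries


def classify_boundary_level(left_label, right_label, is_nested: bool = False):
    """Hierarchy distance of the domains flanking a boundary: 1 = A/B switch,
    2/3 = deeper digit switches, 'gt3' = identical labels, 'nested' when the
    boundary separates nested subdomains."""
    if is_nested:
        return "nested"
    if left_label is None or right_label is None or \
            (isinstance(left_label, float) and np.isnan(left_label)):
        return "unclassified"
    a = str(left_label).split(".")
    b = str(right_label).split(".")
    for lvl, (x, y) in enumerate(zip(a, b), start=1):
        if x != y:
            return lvl
    return "gt3"


def boundary_overlap(a, b, max_dist: float):
    """Fraction of boundaries in ``a`` with a boundary of ``b`` strictly
    closer than ``max_dist`` bp (greedy nearest matching, no reuse).

    Returns ``(fraction, matched_pairs)``; fraction is None for empty ``a``.
    """
    a = np.sort(np.asarray(a, float))
    b = np.sort(np.asarray(b, float))
    if a.size == 0:
        return None, []
    pairs = []
    if b.size:
        cand = [(abs(x - y), i, j) for i, x in enumerate(a)
                for j, y in enumerate(b) if abs(x - y) < max_dist]
        used_a, used_b = set(), set()
        for d, i, j in sorted(cand):
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            pairs.append((float(a[i]), float(b[j])))
    return len(pairs) / a.size, pairs


def ab_index_boundaries(oe, ab) -> np.ndarray:
    """Boundaries from sign switches of the A-B index.

    The A-B index of a bin is its mean distance-corrected (O/E) contact with
    A bins minus with B bins; boundaries fall between runs of opposite sign
    after interior single-bin runs are discarded as noise.  Returns boundary
    positions as the bin index right of each switch.
    """
    vals = oe.values if isinstance(oe, OEMatrix) else np.asarray(oe, float)
    ab = np.asarray(ab)
    a_idx = np.flatnonzero(ab == "A")
    b_idx = np.flatnonzero(ab == "B")
    if a_idx.size == 0 or b_idx.size == 0:
        raise ValueError("both A and B bins required")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        index = np.nanmean(vals[:, a_idx], axis=1) - \
            np.nanmean(vals[:, b_idx], axis=1)
    signs = np.where(index >= 0, 1, -1)
    runs = []  # (sign, length)
    for sgn in signs:
        if runs and runs[-1][0] == sgn:
            runs[-1][1] += 1
        else:
            runs.append([sgn, 1])
    # iteratively drop interior single-bin runs, merging equal neighbours
    changed = True
    while changed and len(runs) > 2:
        changed = False
        for i in range(1, len(runs) - 1):
            if runs[i][1] == 1:
                runs[i - 1][1] += runs[i][1] + runs[i + 1][1] \
                    if runs[i - 1][0] == runs[i + 1][0] else runs[i][1]
                if runs[i - 1][0] == runs[i + 1][0]:
                    del runs[i:i + 2]
                else:
                    del runs[i]
                changed = True
                break
    bounds, pos = [], 0
    for sgn, length in runs[:-1]:
        pos += length
        bounds.append(pos)
    return np.array(bounds, dtype=int)


# ---------------------------------------------------------------------------
# Enrichment


def marker_enrichment(track, seg: DomainSegmentation, labels) -> dict:
    """log2 ratio of the median per-domain mean signal within each 8-class
    compartment over the overall median; NaN for labels with no domain."""
    track = np.asarray(track, float)
    means = np.array([track[s:e].mean() for s, e in seg.domains])
    overall = np.median(means)
    out = {}
    labels = np.asarray(labels)
    for lab in LABELS_8:
        member = means[labels == lab]
        out[lab] = float(np.log2(np.median(member) / overall)) \
            if member.size else float("nan")
    return out


def _least_active(labs):
    return min(labs, key=lambda l: _LABEL_RANK.get(l, np.inf))


def region_state_enrichment(regions: pd.DataFrame, seg: DomainSegmentation,
                            labels, ranks, bin_size: int | None = None) -> pd.DataFrame:
    """Observed/expected compartment-label counts per region state.

    Each region inherits the label of its overlapping domain; regions covered
    by several domains take the least active label (closest to B.2.2) and the
    mean rank.  Expected counts come from genome-wide (bin-weighted) label
    frequencies; regions with no overlapping domain are discarded.
    """
    bs = bin_size or seg.bin_size
    labels = np.asarray(labels)
    ranks = np.asarray(ranks, float)
    dom_start = np.array([s * bs for s, _ in seg.domains])
    dom_end = np.array([e * bs for _, e in seg.domains])
    assigned = []
    for _, row in regions.iterrows():
        hit = np.flatnonzero((dom_start < row["end"]) & (dom_end > row["start"]))
        if hit.size == 0:
            continue
        assigned.append((row["state"], _least_active(labels[hit]),
                         float(ranks[hit].mean())))
    if not assigned:
        raise ValueError("no region overlaps any domain")
    df = pd.DataFrame(assigned, columns=["state", "label", "rank"])
    # genome-wide label frequency, weighted by domain length in bins
    lengths = np.array([e - s for s, e in seg.domains], float)
    freq = {lab: lengths[labels == lab].sum() / lengths.sum() for lab in LABELS_8}
    states = sorted(df["state"].unique())
    out = pd.DataFrame(index=states, columns=LABELS_8, dtype=float)
    for st in states:
        sub = df[df["state"] == st]
        n = len(sub)
        for lab in LABELS_8:
            expected = n * freq[lab]
            out.loc[st, lab] = (sub["label"] == lab).sum() / expected \
                if expected > 0 else float("nan")
    return out


# ---------------------------------------------------------------------------
# Number of sufficient compartments


def delta_mu(x, y, alpha: float = 0.001, tol: float = 1e-6) -> float:
    """Largest shift d such that mean(x) - d is still significantly greater
    than mean(y) (one-tailed Welch t-test at ``alpha``), found by bisection.

    Negative values mean the two samples are not separable at ``alpha``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per side")

    def pval(d):
        return stats.ttest_ind(x - d, y, equal_var=False,
                               alternative="greater").pvalue

    span = abs(x.mean() - y.mean()) + 10 * (x.std() + y.std() + 1.0)
    lo, hi = -span, span
    # p(d) increases with d; root of p(d) = alpha
    if pval(lo) >= alpha:
        return lo
    if pval(hi) < alpha:
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if pval(mid) < alpha:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _level_pairs(tree: TreeNode, level: int):
    """Sibling (left-leaves, right-leaves) pairs of internal nodes at depth
    ``level - 1`` (root = depth 0)."""
    pairs = []

    def walk(node, depth):
        if node.is_leaf:
            return
        if depth == level - 1:
            pairs.append((node.left.members, node.right.members))
            return
        walk(node.left, depth + 1)
        walk(node.right, depth + 1)

    walk(tree, 0)
    return pairs


def _default_gamma(level: int) -> float:
    n_comp = 2 ** level
    if n_comp <= 4:
        return 0.05
    if n_comp == 8:
        return 0.1
    return 0.2


def min_sufficient_compartments(tracks: dict, hierarchies: dict,
                                alpha: float = 0.001, gammas=None,
                                log_transform: bool = True,
                                max_level: int = 6) -> int:
    """Number of compartments sufficient to capture a track's variation.

    ``tracks`` maps chromosome -> per-domain mean signal (domain order
    matching the hierarchy); ``hierarchies`` maps chromosome ->
    :class:`DomainHierarchy`.  Values are ln(x+1)-transformed, then levels
    2, 4, 8, ... are tested: a level passes when every sibling pair has
    median per-chromosome effect size Δμ above the progressive threshold
    γ(level).  Returns the compartment count of the last passing level.
    """
    gamma_of = (lambda lv: gammas[lv]) if gammas else _default_gamma
    chroms = [c for c in hierarchies if c in tracks]
    if len(chroms) < 2:
        raise ValueError("need tracks on at least 2 chromosomes")
    data = {}
    for c in chroms:
        v = np.asarray(tracks[c], float)
        if v.size != hierarchies[c].k:
            warnings.warn(f"track on {c} does not match domains; skipped")
            continue
        data[c] = np.log1p(v) if log_transform else v

    n_ok = 1
    for level in range(1, max_level + 1):
        medians = []
        any_pair = False
        ok = True
        # pair index p is matched across chromosomes by label-path position
        per_pair = {}
        for c in data:
            for pi, (ml, mr) in enumerate(_level_pairs(hierarchies[c].tree, level)):
                xl, xr = data[c][ml], data[c][mr]
                if xl.size < 2 or xr.size < 2:
                    continue
                x, y = (xl, xr) if xl.mean() > xr.mean() else (xr, xl)
                per_pair.setdefault(pi, []).append(delta_mu(x, y, alpha=alpha))
        if not per_pair:
            break
        for pi, dmus in per_pair.items():
            any_pair = True
            if np.median(dmus) <= gamma_of(level):
                ok = False
                break
        if not any_pair or not ok:
            break
        n_ok = 2 ** level
    return n_ok


# ---------------------------------------------------------------------------
# Panel clustering and contact shifts


def cluster_samples(p: CompartmentPanel, n_clusters: int | None = None):
    """Average-linkage clustering of samples on label-Hamming distance.

    Distance between two samples = fraction of commonly covered bins with
    different 8-class labels; a pair with no commonly covered bins is an
    error.  Returns ``(linkage_matrix, flat_cluster_labels, distance_matrix)``.
    """
    lab = p.labels.to_numpy()
    n = lab.shape[1]
    if n < 2:
        raise ValueError("need at least 2 samples")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~(pd.isna(lab[:, i]) | pd.isna(lab[:, j]))
            if not both.any():
                raise ValueError(
                    f"samples {p.labels.columns[i]} and {p.labels.columns[j]} "
                    "share no covered bins")
            D[i, j] = D[j, i] = float(
                (lab[both, i] != lab[both, j]).mean())
    condensed = D[np.triu_indices(n, k=1)]
    Z = sch.linkage(condensed, method="average")
    flat = sch.fcluster(Z, t=n_clusters or 2, criterion="maxclust")
    return Z, flat, D


def interdomain_contact_shift(oe_a, oe_b, target, stable: dict) -> dict:
    """Distributions of mean distance-normalized contact between a target
    domain and label-stable domains, in two conditions.

    ``target`` is a (start, end) bin interval; ``stable`` maps compartment
    label -> list of (start, end) intervals present with that label in both
    conditions.  Returns label -> dict with per-condition value arrays and
    medians.
    """
    va = oe_a.values if isinstance(oe_a, OEMatrix) else np.asarray(oe_a, float)
    vb = oe_b.values if isinstance(oe_b, OEMatrix) else np.asarray(oe_b, float)
    ts, te = target
    out = {}
    for lab, domains in stable.items():
        if not domains:
            continue
        rows_a, rows_b = [], []
        for (s, e) in domains:
            block_a = va[ts:te, s:e]
            block_b = vb[ts:te, s:e]
            rows_a.append(float(np.nanmean(block_a)))
            rows_b.append(float(np.nanmean(block_b)))
        out[lab] = {
            "a": np.array(rows_a),
            "b": np.array(rows_b),
            "median_a": float(np.median(rows_a)),
            "median_b": float(np.median(rows_b)),
        }
    return out
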