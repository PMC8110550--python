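"""Synthetic plaid Hi-C maps, signal tracks and multi-sample panels with
planted ground truth.

The generator emulates the salient structure of real intrachromosomal maps:
power-law distance decay, compartment-driven (plaid) contact enrichment over
a planted depth-3 (8-class) activity hierarchy, Poisson counting noise,
optional zero inflation, and planted nested subdomain splits.  It does not
model loops, translocations or restriction-fragment effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hic_io import ContactMatrix
from .hierarchy import LABELS_8, DomainHierarchy, TreeNode
from .analysis import CompartmentPanel

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "simulate_contact_map",
    "simulate_track",
    "simulate_genes",
    "simulate_panel",
    "planted_hierarchy",
]


@dataclass
class SyntheticSpec:
    """Study conditions of a synthetic chromosome.

    Defaults mirror a mid-size chromosome binned at 40 kb with a planted
    8-class compartment hierarchy and a clearly visible plaid pattern.
    """

    n_bins: int = 500
    bin_size: int = 40_000
    n_domains: int = 10
    hierarchy_depth: int = 3
    decay_exponent: float = 1.0
    plaid_strength: float = 1.5
    sequencing_depth: float = 2e6
    zero_inflation: float = 0.05
    nested_fraction: float = 0.0
    overdispersion: float = 0.0     # 0 = Poisson; >0 adds gamma mixing
    seed: int = 0

    def __post_init__(self):
        if self.n_domains > self.n_bins:
            raise ValueError("n_domains must not exceed n_bins")
        for name in ("decay_exponent", "plaid_strength", "sequencing_depth"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must be in [0, 1)")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic map."""

    domains: list                   # (start, end) bin intervals
    labels: list                    # per-domain 8-class label
    activities: np.ndarray          # per-domain latent activity in [0, 1]
    nested_splits: dict             # domain index -> list of split bins (abs)
    bin_labels: np.ndarray          # per-bin label
    bin_activities: np.ndarray      # per-bin activity


def _n_classes(depth: int) -> int:
    return 2 ** depth


def _class_labels(depth: int) -> list:
    if depth == 3:
        return LABELS_8
    # generic least-to-most-active label paths
    labs = []
    for c in range(2 ** depth):
        bits = [(c >> (depth - 1 - i)) & 1 for i in range(depth)]
        parts = ["A" if bits[0] else "B"] + \
            [("1" if b else "2") for b in bits[1:]]
        labs.append(".".join(parts) if depth > 1 else parts[0])
    return labs


def _plant_domains(spec: SyntheticSpec, rng) -> GroundTruth:
    n, k = spec.n_bins, spec.n_domains
    min_len = max(4, n // (4 * k))
    # random domain lengths with a minimum size
    w = rng.dirichlet(np.ones(k) * 3.0)
    lengths = np.maximum((w * (n - k * min_len)).astype(int), 0) + min_len
    lengths[-1] += n - lengths.sum()
    edges = np.concatenate([[0], np.cumsum(lengths)])
    domains = [(int(edges[i]), int(edges[i + 1])) for i in range(k)]

    n_cls = _n_classes(spec.hierarchy_depth)
    labels_all = _class_labels(spec.hierarchy_depth)
    # cover all classes when possible, forbid identical adjacent classes so
    # every planted boundary is a real compartment switch
    for _ in range(1000):
        classes = list(rng.permutation(n_cls))[:min(k, n_cls)]
        while len(classes) < k:
            classes.append(int(rng.integers(n_cls)))
        classes = [int(c) for c in rng.permutation(classes)]
        if all(classes[i] != classes[i + 1] for i in range(k - 1)):
            break
    activities = (np.array(classes) + 0.5) / n_cls
    labels = [labels_all[c] for c in classes]

    bin_labels = np.empty(n, dtype=object)
    bin_act = np.zeros(n)
    for (s, e), lab, act in zip(domains, labels, activities):
        bin_labels[s:e] = lab
        bin_act[s:e] = act

    nested = {}
    n_nested = int(round(spec.nested_fraction * k))
    eligible = [i for i, (s, e) in enumerate(domains) if e - s >= 8]
    for di in list(rng.permutation(eligible))[:n_nested]:
        s, e = domains[di]
        split = int(rng.integers(s + 3, e - 3))
        nested[int(di)] = [split]
    return GroundTruth(domains=domains, labels=labels, activities=activities,
                       nested_splits=nested, bin_labels=bin_labels,
                       bin_activities=bin_act)


def simulate_contact_map(spec: SyntheticSpec):
    """Draw a symmetric Poisson contact map over planted compartments.

    Intensity: lambda_ij ~ (1+|i-j|)^(-decay) * exp(kappa * (1 - |a_i - a_j|)),
    globally scaled so the expected upper-triangle total equals
    ``sequencing_depth``; planted nested splits enrich within-child blocks by
    x1.5.  Returns ``(ContactMatrix, GroundTruth)``.
    """
    rng = np.random.default_rng(spec.seed)
    gt = _plant_domains(spec, rng)
    n = spec.n_bins
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    decay = (1.0 + dist) ** (-spec.decay_exponent)
    a = gt.bin_activities
    plaid = np.exp(spec.plaid_strength * (1.0 - np.abs(a[:, None] - a[None, :])))
    lam = decay * plaid
    for di, splits in gt.nested_splits.items():
        s, e = gt.domains[di]
        for sp in splits:
            lam[s:sp, s:sp] *= 1.5
            lam[sp:e, sp:e] *= 1.5
    iu = np.triu_indices(n)
    scale = spec.sequencing_depth / lam[iu].sum()
    lam *= scale
    if not np.isfinite(lam).all() or lam.max() > 1e12:
        raise ValueError("infeasible sequencing depth: intensity overflow")
    mean = lam[iu]
    if spec.overdispersion > 0:
        shape = 1.0 / spec.overdispersion
        mean = rng.gamma(shape, mean / shape)
    counts = rng.poisson(mean).astype(float)
    if spec.zero_inflation > 0:
        counts[rng.random(counts.size) < spec.zero_inflation] = 0.0
    M = np.zeros((n, n))
    M[iu] = counts
    M = M + np.triu(M, 1).T
    cm = ContactMatrix(chrom="chrS", bin_size=spec.bin_size, values=M)
    return cm, gt


def simulate_track(gt: GroundTruth, effect: float, noise_sd: float,
                   seed: int, log_scale: bool = False) -> np.ndarray:
    """Per-bin signal driven by the planted activity.

    Linear scale (default): value = effect * activity + N(0, noise_sd),
    truncated at 0.  With ``log_scale``, value = exp(effect * activity +
    N(0, noise_sd)) - 1, so that ln(1+x) has class means ``effect/n_classes``
    apart with Gaussian noise of sd ``noise_sd``.
    """
    if effect < 0:
        raise ValueError("effect must be >= 0")
    rng = np.random.default_rng(seed)
    base = effect * gt.bin_activities + rng.normal(0, noise_sd,
                                                   gt.bin_activities.size)
    if log_scale:
        return np.expm1(base)
    return np.maximum(base, 0.0)


def simulate_genes(gt: GroundTruth, bin_size: int, base_rate: float = 0.2,
                   slope: float = 2.0, seed: int = 0,
                   chrom: str = "chrS") -> pd.DataFrame:
    """Gene intervals with density increasing with activity (A-side denser)."""
    rng = np.random.default_rng(seed)
    counts = rng.poisson(base_rate + slope * gt.bin_activities)
    rows = []
    for b, c in enumerate(counts):
        for g in range(c):
            start = b * bin_size + int(rng.integers(0, max(bin_size - 1000, 1)))
            rows.append((chrom, start, start + 1000))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def planted_hierarchy(gt: GroundTruth) -> DomainHierarchy:
    """Ground-truth :class:`DomainHierarchy` implied by the planted labels.

    Builds the balanced label tree down to the planted depth and chains
    same-class domains below it (synthetic reference object for validating
    the analytics, not an inference result).
    """
    # group domain indices by class, classes ordered least -> most active
    by_class = {}
    for i, lab in enumerate(gt.labels):
        by_class.setdefault(lab, []).append(i)
    ordered_labs = sorted(by_class, key=_label_key)

    def chain(members):
        if len(members) == 1:
            return TreeNode(members)
        return TreeNode(members, TreeNode([members[0]]), chain(members[1:]))

    def build(labs):
        if len(labs) == 1:
            return chain(by_class[labs[0]])
        half = len(labs) // 2
        left = build(labs[:half])
        right = build(labs[half:])
        return TreeNode(left.members + right.members, left, right)

    root = build(ordered_labs)
    leaf_order = np.array([lf.members[0] for lf in root.leaves()], dtype=int)
    k = len(leaf_order)
    ranks = np.zeros(k)
    ranks[leaf_order] = np.arange(1, k + 1) / k
    return DomainHierarchy(tree=root, leaf_order=leaf_order,
                           labels=list(gt.labels), ranks=ranks,
                           z=gt.activities.copy())


def _label_key(lab: str):
    parts = str(lab).split(".")
    key = 0
    for p in parts:
        key = key * 2 + (1 if p in ("A", "1") else 0)
    return key


def simulate_panel(spec: SyntheticSpec, n_samples: int,
                   reposition_rate_by_class: dict, seed: int):
    """Multi-sample label panel with class-dependent repositioning.

    Sample 1 carries the base planted labels; every further sample
    independently reassigns each domain's label with its class's reposition
    rate, drawing the new label from the adjacent activity classes.
    Returns ``(CompartmentPanel, list_of_per_sample_bin_labels)``.
    """
    rng = np.random.default_rng(seed)
    base_rng = np.random.default_rng(spec.seed)
    gt = _plant_domains(spec, base_rng)
    n_cls = _n_classes(spec.hierarchy_depth)
    labels_all = _class_labels(spec.hierarchy_depth)
    cls_of = {lab: c for c, lab in enumerate(labels_all)}
    for lab, rate in reposition_rate_by_class.items():
        if not 0 <= rate <= 1:
            raise ValueError("reposition rates must lie in [0, 1]")

    sample_bin_labels = []
    columns = {}
    for s in range(n_samples):
        dom_labels = list(gt.labels)
        if s > 0:
            for di, lab in enumerate(dom_labels):
                rate = reposition_rate_by_class.get(lab, 0.0)
                if rng.random() < rate:
                    c = cls_of[lab]
                    neigh = [c - 1, c + 1]
                    neigh = [x for x in neigh if 0 <= x < n_cls]
                    dom_labels[di] = labels_all[int(rng.choice(neigh))]
        binlab = np.empty(spec.n_bins, dtype=object)
        for (st, en), lab in zip(gt.domains, dom_labels):
            binlab[st:en] = lab
        sample_bin_labels.append(binlab)
        columns[f"sample_{s}"] = binlab

    bins = pd.DataFrame({
        "chrom": "chrS",
        "start": np.arange(spec.n_bins) * spec.bin_size,
        "end": (np.arange(spec.n_bins) + 1) * spec.bin_size,
    })
    labels_df = pd.DataFrame(columns)
    rank_of = {lab: (c + 1) / n_cls for c, lab in enumerate(labels_all)}
    ranks_df = labels_df.apply(lambda col: col.map(rank_of))
    panel = CompartmentPanel(bins=bins, labels=labels_df, ranks=ranks_df)
    return panel, (gt, sample_bin_labels)
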