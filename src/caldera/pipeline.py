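"""Per-chromosome orchestration of the three inference steps and file output.

The pipeline runs, for every (autosomal) chromosome: sparse-bin filtering ->
balancing (KR with VC fallback) -> column aggregation (bins < 40 kb) ->
similarity -> compartment-domain segmentation -> trend fingerprints ->
weighted PC embedding -> gene-density orientation -> divisive clustering ->
ordering/labels/ranks -> nested subdomains, and writes BED / Newick / TSV
outputs plus the resolved configuration.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hic_io, hierarchy, nested, segmentation
from .analysis import CompartmentPanel, _least_active
from .hic_io import ContactMatrix, KRConvergenceError

log = logging.getLogger("caldera")

__all__ = ["RunConfig", "ChromosomeResult", "run_chromosome", "run_calder",
           "build_panel", "read_annotation_bed"]

MIN_CHROM_BINS = 20
AGGREGATION_BIN_SIZE = 40_000


@dataclass
class RunConfig:
    """Resolved parameters of a full run; serialized next to the outputs."""

    contacts: str | dict = None         # path, or chrom -> ContactMatrix
    format: str = "dense"
    chromosomes: list = None
    bin_size: int = 40_000
    normalization: str = "kr"           # kr | vc | none
    zero_fraction: float = 0.99
    autosomes_only: bool = True
    window_bins: int = 5
    p_cut: float = 0.05
    min_domain_bins: int = 2
    n_pcs: int = 10
    pc1_weight: float = 1.0
    pc_rest_weight: float = 0.25
    m_max: int | None = None   # None: every lag when few domains, else 4
    loess_span: float = 0.75
    nested_min_bins: int = 2
    nested_p_cut: float = 0.05
    delta_mean: float = 0.1
    seed: int = 0
    genes: str = None
    out_dir: str = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(d.get("contacts"), dict):
            d["contacts"] = sorted(d["contacts"])
        return d


@dataclass
class ChromosomeResult:
    chrom: str
    matrix: ContactMatrix
    segmentation: segmentation.DomainSegmentation
    hierarchy: hierarchy.DomainHierarchy
    nested_trees: list
    normalization_used: str
    contact_density: float


def _chrom_seed(seed: int, chrom: str) -> int:
    return (seed * 7919 + zlib.crc32(chrom.encode())) % (2 ** 31)


def run_chromosome(cm: ContactMatrix, gene_density_bins, cfg: RunConfig
                   ) -> ChromosomeResult:
    """Full three-step inference on one chromosome.

    ``gene_density_bins`` is a per-original-bin gene count/density vector
    used to orient PC1 (A side = gene dense).
    """
    cm = hic_io.filter_sparse_bins(cm, cfg.zero_fraction)
    if cm.n_bins < MIN_CHROM_BINS:
        raise ValueError(f"{cm.chrom}: fewer than {MIN_CHROM_BINS} retained bins")
    norm_used = "raw"
    if cfg.normalization == "kr":
        try:
            cm = hic_io.kr_balance(cm)
            norm_used = "KR"
        except KRConvergenceError:
            log.warning("%s: KR failed to converge; falling back to VC", cm.chrom)
            cm = hic_io.vc_balance(cm)
            norm_used = "VC"
    elif cfg.normalization == "vc":
        cm = hic_io.vc_balance(cm)
        norm_used = "VC"
    elif cfg.normalization != "none":
        raise ValueError(f"unknown normalization {cfg.normalization!r}")
    density = hic_io.contact_density(cm)

    if cm.bin_size < AGGREGATION_BIN_SIZE:
        agg = hic_io.aggregate_columns(cm, factor=10)
    else:
        agg = hic_io.AggregatedMatrix(cm.values, 1, cm.bin_size)
    sim = segmentation.similarity_from_contacts(agg)
    seg = segmentation.call_compartment_domains(
        sim, window_bins=cfg.window_bins, min_domain_bins=cfg.min_domain_bins,
        p_cut=cfg.p_cut, chrom=cm.chrom, bin_size=cm.bin_size)

    trend = hierarchy.build_trend_matrix(cm, seg, m_max=cfg.m_max)
    st = hierarchy.trend_similarity(trend)
    emb = hierarchy.pc_embedding(st, n_pcs=cfg.n_pcs, w1=cfg.pc1_weight,
                                 w_rest=cfg.pc_rest_weight)
    gd = np.asarray(gene_density_bins, float)
    if gd.size == cm.retained.size:
        gd = gd[cm.retained]
    if gd.size != cm.n_bins:
        raise ValueError("gene density vector does not match the bin grid")
    per_domain_gd = np.array([gd[s:e].mean() for s, e in seg.domains])
    emb = hierarchy.orient_pc1(emb, per_domain_gd)
    tree = hierarchy.divisive_clustering(emb, seed=_chrom_seed(cfg.seed, cm.chrom))
    hier = hierarchy.order_dendrogram(tree, emb, loess_span=cfg.loess_span)
    trees = nested.call_nested_domains(
        cm, seg, min_bins=cfg.nested_min_bins, p_cut=cfg.nested_p_cut,
        delta_mean=cfg.delta_mean)
    return ChromosomeResult(cm.chrom, cm, seg, hier, trees, norm_used, density)


# ---------------------------------------------------------------------------
# Output


def domain_bed(res: ChromosomeResult) -> pd.DataFrame:
    """Compartment-domain BED: label as name, rank x 1000 as score, rank in
    column 7 (0-based half-open coordinates)."""
    cm, seg, hier = res.matrix, res.segmentation, res.hierarchy
    starts = cm.bin_starts
    rows = []
    for di, (s, e) in enumerate(seg.domains):
        rows.append((cm.chrom, int(starts[s]),
                     int(starts[e - 1]) + cm.bin_size,
                     hier.labels[di], int(round(hier.ranks[di] * 1000)), ".",
                     round(float(hier.ranks[di]), 6)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand", "rank"])


def nested_bed(res: ChromosomeResult) -> pd.DataFrame:
    cm = res.matrix
    starts = cm.bin_starts
    rows = []
    for di, tree in enumerate(res.nested_trees):
        for (s, e) in tree.accepted_leaves():
            rows.append((cm.chrom, int(starts[s]),
                         int(starts[e - 1]) + cm.bin_size, f"domain_{di}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "parent_id"])


def split_stats_tsv(res: ChromosomeResult) -> pd.DataFrame:
    rows = []

    def walk(di, node):
        if node.is_leaf:
            return
        st = node.stats or {}
        rows.append({"domain": di, "start": node.start, "end": node.end,
                     "split": node.split, "accepted": node.accepted,
                     "loglik": node.loglik, **st})
        if node.accepted:
            walk(di, node.left)
            walk(di, node.right)

    for di, tree in enumerate(res.nested_trees):
        walk(di, tree.root)
    return pd.DataFrame(rows)


def _load_matrices(cfg: RunConfig) -> dict:
    if isinstance(cfg.contacts, dict):
        return dict(cfg.contacts)
    if cfg.contacts is None:
        raise ValueError("no contact input configured")
    chroms = cfg.chromosomes or ["chr1"]
    path = Path(cfg.contacts)
    out = {}
    for chrom in chroms:
        p = path if path.is_file() else path / f"{chrom}.txt"
        out[chrom] = hic_io.read_contact_map(p, cfg.format, chrom, cfg.bin_size)
    return out


def run_calder(cfg: RunConfig, gene_density: dict | None = None) -> dict:
    """Run the full pipeline; returns chrom -> :class:`ChromosomeResult` and,
    when ``cfg.out_dir`` is set, writes BED/Newick/TSV outputs and the
    resolved config.

    ``gene_density`` maps chrom -> per-bin density vector; alternatively
    ``cfg.genes`` names a BED/GTF annotation.
    """
    matrices = _load_matrices(cfg)
    genes_df = None
    if gene_density is None:
        if cfg.genes is None:
            raise ValueError(
                "gene annotation required to orient PC1: pass gene_density or "
                "set the --genes option")
        genes_df = hierarchy.read_genes(cfg.genes)

    results = {}
    for chrom in sorted(matrices):
        if cfg.autosomes_only and not hic_io.is_autosome(chrom):
            log.info("%s: skipped (not an autosome)", chrom)
            continue
        cm = matrices[chrom]
        if gene_density is not None:
            gd = gene_density[chrom]
        else:
            counts = np.zeros(cm.retained.size)
            sub = genes_df[genes_df["chrom"].astype(str) == str(chrom)]
            if len(sub):
                idx = (sub["start"].to_numpy() // cm.bin_size)
                idx = idx[(idx >= 0) & (idx < counts.size)]
                np.add.at(counts, idx, 1)
            gd = counts
        try:
            res = run_chromosome(cm, gd, cfg)
        except Exception as e:  # a failing chromosome aborts only itself
            log.warning("%s: skipped (%s)", chrom, e)
            continue
        log.info("%s: %s normalization, density %.3f, %d domains",
                 chrom, res.normalization_used, res.contact_density,
                 res.segmentation.k)
        results[chrom] = res

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        beds = [domain_bed(r) for r in results.values()]
        if beds:
            pd.concat(beds).to_csv(out / "compartment_domains.bed", sep="\t",
                                   header=False, index=False)
            pd.concat([nested_bed(r) for r in results.values()]).to_csv(
                out / "nested_domains.bed", sep="\t", header=False, index=False)
            stats = [split_stats_tsv(r).assign(chrom=c)
                     for c, r in results.items()]
            pd.concat(stats).to_csv(out / "nested_split_stats.tsv", sep="\t",
                                    index=False)
        with open(out / "hierarchies.nwk", "w") as fh:
            for chrom, r in results.items():
                names = [f"{chrom}:{s}-{e}" for s, e in r.segmentation.domains]
                fh.write(f"{chrom}\t{r.hierarchy.tree.newick(names)}\n")
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    return results


# ---------------------------------------------------------------------------
# Panel assembly


def read_annotation_bed(path) -> pd.DataFrame:
    """Read a compartment annotation BED (chrom, start, end, label[, score,
    strand], rank)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 4:
        raise ValueError(f"{path}: need at least 4 BED columns")
    cols = ["chrom", "start", "end", "label"]
    if df.shape[1] >= 7:
        df = df.iloc[:, [0, 1, 2, 3, 6]]
        cols.append("rank")
    elif df.shape[1] >= 5:
        df = df.iloc[:, :5]
        cols.append("rank")
    else:
        df = df.iloc[:, :4]
    df.columns = cols
    if "rank" not in df:
        df["rank"] = np.nan
    return df


def build_panel(bed_paths, grid_bin_size: int = 40_000) -> CompartmentPanel:
    """Resample per-sample compartment BEDs onto a common bin grid.

    Each grid bin takes the bp-majority label (ties -> least active label)
    and the overlap-weighted mean rank.
    """
    samples = {}
    for p in bed_paths:
        samples[Path(str(p)).stem] = read_annotation_bed(p)
    if not samples:
        raise ValueError("no annotation files given")
    chrom_max = {}
    for df in samples.values():
        for chrom, end in df.groupby("chrom")["end"].max().items():
            chrom_max[chrom] = max(chrom_max.get(chrom, 0), int(end))
    bins = []
    for chrom in sorted(chrom_max):
        n = -(-chrom_max[chrom] // grid_bin_size)
        for b in range(n):
            bins.append((chrom, b * grid_bin_size, (b + 1) * grid_bin_size))
    bins_df = pd.DataFrame(bins, columns=["chrom", "start", "end"])
    key = {(c, s): i for i, (c, s, _) in enumerate(bins)}

    labels = pd.DataFrame(index=range(len(bins)), columns=list(samples),
                          dtype=object)
    ranks = pd.DataFrame(index=range(len(bins)), columns=list(samples),
                         dtype=float)
    for name, df in samples.items():
        votes = {}
        for row in df.itertuples(index=False):
            b0 = int(row.start) // grid_bin_size
            b1 = -(-int(row.end) // grid_bin_size)
            for b in range(b0, b1):
                gi = key.get((row.chrom, b * grid_bin_size))
                if gi is None:
                    continue
                ov = min(row.end, (b + 1) * grid_bin_size) - \
                    max(row.start, b * grid_bin_size)
                if ov <= 0:
                    continue
                d = votes.setdefault(gi, {})
                lab_bp, rk_sum = d.get(row.label, (0, 0.0))
                rk = 0.0 if pd.isna(row.rank) else float(row.rank)
                d[row.label] = (lab_bp + ov, rk_sum + ov * rk)
        for gi, d in votes.items():
            top = max(v[0] for v in d.values())
            winner = _least_active([l for l, v in d.items() if v[0] == top])
            labels.at[gi, name] = winner
            total_bp = sum(v[0] for v in d.values())
            ranks.at[gi, name] = sum(v[1] for v in d.values()) / total_bp
    return CompartmentPanel(bins=bins_df, labels=labels, ranks=ranks)
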