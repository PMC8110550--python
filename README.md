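# caldera

Multi-scale inference of chromatin compartment domains and sub-compartments
from intrachromosomal Hi-C contact maps.

Chromosomes partition into two broad spatial compartments: active,
gene-dense **A** and repressed, lamina-proximal **B**. Finer
sub-compartments exist, but most methods that resolve them need extremely
deep sequencing or interchromosomal contacts. `caldera` infers a complete
hierarchy of compartment domains from intrachromosomal contacts alone, in
three steps:

1. **Compartment domain calling.** The whole-chromosome contact profile of
   each bin is converted into a correlation-of-correlation similarity matrix
   (Fisher z-transformed, `sA = arctanh(rho2A)`), and the chromosome is
   segmented at statistically supported local minima of a TopDom-style
   diamond bin-signal computed on `sA`.
2. **Sub-compartment hierarchy.** Domains are clustered purely by 3D
   proximity: binary *trend* fingerprints record, for each domain, whether
   its contact enrichment rises or falls across sliding pairs of partner
   domains; the fingerprints are correlated, embedded with weighted
   principal components (PC1 carries the A/B axis and keeps weight 1, all
   other PCs 0.25), and split recursively with 2-means. Branch flips along
   the LOESS major axis of the PC1/PC2 cloud order the dendrogram from the
   most inactive (left) to the most active (right) leaf. The top three
   split levels yield 8 sub-compartment labels `B.2.2 … A.1.1`; each domain
   also receives a normalized rank `o/k` in `(0, 1]` (1 = most active).
3. **Nested subdomains.** Within each domain, contacts between candidate
   sibling subdomains are modelled with a zero-inflated log-normal
   `p_mix(x) = alpha*p0(x) + (1-alpha)*logN(mu, sigma)`; dynamic programming
   finds the genome-anchored dendrogram maximizing the summed sibling-pair
   log-likelihood in O(n^3), and splits are trimmed with one-tailed Wilcoxon
   tests (p < 0.05 and mean O/E difference > 0.1) on the observed/expected
   matrix.

Cross-sample analytics are included: per-bin compartment entropy
`S_b = -(1/ln 8) * sum_j P_j ln P_j` with a label-permutation null,
boundary-level classification, boundary overlap, A-B index boundaries,
histone-mark and chromatin-state enrichment, the minimum number of
compartments needed to explain an epigenetic track, panel clustering of
samples, and interdomain contact shifts between conditions. A synthetic
plaid-Hi-C generator with planted ground truth (power-law distance decay,
compartment-driven contact enrichment, Poisson noise, zero inflation,
optional nested splits) makes everything testable without downloads.

## Worked example

```python
import numpy as np
from caldera import (SyntheticSpec, simulate_contact_map, simulate_genes,
                     RunConfig, run_chromosome)

spec = SyntheticSpec(seed=1)            # 500 bins x 40 kb, 10 domains
cm, truth = simulate_contact_map(spec)
genes = simulate_genes(truth, spec.bin_size, seed=1)
density = np.zeros(cm.retained.size)
np.add.at(density, genes["start"].to_numpy() // spec.bin_size, 1)

res = run_chromosome(cm, density, RunConfig(seed=1))
print(res.normalization_used, res.segmentation.k)
print(res.segmentation.boundaries)
print([s for s, _ in truth.domains[1:]])
print(res.hierarchy.labels[:4], np.round(res.hierarchy.ranks[:4], 2))
```

prints

```
KR 10
[ 58 116 190 228 286 336 371 410 460]
[58, 116, 190, 228, 286, 336, 371, 410, 460]
['B.2.2', 'A.1.1', 'B.1.1', 'B.2.1'] [0.2 1.  0.4 0.3]
```

— the ten planted compartment domains are recovered exactly (all nine
boundaries at the planted bin), each with an 8-class sub-compartment label
and a rank; ranks near 1 mark the most active (A.1.1-like) domains.

The same pipeline is available from the shell:

```bash
caldera run --contacts chr1.txt --format dense --chrom chr1 \
        --bin-size 40000 --genes genes.bed --out results/ --seed 1
caldera simulate --spec spec.yaml --out sim/
caldera entropy --beds annotations/ --out entropy.tsv --n-perm 1000 --seed 1
caldera compare --beds annotations/ --out compare/
```

`caldera run` writes compartment domains as BED (label, rank x 1000 as the
score, full-precision rank in column 7), nested domains as BED with a
`parent_id` column, per-split statistics as TSV, dendrograms as Newick, and
the resolved configuration as YAML.

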