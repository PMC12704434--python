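# panbgc

Pangenome-style analysis of biosynthetic gene cluster (BGC) families.

Bacterial specialized metabolites — antibiotics, siderophores, pigments —
are encoded by BGCs: physically co-located groups of genes covering
biosynthesis, export and regulation. Tools such as BiG-SLiCE and BiG-SCAPE
group similar BGCs into gene cluster families (GCFs). `panbgc` picks up
where that clustering stops: it treats one GCF as a *population* of
related clusters, the way pangenomics treats a bacterial species as a
population of genomes, and asks how much internal diversity the family
holds and where that diversity comes from.

For a family whose genes have been partitioned into ortholog groups (OGs),
the package:

- builds the **BGC × OG copy-number matrix** and classifies every OG as
  **core** (present in ≥ threshold of members; 100 % by default),
  **accessory** (some but not all) or **unique** (a single member);
- reconstructs the **core BGC** (the conserved scaffold) and the
  **maximum BGC** (every OG observed anywhere in the family), both in a
  consensus gene order derived from orientation-normalized member orders;
- quantifies **openness** with three permutation-based accumulation
  metrics fitted to Heaps' law

  $$y = k \cdot x^{\gamma}$$

  where *x* is the number of members sampled and *y* the cumulative count
  of distinct OGs (*gene-repertoire* openness), distinct OG combinations
  (*composition* openness) or newly appearing OGs (*novel-gene*
  openness). Curves are averaged over 30 sampling permutations (exhaustive
  enumeration when n! ≤ 30), fitted by log–log regression, weighted
  log–log regression and bounded non-linear least squares, and the fit
  with the highest linear-scale R² supplies γ. Families are binned as
  **closed** (γ < 0.3), **intermediate** (0.3 ≤ γ ≤ 0.6) or **open**
  (γ > 0.6); a Kruskal–Wallis rank test compares γ distributions between
  metrics or family groups;
- measures gene-tree vs cluster-tree discordance as a **tanglegram
  crossing count** (inversion number of the induced leaf permutation);
- ships a **greedy single-linkage ortholog grouper** (global-alignment
  identity with a length-ratio gate) so the whole pipeline runs from
  GenBank files alone, plus a **synthetic family generator** with known
  ground truth for testing and calibration.

Inputs are antiSMASH- or MIBiG-dialect GenBank region files, optionally
with a ZOL-style ortholog table (TSV: `og_id  bgc_id  gene_id`); the main
output is a structured JSON summary per family.

## Worked example

```python
from panbgc import (SyntheticGCFSpec, analyze_openness,
                    build_presence_absence, generate_gcf)

spec = SyntheticGCFSpec(n_bgcs=12, core_size=8, accessory_pool_size=4,
                        accessory_prob=0.5, unique_rate=0.0, seed=21)
matrix = build_presence_absence(generate_gcf(spec))
result = analyze_openness(matrix, n_permutations=30, seed=1)
for metric in ("gene_repertoire", "composition"):
    mr = result.metrics[metric]
    print(f"{metric:16s} gamma={mr.best.gamma:6.3f} k={mr.best.k:6.2f} "
          f"R2={mr.best.r2:.4f} ({mr.best.method}) -> {mr.category}")
```

prints

```
gene_repertoire  gamma= 0.044 k= 10.90 R2=0.8946 (nls) -> closed
composition      gamma= 0.651 k=  1.20 R2=0.9974 (nls) -> open
```

This family reshuffles a fixed pool of genes: its total repertoire
saturates almost immediately (γ ≈ 0.04, closed — sampling more members
finds almost no new genes), yet new *combinations* of those genes keep
appearing (γ ≈ 0.65, open). That split — closed repertoire, open
composition — is the signature that modular reshuffling rather than gene
acquisition drives diversity within the family. The `examples/` directory
holds one short script per capability (classification, openness,
reconstruction, grouping from GenBank, tanglegrams), each printing and
explaining its numbers.

A command-line interface wraps the same library:

```bash
panbgc analyze --gcf-dir my_family/ --permutations 30 --seed 1 --out summary.json
panbgc group   --gcf-dir my_family/ --identity 0.5 --coverage 0.7 --out ogs.tsv
panbgc tangle  --left bgc_tree.nwk --right gene_tree.nwk
```

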