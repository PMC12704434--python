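"""Quantify family openness with permutation accumulation curves.

Compares two contrasting families: one where members reshuffle a fixed
gene pool (closed repertoire, high compositional diversity) and one where
every member brings novel genes (open repertoire). For each metric the
mean accumulation curve over 30 sampling permutations is fitted to Heaps'
law y = k*x^gamma by three methods; the best linear-scale R^2 wins and
gamma is binned: < 0.3 closed, 0.3-0.6 intermediate, > 0.6 open.
"""

from panbgc import (
    SyntheticGCFSpec,
    analyze_openness,
    build_presence_absence,
    generate_gcf,
)

families = {
    "reshuffling (fixed pool)": SyntheticGCFSpec(
        n_bgcs=12, core_size=8, accessory_pool_size=4, accessory_prob=0.5,
        unique_rate=0.0, seed=21,
    ),
    "innovating (fresh genes)": SyntheticGCFSpec(
        n_bgcs=12, core_size=2, accessory_pool_size=0, unique_rate=3.0, seed=21,
    ),
}

for label, spec in families.items():
    matrix = build_presence_absence(generate_gcf(spec))
    result = analyze_openness(matrix, n_permutations=30, seed=1)
    print(f"\n{label}:")
    for metric in ("gene_repertoire", "composition"):
        mr = result.metrics[metric]
        print(
            f"  {metric:16s} gamma={mr.best.gamma:6.3f} k={mr.best.k:6.2f} "
            f"R2={mr.best.r2:.4f} ({mr.best.method}) -> {mr.category}"
        )

# In the reshuffling family the repertoire saturates (small gamma, closed)
# while gene combinations keep appearing (large composition gamma): the
# signature that modular reshuffling, not gene acquisition, drives
# within-family diversity.
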