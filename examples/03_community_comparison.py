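"""Multivariate comparison of diet among areas and years.

Fourth-root transformed gravimetric prey matrices are compared with
Bray-Curtis dissimilarity: a two-way PERMANOVA partitions variation into
area and year effects with permutation p-values, the five sub-areas are
clustered by group-average linkage, and stomach fullness is compared among
length groups with Kruskal-Wallis / Dunn tests.
"""

import warnings

import numpy as np

import dietstat as ds

dataset = ds.generate(ds.GeneratorConfig(seed=11, years=(2011, 2012), n_stations=3))
matrix = ds.build_diet_matrix(dataset.stomachs, dataset.stations)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # empty stomachs give all-zero rows
    D = ds.bray_curtis(ds.fourth_root(matrix.weight))

res = ds.permanova_twoway(
    D,
    matrix.labels["area"].to_numpy(),
    matrix.labels["year"].to_numpy(),
    n_perm=999,
    seed=1,
    names=("Area", "Year"),
)
print("Two-way PERMANOVA (stomach-level Bray-Curtis on fourth-root weights):")
print(res.table.round(3).to_string(index=False))

pooled = ds.pool_matrix(matrix, "area")
tree = ds.upgma(ds.bray_curtis(ds.fourth_root(pooled)))
print("\nArea dendrogram (group-average linkage):", ds.to_newick(tree))
for h, s in zip(tree.merges[:, 2], tree.similarity_percent()):
    print(f"  merge at Bray-Curtis distance {h:.3f}  ({s:.0f}% similarity)")

fullness = np.array(
    [s.stomach_weight for s in dataset.stomachs if not s.is_empty]
)
groups = np.array(
    [ds.assign_length_group(s.length) for s in dataset.stomachs if not s.is_empty]
)
h, p = ds.kruskal_wallis(fullness, groups)
print(f"\nStomach weight by length group: Kruskal-Wallis H = {h:.1f}, p = {p:.3f}")
if p < 0.05:
    print(ds.dunns_posthoc(fullness, groups).round(3).to_string(index=False))
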