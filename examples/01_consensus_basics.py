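"""Boolean target-matrix algebra on a tiny hand-built example.

Two binding studies over a five-gene universe: study A calls {G1, G2},
study B calls {G2, G3}.  We build the gene x study matrix, compare the
studies by Hamming similarity, list the exclusive (UpSet-style)
intersections, and take k-of-n consensus sets.
"""

from fkhconsensus import (
    GeneUniverse,
    StudyDataset,
    build_target_matrix,
    exclusive_intersections,
    hamming_similarity,
    k_of_n_consensus,
)

universe = GeneUniverse(("G1", "G2", "G3", "G4", "G5"))
studies = [
    StudyDataset("A", "FKH1", frozenset({"G1", "G2"})),
    StudyDataset("B", "FKH1", frozenset({"G2", "G3"})),
]

matrix = build_target_matrix(studies, universe)
print("target matrix (1 = called a target):")
print(matrix.to_frame().to_string(index=False))

sim = hamming_similarity(matrix)
print("\nHamming similarity (fraction of genes on which two studies agree):")
print(sim.round(2).to_string())
print("-> A and B agree on G2 (both true) and G4, G5 (both false): 3/5 = 0.6")

table = exclusive_intersections(matrix)
print("\nexclusive intersections (genes in exactly this study subset):")
for row in table.itertuples():
    print(f"  {'&'.join(row.subset):6s}  n={row.count}  {','.join(row.genes)}")
print("-> counts sum to |A ∪ B| =", int(table['count'].sum()))

print("\nconsensus sets:")
print("  k=1 (union):       ", sorted(k_of_n_consensus(matrix, 1)))
print("  k=2 (intersection):", sorted(k_of_n_consensus(matrix, 2)))
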