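"""Do HicA toxin domains cluster by class on a distance tree?

Generates 10 sequences for each of 10 emulated HicA classes (each class
has its own sub-ancestor; members diverge by up to 25% per site), builds
a pairwise-identity distance matrix and a neighbor-joining tree, and
reports nearest-neighbor class purity: the fraction of sequences whose
closest relative belongs to the same class (1.0 = perfect clustering).
"""

from hicascan.phylogeny import class_purity, distance_matrix, nj_tree, write_newick
from hicascan.simulate import hica_class_benchmark

seqs, labels = hica_class_benchmark(7)
dm = distance_matrix(seqs)
purity = class_purity(dm, labels)
tree = nj_tree(dm)

print(f"{len(seqs)} HicA domain sequences, {len(set(labels.values()))} classes")
print(f"mean pairwise distance: {dm.d[dm.d > 0].mean():.3f}")
print(f"nearest-neighbor class purity: {purity:.3f}")
newick = write_newick(tree)
print(f"NJ tree: {len(newick)} chars of Newick, starts {newick[:60]}...")
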