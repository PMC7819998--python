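"""Write a benchmark to disk and run the shell pipeline on it.

The generator emits plain-text files (edge-list TSV, GMT, truth JSON)
that round-trip through the package's loaders — the same formats a user
would supply for a real interactome and real disease gene sets.  The
equivalent command-line session is printed at the end.
"""

from netsep import default_benchmark_spec, load_gene_sets, load_interactome, write_benchmark

spec = default_benchmark_spec(seed=4, n_nodes=500, attachment=2)
paths = write_benchmark(spec, "scratch/benchmark_example")

g = load_interactome(paths["edges"])
sets = load_gene_sets(paths["gmt"])
print(f"interactome: {g.number_of_nodes()} nodes, {g.number_of_edges()} edges")
for s in sets:
    print(f"  gene set {s.name:8s} {len(s)} members")

print(
    "\nSame pipeline from a shell:\n"
    "  netsep simulate --nodes 500 --attachment 2 --seed 4 --out bench/\n"
    "  netsep localize  --interactome bench/interactome.tsv --gene-sets bench/modules.gmt --out loc/\n"
    "  netsep separate  --interactome bench/interactome.tsv --gene-sets bench/modules.gmt --out sep/\n"
    "  netsep diseasome --interactome bench/interactome.tsv --gene-sets bench/modules.gmt --out dz/"
)
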