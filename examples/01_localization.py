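"""Module localization: is a gene set clumped in the interactome?

Builds a synthetic 2,000-node interactome, plants one connected module
of 30 genes, and tests whether that module is denser / more connected
than degree-matched random sets.  Small p-values on all three metrics
mean the set forms a genuine network module rather than a scatter of
unrelated proteins.
"""

from netsep import (
    generate_interactome,
    localization_significance,
    map_gene_set,
    plant_module,
)

g = generate_interactome(n=2000, m=3, seed=1)
gene_set = plant_module(g, size=30, cohesion=1.0, seed=1, name="planted")
module = map_gene_set(g, gene_set)

result = localization_significance(g, module, replicates=1000, seed=1)

print(f"module {result.module!r}: {len(module)} genes, R={result.replicates}")
for metric, sig in result.metrics.items():
    print(
        f"  {metric:12s} observed={sig.observed:6.1f}  "
        f"null={sig.null_mean:6.2f}±{sig.null_sd:5.2f}  "
        f"z={sig.z:6.2f}  p={sig.p:.3g}"
    )
print(
    "\nEach z compares the observed metric with 1000 degree-matched random "
    "sets;\nthe one-tailed p is the chance a random set scores at least as high."
)
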