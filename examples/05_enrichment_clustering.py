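"""GO over-representation with semantic clustering and x-value selection.

Fisher (hypergeometric) enrichment of a module against a toy annotation,
the three-criterion redundancy filter, DBSCAN clustering of enriched terms
by a hybrid semantic distance, and selection of each cluster's
representative by x-value = -log10(p) x (summed per-gene BIC score).
"""

import numpy as np
import pandas as pd

from chronode import (AnnotationSet, fisher_enrichment, reduce_redundancy,
                      distance_matrix, cluster_terms)

rng = np.random.default_rng(5)
universe = [f"g{i:03d}" for i in range(400)]
module = set(universe[:60])

# three near-duplicate terms describing the module, plus unrelated terms
term_genes = {
    "GO:0001": set(universe[:40]),
    "GO:0002": set(universe[5:45]),
    "GO:0003": set(universe[10:50]),
    "GO:0100": set(rng.choice(universe, 50, replace=False)),
    "GO:0200": set(universe[200:260]),
}
ann = AnnotationSet(term_genes=term_genes, universe=universe)
scores = pd.Series(rng.uniform(10, 60, len(universe)), index=universe)

terms = fisher_enrichment(module, ann, p_cutoff=0.01, gene_scores=scores)
terms = reduce_redundancy(terms)
print(f"enriched terms after redundancy filter: {[t.term for t in terms]}")

clusters = cluster_terms(terms, distance_matrix(terms, ann))
for cl in clusters:
    members = ", ".join(t.term for t in cl.members)
    rep = cl.representative
    print(f"cluster {cl.cluster_id}: [{members}] -> representative {rep.term} "
          f"(p={rep.p_value:.2e}, sum BIC={rep.sigma_bic:.0f}, x={rep.xvalue:.0f})")
# The three overlapping terms collapse into one cluster whose spokesperson
# is the term with the largest x-value, i.e. the best mix of significance
# and differential-expression weight of its genes.
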