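"""Build the all-sample coexpression network: pairwise Pearson r on
log2(CPM + 1), Fisher-z p-values, Benjamini-Hochberg FDR, and the
|r| > 0.98 / FDR < 0.02 edge selection.

Run:  python examples/02_coexpression_network.py
"""

import numpy as np
import pandas as pd

from rewirenet import network_edges
from rewirenet.io import ExpressionMatrix, Unit

# 15 tightly co-regulated gene pairs among 170 independent noise genes,
# log-scale expression across 17 animals
rng = np.random.default_rng(1)
rows, ids = [], []
for k in range(15):
    base = rng.normal(size=17)
    rows += [base, 1.4 * base + 0.2]
    ids += [f"pair{k}a", f"pair{k}b"]
for j in range(170):
    rows.append(rng.normal(size=17))
    ids.append(f"noise{j:03d}")
em = ExpressionMatrix(
    pd.DataFrame(rows, index=ids, columns=[f"animal{i}" for i in range(17)]),
    Unit.LOG2_CPM,
)

edges = network_edges(em, r_threshold=0.98, fdr_threshold=0.02)
n_pos = int((edges.sign == "+").sum())
print(f"{len(edges)} significant edges ({n_pos} positive, {len(edges) - n_pos} negative)")
print(edges.head().to_string(index=False))
print("\nEach edge is a gene pair whose abundance moves together across every")
print("animal at the strict |r| > 0.98 cut; all 15 planted pairs are found")
print("and the 14,000+ noise pairs contribute none.")
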