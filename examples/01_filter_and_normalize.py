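"""Load a two-layer count fixture, filter lowly expressed features and
subset to the biotype of interest.

Run:  python examples/01_filter_and_normalize.py
"""

import numpy as np

from rewirenet import compute_cpm, filter_expressed, subset_biotype
from rewirenet.simulate import null_spec, simulate_dataset

# a fixture with a wide abundance distribution so the filter has work to do
ds = simulate_dataset(
    null_spec(n_genes=800, n_mirna=120, seed=0,
              baseline_log_mean=np.log(5), baseline_log_sd=2.5,
              mirna_log_mean=np.log(5), mirna_log_sd=2.5)
)

# CPM on the raw matrix (full library sizes), then the expression filter:
# mRNA keeps features with >= 2 CPM in >= 5 samples, miRNA uses >= 1 CPM
mrna = filter_expressed(compute_cpm(ds.mrna), ds.mrna, min_cpm=2, min_samples=5)
mrna = subset_biotype(mrna, ds.annotation, "protein_coding")
mirna = filter_expressed(compute_cpm(ds.mirna), ds.mirna, min_cpm=1, min_samples=5)

print(f"mRNA layer:  {ds.mrna.n_features} raw -> {mrna.n_features} expressed protein-coding")
print(f"miRNA layer: {ds.mirna.n_features} raw -> {mirna.n_features} expressed")
print("Counts surviving both filters feed every downstream stage;")
print("features failing them are too noisy to support correlation or NB tests.")
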