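"""Simulate a four-domain tissue slice and identify its spatial domains.

Generates a 20x20 grid of spots with four banded domains, ten marker
genes per domain, log-normal noise and 20% dropout, then runs the full
pipeline: preprocessing, spatial KNN graph, joint network denoising,
tensor feature extraction, affinity learning and Leiden clustering.
"""

import numpy as np

from stacn import SyntheticSpec, generate_slice, run_pipeline
from stacn.metrics import ari, nmi, morans_i

slice_ = generate_slice(SyntheticSpec(seed=1))
print(f"slice: {slice_.n_cells} spots x {slice_.n_genes} genes, "
      f"{len(np.unique(slice_.labels))} planted domains")

result = run_pipeline(slice_, k_target=4, seed=1)
asn = result.assignment

print(f"found {asn.n_domains} domains at Leiden resolution {asn.resolution:.2f}")
print(f"ARI vs planted labels: {ari(slice_.labels, asn.labels):.3f}")
print(f"NMI vs planted labels: {nmi(slice_.labels, asn.labels):.3f}")
print(f"Moran's I of the learned features over the spatial graph: "
      f"{morans_i(result.features, result.spatial):.3f}")

# ARI/NMI of 1.0 would be a perfect recovery of the planted domains;
# values above ~0.9 mean essentially all spots are assigned to the right
# band. A positive Moran's I says the learned features vary smoothly in
# space, as tissue domains should.
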