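"""Watch the network noise model recover planted subspace structure.

Cells drawn from three independent low-dimensional subspaces are
self-representable only by members of their own subspace. The solver is
given the raw feature matrix and its gram as the two views; a correct
solve concentrates each cell's representation weights inside its own
cluster and leaves the l2,1 noise term empty (the data are noiseless).
"""

import numpy as np

from stacn import DenoiseConfig, admm_solve, generate_subspace_data

D, labels = generate_subspace_data(
    n_per_cluster=10, n_clusters=3, ambient_dim=30, sub_dim=3, noise_sd=0.0, seed=1
)
S = D.T @ D  # second view: similarity structure of the same cells

res = admm_solve(D, S, DenoiseConfig(lambda_noise=10.0, d=10))
We = np.abs(res.state.We)

mass = [
    We[labels == labels[c], c].sum() / We[:, c].sum() for c in range(We.shape[1])
]
Dn = D / np.linalg.norm(D, axis=0).mean()
noise_ratio = np.linalg.norm(res.state.Ee) / np.linalg.norm(res.state.Pe @ Dn)

print(f"converged: {res.converged} after {res.state.iter} iterations")
print(f"within-cluster weight mass: min {min(mass):.3f}, mean {np.mean(mass):.3f}")
print(f"noise fraction ||E_e|| / ||P_e D||: {noise_ratio:.4f}")

# A within-cluster mass near 1 means the learned expression network is
# block-diagonal over the planted clusters — the self-representation
# core works. A noise fraction near 0 confirms that clean data are not
# misattributed to the sparse noise term.
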