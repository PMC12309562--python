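"""A/B compartment eigenvector selection by gene density.

Constructs a two-compartment (checkerboard) correlation structure and shows
the selection rule: among the first five principal components, take the
first whose sign-split has a gene-density ratio >= 1.5, signed so the more
gene-dense (A) side is positive.
"""

import numpy as np

from telsprite.compartments import select_compartment_pc

labels = np.repeat([1, -1, 1, -1], 25)  # planted compartments, 100 bins
rng = np.random.default_rng(0)
corr = 0.5 * np.outer(labels, labels)
jitter = rng.normal(0, 0.1, corr.shape)
corr = corr + (jitter + jitter.T) / 2
np.fill_diagonal(corr, 1.0)

genes = np.where(labels > 0, 3.0, 1.0)  # A side 3x gene-denser

res = select_compartment_pc(corr, genes)
agreement = np.mean(np.sign(res.eigenvector) == labels)
print(f"selected PC index: {res.pc_index}")
print(f"gene-density ratio at selection: {res.gene_density_ratio:.2f} "
      f"(cutoff met: {res.met_cutoff})")
print(f"sign agreement with planted compartments: {agreement:.1%}")
print(f"mean eigenvector on gene-dense side: "
      f"{res.eigenvector[labels > 0].mean():+.3f} (positive = A)")
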