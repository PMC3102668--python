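"""Compare libraries by Pearson correlation of log2(TPM+1) and cluster them.

Average-linkage agglomeration on distance 1 - r groups libraries with similar
transcriptional programs; the tree exports as Newick for any viewer.
"""

import numpy as np
import pandas as pd

from dgetag import correlation_matrix, hierarchical_cluster

rng = np.random.default_rng(3)
base_early = rng.lognormal(3, 1.5, 800)
base_late = rng.lognormal(3, 1.5, 800)

def noisy(v):
    return v * rng.lognormal(0, 0.2, len(v))

tpm = pd.DataFrame({
    "LR_early": noisy(base_early), "LT_early": noisy(base_early),
    "LR_late": noisy(base_late), "LT_late": noisy(base_late),
})

corr = correlation_matrix(tpm)
print(corr.round(3).to_string())
print()
print(hierarchical_cluster(corr))

# Libraries sharing a developmental program (early vs late) correlate highest
# and merge first in the tree, regardless of condition label.
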