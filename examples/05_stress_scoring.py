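"""Score samples for a gene signature and classify stress-high/low.

Builds a toy expression table where two of five samples overexpress the
signature, computes ssGSEA scores with permutation p-values, and applies
the p < 0.05 (high) / p > 0.5 (low) rule.
"""

import numpy as np
import pandas as pd

from primus import classify_stress, permutation_p, ssgsea

rng = np.random.default_rng(3)
genes = [f"g{i}" for i in range(120)]
signature = genes[:15]
expr = pd.DataFrame(
    rng.gamma(2.0, 1.0, size=(120, 5)),
    index=genes,
    columns=[f"sample_{i}" for i in range(5)],
)
expr.loc[signature, ["sample_0", "sample_1"]] *= 6.0  # stressed samples

scores = ssgsea(expr, signature)
pvals = permutation_p(expr, signature, n_perm=1000, seed=9)
labels = classify_stress(pvals)
print(pd.DataFrame({"score": scores.round(3), "p": pvals.round(4), "label": labels}))
# samples 0 and 1 should score highest and be called stress-high; the
# rest get large permutation p-values and are called stress-low.
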