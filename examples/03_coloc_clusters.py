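"""Regulatory clusters: shared vs distinct causal signals.

Builds two association traces with a strong signal at the same variant
(expected: high PP(H4), one shared signal) and two with signals at
different variants (expected: PP(H3) dominates, i.e. two distinct
signals in one region), then groups genes by H4 >= 0.8.
"""

import numpy as np
import pandas as pd

from eqtlkit import coloc_abf
from eqtlkit.clusters import RegulatoryCluster, colocalize_cluster, group_coregulated


def trace(z_at, m=60, z=8.0):
    zvec = np.zeros(m)
    zvec[z_at] = z
    se = np.full(m, 0.1)
    return pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "slope": zvec * se,
            "slope_se": se,
            "nominal_p": 1.0,
        }
    )


shared = coloc_abf(trace(17), trace(17), gene_a="A", gene_b="B")
distinct = coloc_abf(trace(5), trace(50), gene_a="A", gene_b="C")
print(f"same causal variant:    PP(H4) = {shared.pp_h4:.3f}")
print(f"different variants:     PP(H3) = {distinct.pp_h3:.3f}, PP(H4) = {distinct.pp_h4:.3f}")

cluster = RegulatoryCluster(
    chrom="7", start=100, end=500, variant_ids=["v17"], gene_ids=["A", "B", "C"]
)
colocalize_cluster(cluster, {"A": trace(17), "B": trace(17), "C": trace(50)})
group_coregulated(cluster)
print(f"cluster {cluster.cluster_id}: co-regulated groups = {cluster.groups}")
# genes A and B share one causal variant and form a group; C carries an
# independent signal in the same region and stays out.
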