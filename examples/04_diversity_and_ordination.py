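"""Alpha/beta diversity and PCA on OTN patterns, plus the exact U test.

Reproduces the published between-group comparison: one-sided exact
Mann-Whitney U on the printed Shannon/inverse-Simpson triplicates of the
earthworm vs non-earthworm soil libraries, then shows the same statistics on
simulated pattern tables together with chord-distance beta diversity and a
centered PCA ordination.
"""

import numpy as np

from otnalign import (
    SimConfig,
    chord_distance_matrix,
    diversity_report,
    end_to_end_fixture,
    mann_whitney_exact,
    otn_pipeline,
    pca_ordination,
    preprocess_samples,
)

# Published alpha-diversity triplicates (earthworm-exposed vs unexposed):
earthworm_h, control_h = [5.49, 5.41, 5.48], [5.61, 5.55, 5.52]
earthworm_d, control_d = [120.2, 94.68, 117.6], [143.3, 147.1, 151.5]
for name, (a, b) in {"Shannon H": (earthworm_h, control_h),
                     "inverse Simpson D": (earthworm_d, control_d)}.items():
    u, p = mann_whitney_exact(a, b, alternative="less")
    print(f"{name:18s}: U = {u:g}, one-sided exact p = {p:g}")
print("Complete separation of two triplicates gives p = 1/20 = 0.05 exactly:")
print("the unexposed soil is the more diverse in both indices.\n")

fx = end_to_end_fixture(SimConfig(n_taxa=6, reads_per_taxon=20, seed=5,
                                  edge_gen_range=(1e8, 4e8)))
clean, _ = preprocess_samples(fx.samples)
res = otn_pipeline(clean)

# pool the six single-taxon libraries into two composite communities
counts = res.patterns.counts
libraries = counts[["T1", "T2", "T3"]].sum(axis=1).to_frame("cladeA")
libraries["cladeB"] = counts[["T4", "T5", "T6"]].sum(axis=1)

per_sample, _ = diversity_report(libraries)
print("diversity of two composite simulated communities:")
print(per_sample[["shannon_h", "inverse_simpson_d"]].round(3).to_string())

beta = chord_distance_matrix(libraries)
print(f"\nchord distances range {beta.values.max():.3f} max "
      f"(sqrt(2)={np.sqrt(2):.3f} = fully disjoint communities)")

ordination = pca_ordination(res.patterns.patterns.astype(float))
k = ordination.n_components
print(f"PCA: {k} component(s) cover "
      f"{100 * ordination.explained_variance_ratio[:k].sum():.1f}% of variance")
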