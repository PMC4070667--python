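"""Homopolymer sequencing errors and the multiplicity-discharge rule.

Simulates reads with increasing 454-style homopolymer indel rates and shows
that the errors are predominantly absorbed by discharging the affected OTN
columns rather than by inventing spurious new patterns.
"""

from otnalign import SimConfig, end_to_end_fixture, otn_pipeline, preprocess_samples

for rate in (0.0, 0.3, 0.9):
    cfg = SimConfig(n_taxa=4, reads_per_taxon=15, homopolymer_indel_rate=rate,
                    seed=21, edge_gen_range=(1e8, 4e8))
    fx = end_to_end_fixture(cfg)
    clean, _ = preprocess_samples(fx.samples)
    res = otn_pipeline(clean)
    print(f"indel rate {rate:.1f}: {len(res.matrix.discharged):4d} OTNs discharged, "
          f"{res.patterns.n_patterns_total:3d} patterns "
          f"({res.patterns.n_singletons} singletons), "
          f"{len(fx.truth.errors)} indels injected")

print()
print("Discharged-OTN counts grow with the error rate: a trinucleotide that")
print("an indel duplicates inside one bin is removed globally, which costs")
print("some signal but prevents homopolymer noise from inflating distances.")
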