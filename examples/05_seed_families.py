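"""Group sequences by their 7-nt seed and score each family's similarity.

The seed (positions 2-8 of the mature sequence) defines target recognition;
members of a seed family are expected to be far more similar than average.
The report lists, per family, the mean pairwise distance, its percentile
under the all-miRNA KDE law, and the rank-sum p-value.
"""

from mirdist import SimConfig, distance_matrix, family_report, fit_kde, make_dataset

records = make_dataset(
    [
        SimConfig(n_sequences=12, divergence=0.12, seed_motif="GAGGUAG", rng_seed=11),
        SimConfig(n_sequences=3, divergence=0.14, seed_motif="GGAAUGU", rng_seed=12),
        SimConfig(n_sequences=3, divergence=0.0, seed_motif="GGAAGAC", rng_seed=13),
        SimConfig(n_sequences=40, rng_seed=14),
    ]
)
jc = distance_matrix(records, model="JC")
values = jc.defined_values()
ref = fit_kde(values[values > 0])

for comp in family_report(records, {"JC": jc}, {"JC": ref}):
    s = comp.per_model["JC"]
    print(
        f"seed {comp.label}: {len(comp.members)} members, "
        f"mean {s.mean:.4f} ({s.percentile:.2f}th percentile), "
        f"rank-sum p = {s.ranksum_p:.3g}"
    )
# The zero-divergence family prints mean 0 at a sub-5 percentile; background
# sequences have unique seeds and never form a family.
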