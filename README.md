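# mirdist

Pairwise-distance distributions of human mature miRNAs: substitution-model
distances, distribution fitting with Kolmogorov–Smirnov model selection, and
biomarker-set similarity.

## The problem

Mature miRNAs are ~22-nt regulatory RNAs. Panels of miRNA biomarkers are
used to study associations between diseases, and the *pairwise distance*
between miRNA sequences is the workhorse measure of their closeness. To say
whether a panel's mean distance is "small", one needs the distribution of
pairwise distances over all human miRNAs — which is what this package
derives and uses. The reference setting is the 567 *Homo sapiens* miRNA
genes of [MirGeneDB 2.1](https://mirgenedb.org/), whose mature sequences
yield 62,435 defined Jukes–Cantor and 17,519 defined Kimura distances.

## The models and the method

For an aligned sequence pair, with gaps handled by pairwise deletion, let
`L` be the number of compared sites, `X` the differing sites,
`X1`/`X2` the transitional (A↔G, C↔U) / transversional differences, and
`p̂ = X/L`, `P̂ = X1/L`, `Q̂ = X2/L`. The two distances are

```
K1 = -(3/4) ln(1 - (4/3) p̂)                      (Jukes–Cantor)
K2 = (1/2) ln(1/(1-2P̂-Q̂)) + (1/4) ln(1/(1-2Q̂))   (Kimura two-parameter)
```

each defined only while its log arguments stay positive; violating pairs
are recorded as `n/c`. The JC distance carries the approximate sampling
variance `V(K1) = (p̂-p̂²)/(L(1-4p̂/3)²)`.

The defined distances are then fitted by four laws — `N(μ,σ²)`,
`Gamma(α,β)` (shape/scale, MLE), the piecewise-linearly smoothed empirical
CDF `F̂ₙ`, and a Gaussian-kernel density estimate
`f̂ₕ(x) = (1/nh) Σ φ((x-xᵢ)/h)` — and compared by repeatedly drawing a
moderate sample (m = 70, R = 500 repetitions) from each fitted law and
two-sample-KS-testing it against the observed distances; the averaged
p-value ranks the families. A biomarker panel or seed family (sequences
sharing nucleotides 2–8) is then scored by the percentile `100·cdf(mean)`
of its mean distance under the preferred (KDE) law, plus a Wilcoxon
rank-sum comparison of its distances against all distances.

## Worked example

```python
from mirdist import (SimConfig, distance_matrix, family_report, fit_kde,
                     make_dataset)

records = make_dataset([
    SimConfig(n_sequences=12, divergence=0.12, seed_motif="GAGGUAG", rng_seed=11),
    SimConfig(n_sequences=3,  divergence=0.14, seed_motif="GGAAUGU", rng_seed=12),
    SimConfig(n_sequences=3,  divergence=0.0,  seed_motif="GGAAGAC", rng_seed=13),
    SimConfig(n_sequences=40, rng_seed=14),        # unrelated background
])
jc = distance_matrix(records, model="JC")
values = jc.defined_values()
ref = fit_kde(values[values > 0])
for comp in family_report(records, {"JC": jc}, {"JC": ref}):
    s = comp.per_model["JC"]
    print(f"seed {comp.label}: {len(comp.members)} members, "
          f"mean {s.mean:.4f} ({s.percentile:.2f}th percentile), "
          f"rank-sum p = {s.ranksum_p:.3g}")
```

prints

```
seed GAGGUAG: 12 members, mean 0.0516 (2.80th percentile), rank-sum p = 4.21e-37
seed GGAAGAC: 3 members, mean 0.0000 (2.22th percentile), rank-sum p = 0.00265
seed GGAAUGU: 3 members, mean 0.1697 (4.14th percentile), rank-sum p = 0.0098
```

Each simulated seed family sits in the far-left tail of the all-pairs
distance law (percentiles ≪ 50) and its distances differ significantly from
the overall distribution — the same signature real seed families show.
Unrelated background sequences never form a family, and roughly half of
their pairs are undefined (`n/c`) because unrelated 22-mers differ at ~75%
of sites, the JC boundary.

The `examples/` directory holds one short script per capability
(simulation & distance matrices, distribution fitting, goodness-of-fit
ranking, biomarker panels, seed families). A thin CLI mirrors the same
stages: `mirdist simulate | distances | fit | evaluate | percentiles |
compare-set | family-report` (see `mirdist --help`).

## Reference data

The full-scale reference inputs are not redistributed here. To run the
reference-data acceptance tests, place under `data/reference/`:

* `jc_distances.csv`, `k2p_distances.csv` — long-format distance tables
  (`label_a,label_b,distance`, undefined cells `n/c`) for the 567
  MirGeneDB 2.1 human mature miRNAs;
* `hsa_mature.fasta` — their mature sequences;
* optionally `biomarker_mapping.csv` (`printed_name,gene_label`) fixing the
  panel-name → gene-label mapping.

Printed biomarker panels are included as plain-text lists under
`data/biomarker_panels/`.

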