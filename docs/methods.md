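# Methods

## Distance models

Distances are computed on mature sequences only, the functional unit of
target recognition. For each unordered pair, alignment columns carrying a
gap or a masked character (`N`) in either row are excluded (*pairwise
deletion*), leaving `L` compared sites with `X = X1 + X2` differences split
into transitions and transversions. The Jukes–Cantor distance
`K1 = -(3/4) ln(1 - (4/3)p̂)` assumes equal substitution rates among all
base pairs; the Kimura two-parameter distance
`K2 = (1/2) ln(1/(1-2P̂-Q̂)) + (1/4) ln(1/(1-2Q̂))` allows a transition
bias. Both are method-of-moments inversions of closed-form substitution
probabilities and are undefined when a log argument is non-positive; the
boundary (argument exactly 0) is treated as undefined, matching the strict
inequalities of the formulas. Undefined pairs are stored as missing
(`n/c`) entries of the distance matrix, never dropped silently.

A consequence worth stating: the K2P conditions `2P̂+Q̂ < 1` and `Q̂ < 1/2`
jointly force `p̂ < 3/4`, so every K2P-defined pair is JC-defined. K2P
matrices therefore always have at most as many defined entries as JC
matrices on the same input — the asymmetry observed on real miRNA data.

### Alignment

The package's default consumes pre-aligned (equal-length) input and applies
pairwise deletion per pair; `aligned="auto"` treats any equal-length set
this way. For unequal-length input, a built-in Needleman–Wunsch global
aligner is used with match +1, mismatch −1 and a linear gap cost of −2 per
gap character, with a fixed traceback tie-break (match/mismatch preferred
over a gap in the first row, over a gap in the second), making results
deterministic. Reproducing any particular external aligner's multiple
alignment is a non-goal; distance counts on real data depend on that
choice, and the package treats alignment as an input.

## Distribution fitting

Four families share a pdf/cdf/quantile/sample contract:

* **normal** — `μ` = sample mean, `σ` = sample sd with divisor n−1 (at the
  reference sample sizes the n vs n−1 choice is far below reporting
  precision).
* **gamma** — shape/scale MLE with location fixed at 0, so the fitted mean
  is `αβ`. The profile score equation `ln α − ψ(α) = ln x̄ − mean(ln x)`
  is solved by Newton iteration from the standard closed-form start to an
  absolute residual of 1e-10; this matches `scipy.stats.gamma.fit(floc=0)`
  to ~1e-5 relative (cross-checked in tests). Gamma fitting requires
  strictly positive data; zero distances (identical sequence pairs) must be
  excluded by the caller, consistent with reference distance samples whose
  range is open at 0.
* **empirical** — the step ECDF is retained exactly; quantiles and
  inverse-transform sampling use a piecewise-linear smoothed cdf through
  knots `(x₍ᵢ₎, (i−0.5)/n)` (midpoint convention; an `i/n` dialect is
  selectable), flat outside the data range. Duplicate data values collapse
  to one knot at the highest level so knot abscissae stay strictly
  increasing. Step and smoothed cdfs differ by at most 1/n in sup norm.
* **kde** — Gaussian-kernel mixture; the cdf is the exact closed form
  `(1/n) Σ Φ((x−xᵢ)/h)`, and quantiles are obtained by bracketed root
  finding on it to |cdf−q| ≤ 1e-10, never from a gridded density, so no
  grid-resolution error enters downstream percentiles. Sampling draws a
  support point uniformly and adds `h·N(0,1)`.

The default bandwidth is the normal-reference rule `h = s(4/(3n))^{1/5}`
with the robust scale `s = min(sd, IQR/1.349)`; any externally chosen
bandwidth (e.g. one fixed by an earlier analysis) can be passed explicitly,
and all reference-data checks do so.

Percentile tables report `x_q = quantile(q/100)` for `q ∈ (0,100)`; the
100th percentile is reported as the maximum of the fitted sample for every
family, because the kde law has unbounded support and a literal
`quantile(1)` does not exist. (Published percentile tables appear to use a
different, unstated convention for q = 100; the package does not attempt to
match it and documents the data-maximum convention instead.)

## Goodness-of-fit evaluation

A two-sample KS test at the full sample size rejects any imperfect
parametric fit, so model selection uses a moderate per-repetition size:
m = 70 draws from each fitted law, R = 500 repetitions, asymptotic KS
p-values (m = 70 is well inside the asymptotic regime; no exact
small-sample enumeration), averaged per family. Two reference conventions
are implemented because the procedure is ambiguous: `vs-subsample`
(default) compares the draws against m observed values freshly subsampled
without replacement — the variant in which both samples are moderate and
the test retains power without automatic rejection — and `vs-full-data`
compares against the complete observed sample. Fitting on the full data is
deterministic for all four families, so the law is fitted once and only
the sampling repeats; this is exactly equivalent to re-fitting every
repetition and R times cheaper. Average p-values are rank-compared between
families; their absolute values depend on the convention and are not
treated as reproducible constants.

## Set similarity

Panel names are normalised (species prefix, `mir`/`let` spelling, arm and
paralog suffixes, unicode hyphens) into a family+variant key, and a printed
name matches *every* gene label with a compatible key, so one name may map
to several paralogs; the match report lists ambiguous and unmatched names
for audit, and a user mapping file overrides the rule per name. Because
published panels rarely state which database paralogs their authors used,
the default rule is explicit and inspectable rather than claimed to be
identical to any particular manual mapping.

The rank-sum reference sample is the complete defined-distance list
*including* the subset's own values (matching the "different from all
pairwise distances" phrasing of such analyses); an `exclude_subset` option
provides the complement variant, whose p-values differ. The test is the
two-sided Mann–Whitney with normal approximation, tie correction and
continuity correction. Exact published p-values of this kind depend on tie
handling and approximation variant; the package asserts significance
directions, not digit-level p-values.

Seed families group sequences by identical nucleotides 2–8 (1-based) of
the ungapped mature sequence; families below 2 members are excluded.

## Synthetic data

The generator emulates the study conditions: ~22-nt sequences, seed
families of the reported sizes (12, 3, 3) sharing a conserved 7-mer, and a
background of unrelated sequences. Endpoints evolve from a uniform-random
ancestor under the exact K2P transition probabilities (JC at κ = 1), each
branch of length d/2 so the pair is separated by total divergence d — the
quantity the estimators estimate — with no per-generation discretisation
bias. Within-family divergences default to 0.12, 0.14 and 0.0, chosen so
the simulated family means sit near the reported family means (~0.12,
~0.14, 0). Background sequences are i.i.d. uniform 22-mers: unrelated
pairs differ at ~75% of sites, which reproduces the key feature of real
mature-miRNA data that a large fraction of pairs is undefined under JC and
a larger fraction under K2P.

What the generator does *not* emulate: indels (and hence alignment
uncertainty), rate heterogeneity across sites, tree-shaped relatedness
beyond star-like families, and base-composition bias. Passing tests on
synthetic data therefore validate the estimators, the fitting/selection
machinery and the set statistics under the stated substitution models, not
the alignment-dependent counts of any real dataset. In seed families the
conserved motif is held fixed, so the effective pairwise divergence is
d·(L−7)/L; family means are compared against simulation truth only through
the matrix entries, never through d itself.

## Problem sizes and numerical choices

The end-to-end acceptance run uses 120 sequences (7,140 pairs), m = 70 and
R = 500 for model selection, n = 50,000 for gamma-MLE recovery, and 200
replicates of length-10⁴ pairs for estimator recovery — sizes at which
every stochastic summary is stable to well under its assertion tolerance
while the whole run completes in seconds. Distance computation on
equal-length input is vectorised across partner sequences; KS testing uses
the asymptotic p-value; KDE cdf evaluation chunks the kernel matrix to
bound memory. Degenerate inputs fail loudly: zero-variance data reject
normal/gamma/KDE fitting, pairs with no comparable columns become missing
entries, and all-tied rank-sum inputs raise.
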