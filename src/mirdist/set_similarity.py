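"""Similarity of named miRNA subsets relative to all miRNAs.

A disease biomarker panel (or a seed family) is judged by extracting all
defined pairwise distances among its members, taking their mean, and
placing that mean on the fitted KDE law of *all* pairwise distances: the
reported percentile is 100 x cdf(mean).  A panel whose members are unusually
similar to one another sits at a low percentile.  A two-sided Wilcoxon
rank-sum test compares the subset's distances against the complete
defined-distance list, and optionally the KDE law of the subset is compared
against the reference KDE law by repeated two-sample KS testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distribution_fitting import FittedDistribution, fit_kde
from .gof_evaluation import ks_two_sample
from .sequence_io import DistanceMatrix, MatchReport, SequenceRecord, match_set

__all__ = [
    "SubsetDistances",
    "ModelStats",
    "SetComparison",
    "subset_distances",
    "set_percentile",
    "ranksum_test",
    "compare_set",
    "family_report",
    "kde_vs_kde_ks",
]


@dataclass(frozen=True)
class SubsetDistances:
    """Defined distances among a member subset, with the missing-pair count."""

    values: np.ndarray
    n_missing: int

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def subset_distances(m: DistanceMatrix, members: Sequence[str]) -> SubsetDistances:
    """All defined pairwise entries among ``members``; missing pairs counted."""
    members = list(members)
    if len(members) < 2:
        raise ValueError("need at least 2 members")
    values, n_missing = m.values_among(members)
    if values.size < 1:
        raise ValueError("no defined distances among the given members")
    return SubsetDistances(values=values, n_missing=n_missing)


def set_percentile(mean_value: float, ref: FittedDistribution) -> float:
    """Percentile of a subset mean under the reference law: 100 * cdf(mean)."""
    return 100.0 * float(ref.cdf(mean_value))


def ranksum_test(subset_values: Sequence[float], all_values: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Normal approximation with tie correction and continuity correction.  By
    convention ``all_values`` is the complete defined-distance list, subset
    included; pass the complement explicitly for the exclusive variant.
    """
    a = np.asarray(subset_values, dtype=float)
    b = np.asarray(all_values, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        raise ValueError("degenerate rank-sum: all values tied across both samples")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(min(res.pvalue, 1.0))


@dataclass(frozen=True)
class ModelStats:
    """Per-substitution-model similarity summary for one subset."""

    model: str
    n_members: int
    n_pairs_defined: int
    n_pairs_missing: int
    mean: float
    percentile: float
    ranksum_p: float
    kde_ks_p: float | None = None


@dataclass
class SetComparison:
    label: str
    members: list[str]
    unmatched: list[str] = field(default_factory=list)
    ambiguous: dict[str, list[str]] = field(default_factory=dict)
    per_model: dict[str, ModelStats] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "label": self.label,
                "model": s.model,
                "n_members": s.n_members,
                "n_pairs_defined": s.n_pairs_defined,
                "n_pairs_missing": s.n_pairs_missing,
                "mean": s.mean,
                "percentile": s.percentile,
                "ranksum_p": s.ranksum_p,
                "kde_ks_p": s.kde_ks_p,
            }
            for s in self.per_model.values()
        ]
        return pd.DataFrame(rows)


def _model_stats(
    model: str,
    matrix: DistanceMatrix,
    ref: FittedDistribution,
    members: Sequence[str],
    exclude_subset: bool,
    kde_ks: bool,
    m: int,
    R: int,
    seed: int | None,
) -> ModelStats:
    sub = subset_distances(matrix, members)
    all_values = matrix.defined_values()
    if exclude_subset:
        # remove one occurrence per subset value from the reference list
        reference = all_values.tolist()
        for v in sub.values:
            reference.remove(v)
        reference = np.asarray(reference)
    else:
        reference = all_values
    ks_p = (
        kde_vs_kde_ks(sub.values, all_values, m=m, R=R, seed=seed, ref_bandwidth=ref)
        if kde_ks and sub.values.size >= 2 and np.ptp(sub.values) > 0
        else None
    )
    return ModelStats(
        model=model,
        n_members=len(members),
        n_pairs_defined=int(sub.values.size),
        n_pairs_missing=sub.n_missing,
        mean=sub.mean,
        percentile=set_percentile(sub.mean, ref),
        ranksum_p=ranksum_test(sub.values, reference),
        kde_ks_p=ks_p,
    )


def compare_set(
    names: Sequence[str],
    matrices: Mapping[str, DistanceMatrix],
    refs: Mapping[str, FittedDistribution],
    label: str = "set",
    mapping: Mapping[str, Sequence[str]] | None = None,
    exclude_subset: bool = False,
    kde_ks: bool = False,
    m: int = 70,
    R: int = 200,
    seed: int | None = 0,
) -> SetComparison:
    """Full similarity analysis of a printed biomarker name list.

    ``matrices`` and ``refs`` map model tags (e.g. ``"JC"``, ``"K2P"``) to
    the all-miRNA distance matrix and its reference KDE law; the same models
    must be present in both.
    """
    if set(matrices) != set(refs):
        raise ValueError("matrices and refs must cover the same models")
    first = next(iter(matrices.values()))
    report: MatchReport = match_set(names, first.labels, mapping=mapping)
    if len(report.matched_labels) < 2:
        raise ValueError(
            f"fewer than 2 matched members (unmatched: {report.unmatched})"
        )
    out = SetComparison(
        label=label,
        members=list(report.matched_labels),
        unmatched=list(report.unmatched),
        ambiguous=report.ambiguous,
    )
    for model, matrix in matrices.items():
        out.per_model[model] = _model_stats(
            model, matrix, refs[model], report.matched_labels,
            exclude_subset, kde_ks, m, R, seed,
        )
    return out


def family_report(
    records: Sequence[SequenceRecord],
    matrices: Mapping[str, DistanceMatrix],
    refs: Mapping[str, FittedDistribution],
    min_size: int = 2,
    kde_ks: bool = False,
    m: int = 70,
    R: int = 200,
    seed: int | None = 0,
) -> list[SetComparison]:
    """Group sequences by identical 7-nt seed and analyse each family.

    Families smaller than ``min_size`` are excluded.  Results are sorted by
    decreasing family size, ties by seed.
    """
    if set(matrices) != set(refs):
        raise ValueError("matrices and refs must cover the same models")
    groups: dict[str, list[str]] = {}
    for rec in records:
        if rec.seed is not None:
            groups.setdefault(rec.seed, []).append(rec.id)
    out = []
    for seed_motif, members in sorted(
        groups.items(), key=lambda kv: (-len(kv[1]), kv[0])
    ):
        if len(members) < min_size:
            continue
        comp = SetComparison(label=seed_motif, members=members)
        for model, matrix in matrices.items():
            comp.per_model[model] = _model_stats(
                model, matrix, refs[model], members, False, kde_ks, m, R, seed
            )
        out.append(comp)
    return out


def kde_vs_kde_ks(
    values_a: Sequence[float],
    values_b: Sequence[float],
    m: int = 70,
    R: int = 200,
    seed: int | None = 0,
    bandwidth_a: float | None = None,
    ref_bandwidth: FittedDistribution | float | None = None,
) -> float:
    """Average KS p-value between the KDE laws of two distance samples.

    Each repetition draws m values from each fitted KDE and applies the
    two-sample KS test; the R p-values are averaged.  ``ref_bandwidth`` may
    be a number or an already-fitted reference law whose bandwidth is reused
    for ``values_b``.
    """
    if isinstance(ref_bandwidth, FittedDistribution):
        hb = ref_bandwidth.params.get("bandwidth")
    else:
        hb = ref_bandwidth
    da = fit_kde(values_a, bandwidth=bandwidth_a)
    db = fit_kde(values_b, bandwidth=hb)
    rng = np.random.default_rng(seed)
    ps = np.empty(R)
    for r in range(R):
        _, ps[r] = ks_two_sample(da.sample(m, seed=rng), db.sample(m, seed=rng))
    return float(ps.mean())
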