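"""Pairwise substitution-model distances between mature miRNA sequences.

Two classical nucleotide substitution models are implemented.  Writing
``p̂ = X/L`` for the observed proportion of differing compared sites, the
Jukes-Cantor one-parameter distance (equal substitution rates among all
four bases) is

    K1 = -(3/4) * ln(1 - (4/3) p̂),           defined iff 1 - (4/3) p̂ > 0,

with approximate sampling variance ``V(K1) = (p̂ - p̂²) / (L (1 - 4p̂/3)²)``.
The Kimura two-parameter distance separates transitions (A<->G, C<->U;
proportion ``P̂ = X1/L``) from transversions (proportion ``Q̂ = X2/L``):

    K2 = (1/2) ln(1 / (1 - 2P̂ - Q̂)) + (1/4) ln(1 / (1 - 2Q̂)),

defined iff both ``1 - 2P̂ - Q̂ > 0`` and ``1 - 2Q̂ > 0``.  Pairs violating
a model's condition carry an UNDEFINED distance (the ``n/c`` of distance
tables); at the exact boundary (log argument 0) the distance is likewise
undefined, matching the strict inequalities.

Gaps and masked characters are handled by *pairwise deletion*: for each
pair separately, alignment columns with a gap/mask in either row are
excluded from the compared length L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .sequence_io import GAP, RNA_ALPHABET, DistanceMatrix, SequenceRecord

__all__ = [
    "AlignedPair",
    "SiteCounts",
    "DistanceEstimate",
    "AlignmentParams",
    "align_pair",
    "count_sites",
    "jc_distance",
    "jc_variance",
    "k2p_distance",
    "distance_matrix",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CU")


@dataclass(frozen=True)
class AlignedPair:
    """Two equal-length gapped rows of a pairwise alignment."""

    a: str
    b: str

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError(
                f"aligned rows differ in length ({len(self.a)} vs {len(self.b)})"
            )
        if not self.a:
            raise ValueError("empty alignment")


@dataclass(frozen=True)
class SiteCounts:
    """Compared-site tallies for one pair under pairwise deletion.

    L compared columns, X differing, split into X1 transitions and X2
    transversions.
    """

    L: int
    X: int
    X1: int
    X2: int

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("SiteCounts needs L >= 1")
        if not (0 <= self.X <= self.L):
            raise ValueError(f"need 0 <= X <= L, got X={self.X}, L={self.L}")
        if self.X1 + self.X2 != self.X:
            raise ValueError(f"X1 + X2 must equal X ({self.X1}+{self.X2} != {self.X})")
        if self.X1 < 0 or self.X2 < 0:
            raise ValueError("negative difference counts")

    @property
    def p_hat(self) -> float:
        """Observed proportion of differing sites, X/L."""
        return self.X / self.L

    @property
    def P_hat(self) -> float:
        """Observed proportion of transitional differences, X1/L."""
        return self.X1 / self.L

    @property
    def Q_hat(self) -> float:
        """Observed proportion of transversional differences, X2/L."""
        return self.X2 / self.L


@dataclass(frozen=True)
class DistanceEstimate:
    """One pairwise distance: substitutions per site, or undefined."""

    model: str
    value: float | None
    variance: float | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class AlignmentParams:
    """Global-alignment scoring: match reward, mismatch and per-gap-character
    penalties (linear gap cost; open and extend are both ``gap``)."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0


def _as_seq(s: SequenceRecord | str) -> str:
    return s.sequence if isinstance(s, SequenceRecord) else s


def align_pair(
    s1: SequenceRecord | str,
    s2: SequenceRecord | str,
    params: AlignmentParams | None = None,
    mode: str = "global",
) -> AlignedPair:
    """Globally align two sequences (Needleman-Wunsch), or pass through.

    Ties in the traceback are broken deterministically: a match/mismatch
    column is preferred over a gap in row ``a``, which is preferred over a
    gap in row ``b``.  ``mode="passthrough"`` returns pre-aligned input
    unchanged after an equal-length check.
    """
    a, b = _as_seq(s1), _as_seq(s2)
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if mode == "passthrough":
        return AlignedPair(a, b)
    if mode != "global":
        raise ValueError(f"unknown alignment mode {mode!r}")
    params = params or AlignmentParams()
    match, mismatch, gap = params.match, params.mismatch, params.gap

    n, m = len(a), len(b)
    S = [[0.0] * (m + 1) for _ in range(n + 1)]
    for j in range(1, m + 1):
        S[0][j] = j * gap
    for i in range(1, n + 1):
        S[i][0] = i * gap
        row, prev = S[i], S[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            sub = match if ai == b[j - 1] else mismatch
            row[j] = max(prev[j - 1] + sub, row[j - 1] + gap, prev[j] + gap)

    # traceback, tie-break: diagonal > gap-in-a (consume b) > gap-in-b
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        here = S[i][j]
        if i > 0 and j > 0:
            sub = match if a[i - 1] == b[j - 1] else mismatch
            if here == S[i - 1][j - 1] + sub:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i, j = i - 1, j - 1
                continue
        if j > 0 and here == S[i][j - 1] + gap:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
            continue
        out_a.append(a[i - 1])
        out_b.append(GAP)
        i -= 1
    return AlignedPair("".join(reversed(out_a)), "".join(reversed(out_b)))


def count_sites(p: AlignedPair) -> SiteCounts:
    """Tally compared sites under pairwise deletion.

    Columns where either row carries a gap or a non-RNA (masked) character
    are excluded.  Differences among compared columns are classified as
    transitions (purine<->purine, pyrimidine<->pyrimidine) or transversions
    (purine<->pyrimidine).
    """
    L = X1 = X2 = 0
    for ca, cb in zip(p.a, p.b):
        if ca not in RNA_ALPHABET or cb not in RNA_ALPHABET:
            continue
        L += 1
        if ca == cb:
            continue
        if (ca in _PURINES) == (cb in _PURINES):
            X1 += 1
        else:
            X2 += 1
    if L == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    return SiteCounts(L=L, X=X1 + X2, X1=X1, X2=X2)


def jc_variance(c: SiteCounts) -> float:
    """Approximate sampling variance of the JC distance, (p̂-p̂²)/(L(1-4p̂/3)²)."""
    p = c.p_hat
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        raise ValueError("JC variance requires 1 - (4/3) p̂ > 0")
    return (p - p * p) / (c.L * arg * arg)


def jc_distance(c: SiteCounts) -> DistanceEstimate:
    """Jukes-Cantor distance; UNDEFINED when 1 - (4/3) p̂ <= 0."""
    arg = 1.0 - 4.0 * c.p_hat / 3.0
    if arg <= 0.0:
        return DistanceEstimate(model="JC", value=None)
    value = -0.75 * math.log(arg)
    return DistanceEstimate(model="JC", value=value, variance=jc_variance(c))


def k2p_distance(c: SiteCounts) -> DistanceEstimate:
    """Kimura two-parameter distance; UNDEFINED when either condition fails."""
    P, Q = c.P_hat, c.Q_hat
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0.0 or arg2 <= 0.0:
        return DistanceEstimate(model="K2P", value=None)
    value = 0.5 * math.log(1.0 / arg1) + 0.25 * math.log(1.0 / arg2)
    return DistanceEstimate(model="K2P", value=value)


_ESTIMATORS = {"JC": jc_distance, "K2P": k2p_distance}


def _pair_counts_aligned(records: Sequence[SequenceRecord]) -> Iterable[tuple[int, int, SiteCounts | None]]:
    """Vectorised site counting for equal-length (column-sharing) input."""
    codes = {"A": 0, "C": 1, "G": 2, "U": 3}
    arr = np.full((len(records), len(records[0].sequence)), 255, dtype=np.uint8)
    for i, rec in enumerate(records):
        for k, ch in enumerate(rec.sequence):
            arr[i, k] = codes.get(ch, 255)
    purine = (arr == 0) | (arr == 2)
    valid = arr != 255
    n = len(records)
    for i in range(n - 1):
        v = valid[i] & valid[i + 1 :]
        L = v.sum(axis=1)
        diff = (arr[i] != arr[i + 1 :]) & v
        ts = diff & (purine[i] == purine[i + 1 :])
        X1 = ts.sum(axis=1)
        X = diff.sum(axis=1)
        for off in range(n - 1 - i):
            j = i + 1 + off
            if L[off] == 0:
                yield i, j, None
            else:
                yield i, j, SiteCounts(
                    L=int(L[off]), X=int(X[off]), X1=int(X1[off]), X2=int(X[off] - X1[off])
                )


def distance_matrix(
    records: Sequence[SequenceRecord],
    model: str = "JC",
    params: AlignmentParams | None = None,
    aligned: bool | str = "auto",
) -> DistanceMatrix:
    """Compute all unordered pairwise distances for a set of sequences.

    ``aligned=True`` (or ``"auto"`` with equal-length input, e.g. a
    pre-aligned multi-FASTA or fixed-length simulated set) treats sequences
    as sharing columns and applies pairwise deletion per pair; otherwise
    each pair is globally aligned first.  Undefined estimates are stored as
    missing entries; pairs with no comparable sites are likewise missing.
    """
    model = model.upper()
    if model not in _ESTIMATORS:
        raise ValueError(f"unknown model {model!r}; expected 'JC' or 'K2P'")
    if len(records) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence ids: {dupes}")
    if aligned == "auto":
        aligned = len({len(r.sequence) for r in records}) == 1
    estimator = _ESTIMATORS[model]
    m = DistanceMatrix(ids, model=model)
    if aligned:
        if len({len(r.sequence) for r in records}) != 1:
            raise ValueError("aligned mode requires equal-length (pre-aligned) sequences")
        for i, j, counts in _pair_counts_aligned(records):
            est = estimator(counts) if counts is not None else None
            m.set(ids[i], ids[j], est.value if est is not None else None)
        return m
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            pair = align_pair(records[i], records[j], params=params)
            try:
                counts = count_sites(pair)
            except ValueError:
                m.set(ids[i], ids[j], None)
                continue
            m.set(ids[i], ids[j], estimator(counts).value)
    return m
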