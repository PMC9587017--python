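"""Reading and writing mature-miRNA sequences and pairwise-distance tables.

Mature miRNAs are ~22-nt single-stranded RNAs.  Databases and published
biomarker lists mix conventions freely -- DNA vs RNA alphabet, ``hsa-``
species prefixes, ``miR``/``Mir`` capitalisation, arm suffixes (``-5p``),
paralog suffixes (``-P1``) -- so this module also provides a documented
name-normalisation scheme used to match printed biomarker panels against
database-style gene labels.

Distance tables use ``n/c`` (case-insensitive, also blank) as the marker for
pairs whose substitution-model distance is undefined.  The canonical
interchange dialect is a long-format CSV with header
``label_a,label_b,distance``; square and lower-triangular dialects are read
and written as well.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "DistanceMatrix",
    "MISSING",
    "DEFAULT_MISSING_TOKENS",
    "read_fasta",
    "write_fasta",
    "read_distance_table",
    "write_distance_table",
    "normalize_name",
    "parse_name",
    "ParsedName",
    "match_set",
    "MatchReport",
    "read_mapping",
]

RNA_ALPHABET = frozenset("ACGU")
#: characters tolerated in stored sequences: RNA bases, alignment gap, mask
ALLOWED_CHARS = frozenset("ACGUN-")
GAP = "-"
MASK = "N"

#: sentinel stored for an undefined ("n/c") distance
MISSING = None

DEFAULT_MISSING_TOKENS = ("n/c", "")

# seed = positions 2..8 of the mature sequence, 1-based
_SEED_SLICE = slice(1, 8)


def canonicalize_sequence(seq: str) -> str:
    """Upper-case and map the DNA convention T to the RNA convention U."""
    return seq.strip().upper().replace("T", "U")


def _seed_of(sequence: str) -> str | None:
    ungapped = sequence.replace(GAP, "")
    if len(ungapped) < 8:
        return None
    seed = ungapped[_SEED_SLICE]
    return seed if set(seed) <= RNA_ALPHABET else None


@dataclass(frozen=True)
class SequenceRecord:
    """One mature miRNA: identifier, RNA sequence, optional 7-nt seed.

    The seed is the target-recognition region, nucleotides 2-8 (1-based) of
    the mature sequence; it defines seed families.
    """

    id: str
    sequence: str
    seed: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record needs a non-empty id")
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - ALLOWED_CHARS
        if bad:
            raise ValueError(
                f"{self.id}: invalid characters {sorted(bad)} (expected A/C/G/U, "
                f"'{GAP}' for gaps, '{MASK}' for masked sites)"
            )
        if self.seed is not None and _seed_of(self.sequence) != self.seed:
            raise ValueError(
                f"{self.id}: seed {self.seed!r} does not equal positions 2-8 "
                "of the ungapped sequence"
            )

    @classmethod
    def from_sequence(cls, id: str, sequence: str) -> "SequenceRecord":
        """Build a record, canonicalizing the sequence and deriving the seed."""
        seq = canonicalize_sequence(sequence)
        return cls(id=id, sequence=seq, seed=_seed_of(seq))

    @property
    def ungapped(self) -> str:
        return self.sequence.replace(GAP, "")


def read_fasta(path: str | Path, on_invalid: str = "error") -> list[SequenceRecord]:
    """Read a (plain or pre-aligned) FASTA file of mature miRNA sequences.

    T is canonicalized to U.  Characters outside {A,C,G,U,-} are rejected
    (``on_invalid="error"``) or replaced by the mask character ``N``
    (``on_invalid="mask"``); masked sites are excluded downstream by pairwise
    deletion, exactly like gaps.
    """
    if on_invalid not in ("error", "mask"):
        raise ValueError(f"on_invalid must be 'error' or 'mask', got {on_invalid!r}")
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: line {lineno}: expected FASTA header '>', "
                        f"got {line.strip()[:40]!r}"
                    )
                break
        else:
            raise ValueError(f"{path}: empty FASTA file")
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = canonicalize_sequence(str(entry.seq))
        if not seq:
            raise ValueError(f"{path}: entry {entry.id!r} has an empty sequence")
        invalid = set(seq) - RNA_ALPHABET - {GAP}
        if invalid:
            if on_invalid == "error":
                raise ValueError(
                    f"{path}: entry {entry.id!r} contains non-RNA characters "
                    f"{sorted(invalid)}"
                )
            keep = RNA_ALPHABET | {GAP}
            seq = "".join(c if c in keep else MASK for c in seq)
        records.append(SequenceRecord(id=entry.id, sequence=seq, seed=_seed_of(seq)))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


class DistanceMatrix:
    """Labeled lower-triangular collection of pairwise distances.

    Undefined entries (the ``n/c`` of the substitution-model formulas, whose
    log argument is non-positive) are stored as :data:`MISSING`.  Only
    unordered pairs are stored, never self-pairs.
    """

    def __init__(self, labels: Sequence[str], model: str = "JC"):
        labels = list(labels)
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate labels: {dupes}")
        self.labels = labels
        self.model = model
        self._index = {lab: i for i, lab in enumerate(labels)}
        self._values: dict[tuple[int, int], float | None] = {}

    # -- mapping helpers -------------------------------------------------
    def _key(self, a: str, b: str) -> tuple[int, int]:
        try:
            i, j = self._index[a], self._index[b]
        except KeyError as exc:
            raise KeyError(f"unknown label {exc.args[0]!r}") from None
        if i == j:
            raise ValueError(f"self-pair ({a!r}) not stored")
        return (i, j) if i < j else (j, i)

    def set(self, a: str, b: str, value: float | None) -> None:
        if value is not None:
            value = float(value)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"distance must be finite and >= 0, got {value}")
        self._values[self._key(a, b)] = value

    def get(self, a: str, b: str) -> float | None:
        return self._values[self._key(a, b)]

    def __contains__(self, pair: tuple[str, str]) -> bool:
        try:
            return self._key(*pair) in self._values
        except (KeyError, ValueError):
            return False

    def __len__(self) -> int:
        return len(self._values)

    # -- summaries -------------------------------------------------------
    @property
    def n_pairs(self) -> int:
        """Number of stored pairs (defined + missing)."""
        return len(self._values)

    @property
    def n_defined(self) -> int:
        return sum(1 for v in self._values.values() if v is not None)

    @property
    def n_missing(self) -> int:
        return self.n_pairs - self.n_defined

    def defined_values(self) -> np.ndarray:
        return np.array(
            [v for _, v in sorted(self._values.items()) if v is not None], dtype=float
        )

    def pairs(self) -> Iterable[tuple[str, str, float | None]]:
        """Yield (label_a, label_b, value) in canonical (row-major) order."""
        for (i, j), v in sorted(self._values.items()):
            yield self.labels[i], self.labels[j], v

    def values_among(self, members: Sequence[str]) -> tuple[np.ndarray, int]:
        """Defined distances among ``members`` and the count of missing pairs.

        Only pairs actually stored in the matrix are considered.
        """
        idx = [self._index[m] if m in self._index else self._missing_label(m) for m in members]
        out, n_missing = [], 0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                key = (i, j) if i < j else (j, i)
                if key not in self._values:
                    continue
                v = self._values[key]
                if v is None:
                    n_missing += 1
                else:
                    out.append(v)
        return np.array(out, dtype=float), n_missing

    @staticmethod
    def _missing_label(m: str):
        raise KeyError(f"unknown label {m!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DistanceMatrix):
            return NotImplemented
        return (
            self.labels == other.labels
            and self.model == other.model
            and self._values == other._values
        )


# ---------------------------------------------------------------------------
# distance-table dialects
# ---------------------------------------------------------------------------

_DIALECTS = ("long", "square", "lower")


def _is_missing(token: str, missing_tokens: Sequence[str]) -> bool:
    return token.strip().lower() in tuple(t.lower() for t in missing_tokens)


def _parse_cell(token: str, missing_tokens: Sequence[str], context: str) -> float | None:
    if _is_missing(token, missing_tokens):
        return MISSING
    try:
        return float(token)
    except ValueError:
        raise ValueError(f"{context}: non-numeric, non-missing cell {token!r}") from None


def read_distance_table(
    path: str | Path,
    dialect: str = "long",
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
    model: str | None = None,
    atol: float = 1e-8,
) -> DistanceMatrix:
    """Read a pairwise-distance table.

    Dialects: ``long`` (CSV ``label_a,label_b,distance``, the canonical
    interchange format; lines starting with ``#`` are comments), ``square``
    (full symmetric matrix with a label header row/column), ``lower``
    (ragged lower triangle, row *i* holding *i* cells).  Cells equal to a
    missing token (default ``n/c`` case-insensitively, or blank) become
    :data:`MISSING`.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    path = Path(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not (r[0].startswith("#"))]
    if not rows:
        raise ValueError(f"{path}: empty table")

    if dialect == "long":
        header = [c.strip().lower() for c in rows[0]]
        if header[:3] != ["label_a", "label_b", "distance"]:
            raise ValueError(
                f"{path}: long-format header must be 'label_a,label_b,distance', got {rows[0]}"
            )
        labels: list[str] = []
        seen: set[str] = set()
        entries: list[tuple[str, str, float | None]] = []
        for k, row in enumerate(rows[1:], 2):
            if len(row) != 3:
                raise ValueError(f"{path}: line {k}: expected 3 columns, got {len(row)}")
            a, b, cell = row[0].strip(), row[1].strip(), row[2]
            for lab in (a, b):
                if lab not in seen:
                    seen.add(lab)
                    labels.append(lab)
            entries.append((a, b, _parse_cell(cell, missing_tokens, f"{path}: line {k}")))
        m = DistanceMatrix(labels, model=model or "JC")
        for a, b, v in entries:
            if (a, b) in m:
                raise ValueError(f"{path}: duplicate pair ({a!r}, {b!r})")
            m.set(a, b, v)
        return m

    if dialect == "square":
        header = rows[0]
        labels = [c.strip() for c in header[1:]]
        if len(rows) - 1 != len(labels):
            raise ValueError(
                f"{path}: square table has {len(labels)} columns but {len(rows) - 1} rows"
            )
        m = DistanceMatrix(labels, model=model or "JC")
        cells: dict[tuple[int, int], float | None] = {}
        for i, row in enumerate(rows[1:]):
            if row[0].strip() != labels[i]:
                raise ValueError(
                    f"{path}: row label {row[0]!r} does not match column label {labels[i]!r}"
                )
            if len(row) - 1 != len(labels):
                raise ValueError(f"{path}: row {labels[i]!r} has {len(row) - 1} cells")
            for j, cell in enumerate(row[1:]):
                if i == j:
                    continue
                cells[(i, j)] = _parse_cell(
                    cell, missing_tokens, f"{path}: cell ({labels[i]}, {labels[j]})"
                )
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                lo, hi = cells[(i, j)], cells[(j, i)]
                if (lo is None) != (hi is None):
                    raise ValueError(
                        f"{path}: asymmetric missingness at ({labels[i]}, {labels[j]})"
                    )
                if lo is not None and abs(lo - hi) > atol:
                    raise ValueError(
                        f"{path}: asymmetric cells at ({labels[i]}, {labels[j]}): "
                        f"{lo} vs {hi} (tolerance {atol})"
                    )
                m.set(labels[i], labels[j], lo)
        return m

    # lower-triangular: row i (0-based) = label, then i cells
    labels = []
    cell_rows = []
    for i, row in enumerate(rows):
        labels.append(row[0].strip())
        if len(row) - 1 != i:
            raise ValueError(
                f"{path}: ragged triangle: row {row[0]!r} has {len(row) - 1} cells, expected {i}"
            )
        cell_rows.append(row[1:])
    m = DistanceMatrix(labels, model=model or "JC")
    for i, cells_i in enumerate(cell_rows):
        for j, cell in enumerate(cells_i):
            m.set(
                labels[i], labels[j], _parse_cell(cell, missing_tokens, f"{path}: row {labels[i]!r}")
            )
    return m


def write_distance_table(
    m: DistanceMatrix,
    path: str | Path,
    dialect: str = "long",
    missing_token: str = "n/c",
    header_comments: Sequence[str] = (),
) -> None:
    """Write a distance table; the long dialect round-trips bit-identically.

    Floats are rendered with :func:`repr`, the shortest representation that
    reparses to the identical IEEE double.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    path = Path(path)

    def cell(v: float | None) -> str:
        return missing_token if v is None else repr(v)

    with open(path, "w", newline="") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        w = csv.writer(fh, lineterminator="\n")
        if dialect == "long":
            w.writerow(["label_a", "label_b", "distance"])
            for a, b, v in m.pairs():
                w.writerow([a, b, cell(v)])
        elif dialect == "square":
            w.writerow([""] + m.labels)
            for i, lab in enumerate(m.labels):
                row = [lab]
                for j, other in enumerate(m.labels):
                    if i == j:
                        row.append("0")
                    else:
                        pair = (lab, other)
                        row.append(cell(m.get(*pair)) if pair in m else missing_token)
                w.writerow(row)
        else:
            for i, lab in enumerate(m.labels):
                row = [lab]
                for j in range(i):
                    pair = (lab, m.labels[j])
                    row.append(cell(m.get(*pair)) if pair in m else missing_token)
                w.writerow(row)


# ---------------------------------------------------------------------------
# miRNA name normalisation and biomarker-set matching
# ---------------------------------------------------------------------------

# unicode hyphen variants seen in published tables
_HYPHENS = re.compile(r"[‐‑‒–—−_]")
_SPECIES_PREFIXES = frozenset({"hsa", "mmu", "rno", "dme", "cel", "gga", "dre", "sim"})
_BASE_MAP = {"mir": "mir", "let": "let", "lin": "lin"}
_NUM_VAR = re.compile(r"^(\d+)([a-z]*)$")
_ARM = re.compile(r"^[35]p$")
_PARALOG = re.compile(r"^(p\d+[a-z0-9]*|v\d+)$")


@dataclass(frozen=True)
class ParsedName:
    """Decomposition of a miRNA name into comparable parts.

    ``family`` is e.g. ``"mir-21"`` or ``"let-7"``; ``variant`` the paralog
    letter of the mirBase convention (``"a"`` in ``let-7a``); ``paralog`` a
    database paralog suffix (``"p1"`` in ``Hsa-Mir-10-P1``); ``arm`` the
    ``5p``/``3p`` strand suffix.  Unparseable names are opaque: ``family``
    holds the cleaned input and all other parts are ``None``.
    """

    family: str
    variant: str | None = None
    paralog: str | None = None
    arm: str | None = None
    opaque: bool = False

    @property
    def key(self) -> str:
        if self.opaque:
            return self.family
        return self.family + (self.variant or "")


def parse_name(name: str) -> ParsedName:
    cleaned = _HYPHENS.sub("-", name.strip().lower())
    cleaned = re.sub(r"\s+", "", cleaned)
    cleaned = cleaned.strip("-")
    tokens = [t for t in cleaned.split("-") if t]
    if tokens and tokens[0] in _SPECIES_PREFIXES and len(tokens) > 1:
        tokens = tokens[1:]
    if not tokens:
        return ParsedName(family=cleaned, opaque=True)
    base = tokens[0]
    if base == "mirna":
        base = "mir"
    if base not in _BASE_MAP:
        return ParsedName(family=cleaned, opaque=True)
    base = _BASE_MAP[base]
    if len(tokens) < 2:
        return ParsedName(family=cleaned, opaque=True)
    mnum = _NUM_VAR.match(tokens[1])
    if not mnum:
        return ParsedName(family=cleaned, opaque=True)
    number, variant = mnum.group(1), mnum.group(2) or None
    paralog = arm = None
    for tok in tokens[2:]:
        if _ARM.match(tok):
            arm = tok
        elif _PARALOG.match(tok):
            paralog = tok
        elif _NUM_VAR.match(tok) and paralog is None and tok.isdigit():
            # trailing cluster index (e.g. mir-199-2): fold into paralog slot
            paralog = tok
        else:
            return ParsedName(family=cleaned, opaque=True)
    return ParsedName(family=f"{base}-{number}", variant=variant, paralog=paralog, arm=arm)


def normalize_name(name: str) -> str:
    """Canonical key for a miRNA name: family plus optional variant letter.

    ``"miR-21"`` and ``"Hsa-Mir-21"`` map to the same key ``"mir-21"``;
    ``"let-7a"`` to ``"let-7a"``; variant letters are preserved so
    ``"miR-19a"`` and ``"miR-19b"`` stay distinct.  Idempotent.  Unparseable
    names return their cleaned text unchanged (an opaque key).
    """
    return parse_name(name).key


@dataclass
class MatchReport:
    """Audit of printed-name -> gene-label matching (many-to-many)."""

    matches: dict[str, list[str]] = field(default_factory=dict)
    matched_labels: list[str] = field(default_factory=list)
    unmatched: list[str] = field(default_factory=list)

    @property
    def ambiguous(self) -> dict[str, list[str]]:
        """Names that matched more than one gene label."""
        return {n: ls for n, ls in self.matches.items() if len(ls) > 1}


def match_set(
    names: Sequence[str],
    labels: Sequence[str],
    mapping: Mapping[str, Sequence[str]] | None = None,
) -> MatchReport:
    """Match printed biomarker names against database gene labels.

    A printed name matches every label whose normalized family agrees and
    whose variant letter is compatible (equal, or absent on either side), so
    one name may map to several paralog gene labels.  A user ``mapping``
    (printed name -> explicit labels) overrides the rule per name.
    """
    if len(set(labels)) != len(labels):
        raise ValueError("gene labels must be unique")
    parsed_labels = [(lab, parse_name(lab)) for lab in labels]
    report = MatchReport()
    seen_labels: set[str] = set()
    for name in names:
        if mapping is not None and name in mapping:
            hits = [l for l in mapping[name] if l in labels]
        else:
            p = parse_name(name)
            if p.opaque:
                hits = [lab for lab, q in parsed_labels if q.key == p.key]
            else:
                hits = [
                    lab
                    for lab, q in parsed_labels
                    if not q.opaque
                    and q.family == p.family
                    and (p.variant is None or q.variant is None or p.variant == q.variant)
                ]
        if hits:
            report.matches[name] = hits
            for lab in hits:
                if lab not in seen_labels:
                    seen_labels.add(lab)
                    report.matched_labels.append(lab)
        else:
            report.unmatched.append(name)
    return report


def read_mapping(path: str | Path) -> dict[str, list[str]]:
    """Read a user mapping CSV ``printed_name,gene_label`` (repeatable names)."""
    mapping: dict[str, list[str]] = {}
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    if rows and [c.strip().lower() for c in rows[0][:2]] == ["printed_name", "gene_label"]:
        rows = rows[1:]
    for row in rows:
        if len(row) < 2:
            raise ValueError(f"{path}: mapping rows need 2 columns, got {row}")
        mapping.setdefault(row[0].strip(), []).append(row[1].strip())
    return mapping
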