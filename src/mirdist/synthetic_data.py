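"""Simulated miRNA-like inputs with known statistical structure.

Sequence pairs and seed families are evolved under the Kimura two-parameter
substitution process (Jukes-Cantor when ``kappa = 1``) using the exact
closed-form transition probabilities, so estimator-recovery tests carry no
discretisation bias.  Divergence ``d`` is the *total* expected number of
substitutions per site separating two endpoints (the quantity the JC/K2P
estimators estimate); each endpoint therefore evolves for time ``d/2`` from
a shared uniform-random ancestor.

With per-site rates alpha for the transition and beta for each of the two
transversions, ``kappa = alpha/beta``, and time t measured in expected
substitutions per site (so ``(alpha + 2 beta) t = t``):

    P(transition)       = 1/4 + 1/4 e^{-4 beta t} - 1/2 e^{-2 (alpha+beta) t}
    P(transversion_tot) = 1/2 - 1/2 e^{-4 beta t}

with ``beta t = t/(kappa+2)`` and ``(alpha+beta) t = (kappa+1) t/(kappa+2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .sequence_io import RNA_ALPHABET, SequenceRecord

__all__ = [
    "SimConfig",
    "k2p_site_probs",
    "evolve_pair",
    "make_family",
    "make_dataset",
    "sample_gamma",
]

_BASES = np.array(list("ACGU"))
# base codes 0=A 1=C 2=G 3=U; transitions A<->G, C<->U
_TS_PARTNER = np.array([2, 3, 0, 1])
_TV_PARTNER_1 = np.array([1, 0, 1, 0])
_TV_PARTNER_2 = np.array([3, 2, 3, 2])

_SEED_SLICE = slice(1, 8)


@dataclass(frozen=True)
class SimConfig:
    """Conditions for one simulated pair, family, or background set.

    ``divergence`` is the total expected substitutions/site between any two
    members (both branches); ``kappa`` the transition/transversion rate
    ratio (1 = JC); ``seed_motif`` a 7-mer held invariant at positions 2-8.
    """

    n_sequences: int = 2
    length: int = 22
    divergence: float = 0.3
    kappa: float = 1.0
    seed_motif: str | None = None
    rng_seed: int = 0
    label_prefix: str = "Sim"

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.seed_motif is not None:
            if len(self.seed_motif) != 7 or set(self.seed_motif) - RNA_ALPHABET:
                raise ValueError("seed_motif must be a 7-mer over {A,C,G,U}")
            if self.length < 8:
                raise ValueError("length must be >= 8 when seed_motif is set")


def k2p_site_probs(t: float, kappa: float) -> tuple[float, float, float]:
    """(P_same, P_transition, P_transversion_total) after time t per site."""
    if t < 0:
        raise ValueError("t must be >= 0")
    bt = t / (kappa + 2.0)
    e1 = math.exp(-4.0 * bt)
    e2 = math.exp(-2.0 * (kappa + 1.0) * t / (kappa + 2.0))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.5 - 0.5 * e1
    return 1.0 - p_ts - p_tv, p_ts, p_tv


def _evolve_codes(codes: np.ndarray, t: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    p_same, p_ts, p_tv = k2p_site_probs(t, kappa)
    cat = rng.choice(4, size=codes.size, p=[p_same, p_ts, p_tv / 2.0, p_tv / 2.0])
    out = codes.copy()
    out[cat == 1] = _TS_PARTNER[codes[cat == 1]]
    out[cat == 2] = _TV_PARTNER_1[codes[cat == 2]]
    out[cat == 3] = _TV_PARTNER_2[codes[cat == 3]]
    return out


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


def evolve_pair(cfg: SimConfig) -> tuple[SequenceRecord, SequenceRecord]:
    """Two sequences separated by total divergence ``cfg.divergence``.

    A uniform-random ancestor evolves independently down two branches of
    length d/2 each under the exact K2P transition matrix.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    anc = rng.integers(0, 4, size=cfg.length)
    t = cfg.divergence / 2.0
    a = _evolve_codes(anc, t, cfg.kappa, rng)
    b = _evolve_codes(anc, t, cfg.kappa, rng)
    return (
        SequenceRecord.from_sequence(f"{cfg.label_prefix}-pair-a", _codes_to_str(a)),
        SequenceRecord.from_sequence(f"{cfg.label_prefix}-pair-b", _codes_to_str(b)),
    )


def make_family(cfg: SimConfig, family_name: str | None = None) -> list[SequenceRecord]:
    """A seed family: members share the motif at positions 2-8 exactly.

    Non-seed positions evolve from a common family ancestor, each member on
    its own branch of length d/2, so any two members are separated by
    divergence ~ d at the non-seed sites.  Labels follow a database-style
    scheme (``<family_name>-P<i>``) compatible with name normalisation.
    """
    if cfg.seed_motif is None:
        raise ValueError("make_family requires seed_motif")
    family_name = family_name or f"{cfg.label_prefix}-Mir-1"
    rng = np.random.default_rng(cfg.rng_seed)
    anc = rng.integers(0, 4, size=cfg.length)
    t = cfg.divergence / 2.0
    motif_codes = np.array([{"A": 0, "C": 1, "G": 2, "U": 3}[c] for c in cfg.seed_motif])
    records = []
    for i in range(cfg.n_sequences):
        codes = _evolve_codes(anc, t, cfg.kappa, rng)
        codes[_SEED_SLICE] = motif_codes
        records.append(
            SequenceRecord.from_sequence(f"{family_name}-P{i + 1}", _codes_to_str(codes))
        )
    return records


def make_dataset(cfgs: Sequence[SimConfig]) -> list[SequenceRecord]:
    """Concatenate simulated families and background sets, labels unique.

    Configs with a seed motif produce families; configs without produce
    independent uniform-random sequences (unrelated background miRNAs).
    Each config uses its own rng_seed, so a dataset is reproducible
    element-wise.
    """
    if not cfgs:
        raise ValueError("make_dataset needs at least one SimConfig")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for k, cfg in enumerate(cfgs, 1):
        if cfg.seed_motif is not None:
            batch = make_family(cfg, family_name=f"{cfg.label_prefix}-Mir-{k}")
        else:
            rng = np.random.default_rng(cfg.rng_seed)
            batch = [
                SequenceRecord.from_sequence(
                    f"{cfg.label_prefix}-Mir-{k}-bg{i + 1}",
                    _codes_to_str(rng.integers(0, 4, size=cfg.length)),
                )
                for i in range(cfg.n_sequences)
            ]
        for rec in batch:
            if rec.id in seen:
                raise ValueError(f"label collision: {rec.id!r}")
            seen.add(rec.id)
        records.extend(batch)
    return records


def sample_gamma(alpha: float, beta: float, n: int, rng_seed: int = 0) -> np.ndarray:
    """i.i.d. draws from Gamma(shape=alpha, scale=beta), reproducible."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.random.default_rng(rng_seed).gamma(shape=alpha, scale=beta, size=n)
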