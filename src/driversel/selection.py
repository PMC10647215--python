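"""Short-term somatic selection on mutated genes.

The neutral expectation for a gene comes from enumerating every possible
point mutation of its coding sequence ("saturated" mutagenesis) through the
standard genetic code, weighting each substitution by a mutation-rate model.
This yields the expected proportions of synonymous, missense and truncating
(stop-gained) changes under neutrality, plus per-codon weights used for
sampling and hotspot nulls.

Observed counts are then compared with the expectation in a three-category
multinomial likelihood with category probabilities proportional to
``(p_syn, ω·p_mis, φ·p_trunc)``: synonymous mutations are the neutral
baseline, ω scales missense and φ scales truncating mutations.  The MLE has
a closed form (ratio of observed to expected odds against synonymous),
which the test suite verifies against a numerical maximizer.  Logs are
clamped to [−5, 5]: zero counts or opportunities saturate the clamp instead
of producing infinities.  Positive log values indicate positive selection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .io_formats import (
    MISSENSE,
    NONSENSE,
    SYNONYMOUS,
    TRUNCATING_CONSEQUENCES,
    MutationRecord,
    ValidationError,
)

logger = logging.getLogger("driversel")

BASES = "ACGT"
_TABLE = unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
CODON_TO_AA = dict(_TABLE.forward_table)

LOG_CLAMP = 5.0

#: substitution class indices in all per-site weight arrays
SYN, MIS, TRUNC = 0, 1, 2

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class UndefinedEstimateError(ValueError):
    """No observed mutations at all: selection coefficients are undefined."""


class ImpossibleObservationError(ValueError):
    """Observed mutations in a class with zero neutral opportunity."""


@dataclass(frozen=True)
class MutationModel:
    """Relative rates for the 12 directed single-base substitutions."""

    rates: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        for pair, rate in self.rates.items():
            if rate <= 0:
                raise ValidationError(f"substitution rate for {pair} must be > 0")

    @classmethod
    def uniform(cls) -> "MutationModel":
        return cls({(a, b): 1.0 for a in BASES for b in BASES if a != b})

    @classmethod
    def ts_tv(cls, kappa: float) -> "MutationModel":
        """Transition/transversion model: transitions weighted by kappa."""
        return cls(
            {
                (a, b): (kappa if (a, b) in _TRANSITIONS else 1.0)
                for a in BASES
                for b in BASES
                if a != b
            }
        )

    def rate(self, ref: str, alt: str) -> float:
        return self.rates[(ref, alt)]


def _codon_changes(codon: str) -> list[tuple[int, str, int]]:
    """All 9 single-base changes of a codon: (offset, alt base, class)."""
    aa = CODON_TO_AA[codon]
    out = []
    for off in range(3):
        for alt in BASES:
            if alt == codon[off]:
                continue
            new = codon[:off] + alt + codon[off + 1 :]
            if new in STOP_CODONS:
                cls = TRUNC
            elif CODON_TO_AA[new] == aa:
                cls = SYN
            else:
                cls = MIS
            out.append((off, alt, cls))
    return out


_CODON_CHANGES = {c: _codon_changes(c) for c in CODON_TO_AA}


@dataclass
class SaturatedExpectation:
    """Neutral mutational opportunity of one coding sequence.

    ``site_weights[i, k]`` is the summed model rate of substitutions at
    codon i (protein position i+1) falling in class k (syn/mis/trunc); the
    gene-level proportions are the normalized column sums.
    """

    p_syn: float
    p_mis: float
    p_trunc: float
    site_weights: np.ndarray  # (n_codons, 3)

    @property
    def n_codons(self) -> int:
        return self.site_weights.shape[0]

    def proportions(self) -> np.ndarray:
        return np.array([self.p_syn, self.p_mis, self.p_trunc])


def enumerate_saturated_mutations(
    cds: str, model: MutationModel | None = None
) -> SaturatedExpectation:
    """Enumerate all point mutations of a CDS and classify their effects.

    A trailing stop codon, if present, is excluded from the enumeration.
    Internal stop codons are rejected.
    """
    if model is None:
        model = MutationModel.uniform()
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValidationError(f"CDS length {len(cds)} not divisible by 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    for idx, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise ValidationError(f"internal stop codon at codon index {idx}")
        if codon not in CODON_TO_AA:
            raise ValidationError(f"invalid codon {codon!r} at index {idx}")
    weights = np.zeros((len(codons), 3))
    for idx, codon in enumerate(codons):
        for off, alt, cls in _CODON_CHANGES[codon]:
            weights[idx, cls] += model.rate(codon[off], alt)
    totals = weights.sum(axis=0)
    grand = totals.sum()
    if grand <= 0:
        raise ValidationError("empty CDS: no substitutions to enumerate")
    p = totals / grand
    return SaturatedExpectation(
        p_syn=float(p[SYN]), p_mis=float(p[MIS]), p_trunc=float(p[TRUNC]), site_weights=weights
    )


@dataclass(frozen=True)
class MutationCounts:
    """Observed per-gene counts; truncating = nonsense + frameshift."""

    n_syn: int
    n_mis: int
    n_trunc: int

    def __post_init__(self) -> None:
        if min(self.n_syn, self.n_mis, self.n_trunc) < 0:
            raise ValidationError("mutation counts must be non-negative")

    @classmethod
    def from_records(cls, records: Iterable[MutationRecord]) -> "MutationCounts":
        n_syn = n_mis = n_trunc = 0
        for rec in records:
            if rec.consequence == SYNONYMOUS:
                n_syn += 1
            elif rec.consequence == MISSENSE:
                n_mis += 1
            elif rec.consequence in TRUNCATING_CONSEQUENCES:
                n_trunc += 1
        return cls(n_syn, n_mis, n_trunc)

    @property
    def total(self) -> int:
        return self.n_syn + self.n_mis + self.n_trunc


@dataclass(frozen=True)
class SelectionEstimate:
    """ω (missense) and φ (truncating) with clamped natural logs."""

    omega: float
    phi: float
    log_omega: float
    log_phi: float


def clamp_log(x: float) -> float:
    """Natural log clamped to [−5, 5]; ln 0 saturates at −5."""
    if x < 0:
        raise ValidationError(f"clamp_log requires x >= 0, got {x}")
    if x == 0:
        return -LOG_CLAMP
    return min(LOG_CLAMP, max(-LOG_CLAMP, math.log(x)))


def _ratio_mle(n_obs: int, n_syn: int, p_obs: float, p_syn: float, name: str) -> float:
    if p_obs == 0:
        if n_obs > 0:
            raise ImpossibleObservationError(
                f"observed {n_obs} {name} mutations but neutral opportunity is zero"
            )
        return 0.0
    if n_obs == 0:
        return 0.0
    if n_syn == 0:
        return math.inf
    return (n_obs / n_syn) * (p_syn / p_obs)


def estimate_selection(
    counts: MutationCounts, expectation: SaturatedExpectation
) -> SelectionEstimate:
    """Maximum-likelihood ω and φ against the saturated neutral expectation.

    The multinomial with category probabilities ∝ (p_syn, ω·p_mis, φ·p_trunc)
    is maximized by the observed/expected odds ratios against the synonymous
    baseline; degenerate counts saturate the ±5 log clamp.
    """
    if counts.total == 0:
        raise UndefinedEstimateError("all mutation counts are zero")
    p_syn, p_mis, p_trunc = expectation.p_syn, expectation.p_mis, expectation.p_trunc
    if p_syn == 0:
        raise ValidationError("CDS offers no synonymous opportunity; baseline undefined")
    omega = _ratio_mle(counts.n_mis, counts.n_syn, p_mis, p_syn, "missense")
    phi = _ratio_mle(counts.n_trunc, counts.n_syn, p_trunc, p_syn, "truncating")
    log_omega = LOG_CLAMP if omega == math.inf else clamp_log(omega)
    log_phi = LOG_CLAMP if phi == math.inf else clamp_log(phi)
    return SelectionEstimate(omega=omega, phi=phi, log_omega=log_omega, log_phi=log_phi)


def multinomial_loglik(
    omega: float, phi: float, counts: MutationCounts, expectation: SaturatedExpectation
) -> float:
    """Log-likelihood of (ω, φ); exposed for the numerical cross-check."""
    w = np.array(
        [expectation.p_syn, omega * expectation.p_mis, phi * expectation.p_trunc]
    )
    z = w.sum()
    n = np.array([counts.n_syn, counts.n_mis, counts.n_trunc], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > 0, n * np.log(w / z), 0.0)
    return float(terms.sum())
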