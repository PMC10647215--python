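"""Turning forest probabilities into OG/TSG/PG calls, the 20/20-rule
baseline, and concordance summaries between prediction sets.

A gene is called a driver (OG or TSG) only when that class has the maximum
probability AND the probability exceeds the cutoff (default 0.5); otherwise
it is a passenger.  The 20/20 rule is the classical frequency heuristic:
>20% truncating mutations → TSG, >20% missense mutations at recurrent
positions → OG.  Concordance between two prediction sets (optionally linked
through an ortholog map) is summarized as a 3×3 confusion table with
accuracy, per-class PPV/NPV/sensitivity/specificity, always reporting raw
counts next to the ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, feature_array
from .forest import CLASSES, KIND_ADAPTED, KIND_SOURCE, Forest, predict_proba
from .io_formats import (
    CODING_CONSEQUENCES,
    MISSENSE,
    TRUNCATING_CONSEQUENCES,
    MutationRecord,
    MutationTable,
    PredictionRecord,
    ValidationError,
)

logger = logging.getLogger("driversel")

DEFAULT_CUTOFF = 0.5
RULE_2020_THRESHOLD = 0.20
RECURRENT_MIN_COUNT = 2


def classify(
    forest: Forest,
    features: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[PredictionRecord]:
    """Per-gene class calls from forest probabilities.

    The feature matrix is standardized with the forest's stored source
    parameters when present.  An un-adapted source forest is accepted with
    a warning (its calibration belongs to the source domain).
    """
    if not 0.0 < cutoff < 1.0:
        raise ValidationError(f"cutoff must lie in (0, 1), got {cutoff}")
    if forest.kind == KIND_SOURCE:
        logger.warning("classifying with an un-adapted source forest")
    X = feature_array(features)
    if forest.standardization is not None:
        X = forest.standardization.transform(X)
    proba = predict_proba(forest, X)
    records: list[PredictionRecord] = []
    for gene, row, p in zip(features.index, X, proba):
        k = int(np.argmax(p))
        label = CLASSES[k]
        if label in ("OG", "TSG") and p[k] <= cutoff:
            label = "PG"
            k = CLASSES.index("PG")
        records.append(
            PredictionRecord(
                gene=str(gene),
                class_label=label,
                probability=float(p[k]),
                log_omega=float(features.loc[gene, "log_omega"]),
                log_phi=float(features.loc[gene, "log_phi"]),
                feature_vector=tuple(float(v) for v in features.loc[gene, list(FEATURE_NAMES)]),
            )
        )
    return records


def rule_20_20(records: Sequence[MutationRecord]) -> str:
    """The 20/20 frequency heuristic for one gene's mutations.

    Truncating fraction > 20% → TSG; else missense-at-recurrent-positions
    fraction > 20% → OG (recurrent = position with >= 2 missense
    mutations); else PG.  When both thresholds are exceeded TSG wins.
    Fractions are over all coding mutations.
    """
    coding = [r for r in records if r.consequence in CODING_CONSEQUENCES]
    n = len(coding)
    if n == 0:
        return "PG"
    n_trunc = sum(1 for r in coding if r.consequence in TRUNCATING_CONSEQUENCES)
    if n_trunc / n > RULE_2020_THRESHOLD:
        return "TSG"
    mis_counts: dict[int, int] = {}
    for r in coding:
        if r.consequence == MISSENSE:
            mis_counts[r.protein_pos] = mis_counts.get(r.protein_pos, 0) + 1
    n_recurrent = sum(c for c in mis_counts.values() if c >= RECURRENT_MIN_COUNT)
    if n_recurrent / n > RULE_2020_THRESHOLD:
        return "OG"
    return "PG"


def rule_20_20_table(table: MutationTable) -> dict[str, str]:
    """20/20-rule call per gene of a (filtered) mutation table."""
    return {g: rule_20_20(table.for_gene(g)) for g in table.genes()}


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------


class NoOverlapError(ValueError):
    """The two prediction sets share no (mapped) genes."""


@dataclass
class ConcordanceSummary:
    """3×3 confusion counts plus derived metrics.

    Set A is the reference (surrogate truth); rows of the confusion table
    are A's classes, columns are B's.  All ratios are reported with their
    numerator/denominator counts.
    """

    confusion: pd.DataFrame
    n_pairs: int
    accuracy: float
    per_class: dict[str, dict[str, tuple[float, int, int]]]  # class -> metric -> (value, num, den)

    @property
    def n_concordant(self) -> int:
        return int(np.diag(self.confusion.to_numpy()).sum())


def _safe_ratio(num: int, den: int) -> tuple[float, int, int]:
    return (num / den if den else float("nan"), num, den)


def concordance(
    preds_a: Mapping[str, str] | Sequence[PredictionRecord],
    preds_b: Mapping[str, str] | Sequence[PredictionRecord],
    ortholog_map: Mapping[str, str] | None = None,
) -> ConcordanceSummary:
    """Concordance between two prediction sets over shared/mapped genes.

    ``ortholog_map`` maps A-namespace genes to B-namespace genes; identity
    when omitted.  Unmapped genes are excluded with a logged count.  Set A
    is treated as the reference for PPV/NPV/sensitivity/specificity.
    """
    a = {p.gene: p.class_label for p in preds_a} if not isinstance(preds_a, Mapping) else dict(preds_a)
    b = {p.gene: p.class_label for p in preds_b} if not isinstance(preds_b, Mapping) else dict(preds_b)
    pairs: list[tuple[str, str]] = []
    n_unmapped = 0
    for gene_a, label_a in a.items():
        gene_b = ortholog_map.get(gene_a, None) if ortholog_map is not None else gene_a
        if gene_b is None or gene_b not in b:
            n_unmapped += 1
            continue
        pairs.append((label_a, b[gene_b]))
    if n_unmapped:
        logger.info("%d genes excluded from concordance (unmapped or unshared)", n_unmapped)
    if not pairs:
        raise NoOverlapError("no shared genes between the two prediction sets")

    conf = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES))
    for la, lb in pairs:
        conf.loc[la, lb] += 1
    total = len(pairs)
    m = conf.to_numpy()
    accuracy = float(np.trace(m)) / total

    per_class: dict[str, dict[str, tuple[float, int, int]]] = {}
    for k, cls in enumerate(CLASSES):
        tp = int(m[k, k])
        fp = int(m[:, k].sum() - tp)          # B called cls, A disagrees
        fn = int(m[k, :].sum() - tp)          # A is cls, B missed it
        tn = total - tp - fp - fn
        per_class[cls] = {
            "ppv": _safe_ratio(tp, tp + fp),
            "npv": _safe_ratio(tn, tn + fn),
            "sensitivity": _safe_ratio(tp, tp + fn),
            "specificity": _safe_ratio(tn, tn + fp),
        }
    return ConcordanceSummary(
        confusion=conf, n_pairs=total, accuracy=accuracy, per_class=per_class
    )


# ---------------------------------------------------------------------------
# Method comparison (adapted forest vs. 20/20 rule)
# ---------------------------------------------------------------------------


@dataclass
class AgreementReport:
    """Per-class shared and method-exclusive calls between two methods."""

    shared: dict[str, list[str]]
    only_a: dict[str, list[str]]
    only_b: dict[str, list[str]]


def compare_rules(
    preds_a: Mapping[str, str] | Sequence[PredictionRecord],
    preds_b: Mapping[str, str] | Sequence[PredictionRecord],
) -> AgreementReport:
    """Shared and exclusive driver calls, per class, for two methods run on
    the same filtered gene set."""
    a = {p.gene: p.class_label for p in preds_a} if not isinstance(preds_a, Mapping) else dict(preds_a)
    b = {p.gene: p.class_label for p in preds_b} if not isinstance(preds_b, Mapping) else dict(preds_b)
    if set(a) != set(b):
        raise ValidationError(
            "the two prediction sets cover different genes; run both methods "
            "on the same filtered gene set"
        )
    shared: dict[str, list[str]] = {c: [] for c in CLASSES}
    only_a: dict[str, list[str]] = {c: [] for c in CLASSES}
    only_b: dict[str, list[str]] = {c: [] for c in CLASSES}
    for gene in sorted(a):
        la, lb = a[gene], b[gene]
        if la == lb:
            shared[la].append(gene)
        else:
            only_a[la].append(gene)
            only_b[lb].append(gene)
    return AgreementReport(shared=shared, only_a=only_a, only_b=only_b)
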