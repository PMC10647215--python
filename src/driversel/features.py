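"""The 10-predictor feature vector per gene, and the gene inclusion filter.

Feature order (fixed, used by the forest and all serialization):
E_gene, E_summit, log_omega, log_phi, R_missense, R_truncating, R_peak,
R_summit, C_summit, R_length.

The six mutation-distribution features:

* R_missense / R_truncating — fractions of all coding mutations (the
  denominator includes synonymous mutations).
* summit — the protein position with the most non-synonymous mutations
  (ties broken toward the lowest position; genes whose coding mutations are
  all synonymous fall back to counting every coding mutation).
* C_summit — mutation count at the summit; R_summit = C_summit / N.
* R_peak — fraction of coding mutations within ±window_aa of the summit.
* R_length — mean relative protein position of truncating mutations
  (1.0 when no truncating mutations: the protein stays full length).
  Low values (early truncation) are the tumor-suppressor signature.

Only genes with at least ``min_mutations`` (default 5) coding mutations
enter classification.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CODING_CONSEQUENCES,
    NONSYNONYMOUS_CONSEQUENCES,
    TRUNCATING_CONSEQUENCES,
    MutationRecord,
    MutationTable,
    ValidationError,
)
from .long_term import RateFeatures
from .selection import SelectionEstimate

logger = logging.getLogger("driversel")

FEATURE_NAMES = (
    "E_gene",
    "E_summit",
    "log_omega",
    "log_phi",
    "R_missense",
    "R_truncating",
    "R_peak",
    "R_summit",
    "C_summit",
    "R_length",
)

DEFAULT_MIN_MUTATIONS = 5
DEFAULT_WINDOW_AA = 5


class UndefinedFeatureError(ValueError):
    """A feature is undefined (e.g. no coding mutations for the gene)."""


def filter_genes(table: MutationTable, min_mutations: int = DEFAULT_MIN_MUTATIONS) -> MutationTable:
    """Keep genes with at least ``min_mutations`` coding mutations.

    Records with consequence ``other`` never count toward the threshold.
    """
    keep = [
        g for g in table.genes() if len(table.coding_for_gene(g)) >= min_mutations
    ]
    dropped = len(table.genes()) - len(keep)
    if dropped:
        logger.info("filter_genes dropped %d genes below %d coding mutations", dropped, min_mutations)
    return table.subset(keep)


def _coding(records: Iterable[MutationRecord]) -> list[MutationRecord]:
    return [r for r in records if r.consequence in CODING_CONSEQUENCES]


def mutation_fractions(records: Sequence[MutationRecord]) -> tuple[float, float]:
    """(R_missense, R_truncating) over all coding mutations of one gene."""
    coding = _coding(records)
    n = len(coding)
    if n == 0:
        raise UndefinedFeatureError("gene has no coding mutations")
    n_mis = sum(1 for r in coding if r.consequence == "missense")
    n_trunc = sum(1 for r in coding if r.consequence in TRUNCATING_CONSEQUENCES)
    return n_mis / n, n_trunc / n


def summit_position(records: Sequence[MutationRecord]) -> int:
    """Most-mutated protein position, by non-synonymous counts.

    Falls back to all coding mutations when the gene has none; ties break
    toward the lowest position.
    """
    coding = _coding(records)
    if not coding:
        raise UndefinedFeatureError("gene has no coding mutations")
    pool = [r for r in coding if r.consequence in NONSYNONYMOUS_CONSEQUENCES] or coding
    counts: dict[int, int] = {}
    for r in pool:
        counts[r.protein_pos] = counts.get(r.protein_pos, 0) + 1
    return min(counts, key=lambda p: (-counts[p], p))


def hotspot_features(
    records: Sequence[MutationRecord], window_aa: int = DEFAULT_WINDOW_AA
) -> tuple[float, float, int]:
    """(R_peak, R_summit, C_summit) for one gene.

    C_summit counts every coding mutation at the summit position; the peak
    is all coding mutations within ±window_aa of the summit.
    """
    coding = _coding(records)
    if not coding:
        raise UndefinedFeatureError("gene has no coding mutations")
    n = len(coding)
    summit = summit_position(records)
    c_summit = sum(1 for r in coding if r.protein_pos == summit)
    in_peak = sum(1 for r in coding if abs(r.protein_pos - summit) <= window_aa)
    return in_peak / n, c_summit / n, c_summit


def truncation_length(records: Sequence[MutationRecord], protein_length: int) -> float:
    """Mean relative position of truncating mutations (1.0 if none)."""
    if protein_length < 1:
        raise ValidationError(f"protein_length must be >= 1, got {protein_length}")
    positions = [
        r.protein_pos for r in records if r.consequence in TRUNCATING_CONSEQUENCES
    ]
    if not positions:
        return 1.0
    return float(np.mean(positions)) / protein_length


def build_feature_matrix(
    table: MutationTable,
    selection: Mapping[str, SelectionEstimate],
    rates: Mapping[str, RateFeatures] | None = None,
    window_aa: int = DEFAULT_WINDOW_AA,
    impute_value: float | None = None,
) -> pd.DataFrame:
    """Assemble the per-gene 10-feature matrix (genes as the index).

    ``rates`` maps gene → (E.gene, E.summit); genes without an entry get
    both long-term features imputed (median of the available E.gene values,
    or ``impute_value`` when given / when no rates exist at all) and the
    ``imputed_rates`` flag column set.  Genes without a selection estimate
    are skipped with a logged reason.
    """
    rates = rates or {}
    available = [rf.e_gene for rf in rates.values() if not rf.imputed]
    if impute_value is None:
        impute_value = float(np.median(available)) if available else 1.0

    rows = []
    index = []
    flags = []
    for gene in table.genes():
        records = table.for_gene(gene)
        est = selection.get(gene)
        if est is None:
            logger.warning("gene %s skipped: no selection estimate", gene)
            continue
        try:
            r_mis, r_trunc = mutation_fractions(records)
            r_peak, r_summit, c_summit = hotspot_features(records, window_aa)
        except UndefinedFeatureError as exc:
            logger.warning("gene %s skipped: %s", gene, exc)
            continue
        r_length = truncation_length(records, table.gene_lengths[gene])
        rf = rates.get(gene)
        if rf is None:
            e_gene = e_summit = impute_value
            imputed = True
        else:
            e_gene, e_summit, imputed = rf.e_gene, rf.e_summit, rf.imputed
        rows.append(
            (e_gene, e_summit, est.log_omega, est.log_phi, r_mis, r_trunc,
             r_peak, r_summit, float(c_summit), r_length)
        )
        index.append(gene)
        flags.append(imputed)
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES), index=pd.Index(index, name="gene"))
    df["imputed_rates"] = flags
    return df


def feature_array(df: pd.DataFrame) -> np.ndarray:
    """The (n_genes, 10) float array in canonical feature order."""
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValidationError(f"feature matrix missing columns {missing}")
    arr = df.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValidationError("feature matrix contains non-finite entries")
    return arr
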