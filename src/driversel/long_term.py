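"""Long-term (cross-species) evolutionary rates at mutated sites.

Per-site substitution counts come from Fitch small parsimony on a dated
species tree; dividing by total tree length (in billions of years) gives a
rate in substitutions per billion years (s/bys).  Two gene-level features
summarize the rates at somatically mutated positions:

* ``E.gene``  — mean rate over the distinct mutated positions of the gene;
* ``E.summit`` — rate at the most frequently mutated position (the summit).

Low rates mean strong purifying selection across species, i.e. functionally
important sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import dendropy
from Bio import SeqIO

from .io_formats import MutationRecord, ValidationError

logger = logging.getLogger("driversel")

#: residues treated as missing data in non-reference rows
GAP_CHARS = frozenset("-.?Xx")


class MappingError(ValueError):
    """A species in the alignment column is absent from the tree."""


@dataclass
class SpeciesAlignment:
    """Aligned protein sequences keyed by species, anchored on a reference.

    ``column_map`` (set by :func:`project_to_reference`) gives, for each
    retained column, its 0-based index in the original alignment; retained
    columns correspond to reference positions 1..k in order.
    """

    sequences: dict[str, str]
    reference_species: str
    column_map: list[int] | None = None

    def __post_init__(self) -> None:
        if self.reference_species not in self.sequences:
            raise ValidationError(
                f"reference species {self.reference_species!r} not in alignment"
            )
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValidationError(f"aligned sequences differ in length: {lengths}")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[self.reference_species])

    def column(self, i: int) -> dict[str, str]:
        return {sp: seq[i] for sp, seq in self.sequences.items()}


def read_alignment_fasta(path: str | Path, reference_species: str) -> SpeciesAlignment:
    """Read a per-gene protein MSA with species names in FASTA headers."""
    sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not sequences:
        raise ValidationError(f"no sequences in {path}")
    return SpeciesAlignment(sequences=sequences, reference_species=reference_species)


@dataclass
class PhyloTree:
    """Rooted species tree with branch lengths in billions of years (bys)."""

    tree: dendropy.Tree

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        return cls(dendropy.Tree.get(data=newick, schema="newick"))

    @classmethod
    def from_file(cls, path: str | Path) -> "PhyloTree":
        return cls(dendropy.Tree.get(path=str(path), schema="newick"))

    @property
    def total_branch_length(self) -> float:
        return sum(e.length or 0.0 for e in self.tree.edges())

    def leaf_labels(self) -> set[str]:
        return {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}

    def scaled(self, factor: float) -> "PhyloTree":
        clone = self.tree.clone(depth=1)
        for e in clone.edges():
            if e.length is not None:
                e.length *= factor
        return PhyloTree(clone)


def project_to_reference(msa: SpeciesAlignment) -> SpeciesAlignment:
    """Drop columns where the reference sequence has a gap.

    The retained columns map 1:1 onto reference protein positions 1..k; the
    mapping back to original column indices is recorded in ``column_map``.
    """
    ref = msa.sequences[msa.reference_species]
    keep = [i for i, c in enumerate(ref) if c not in GAP_CHARS]
    if not keep:
        raise ValidationError("reference sequence is all gaps")
    return SpeciesAlignment(
        sequences={sp: "".join(seq[i] for i in keep) for sp, seq in msa.sequences.items()},
        reference_species=msa.reference_species,
        column_map=keep,
    )


def fitch_site_substitutions(column: Mapping[str, str], tree: PhyloTree) -> int:
    """Minimum number of substitutions explaining one alignment column.

    Classic bottom-up set-intersection pass.  Gaps/missing residues in
    non-reference species are wildcards: the leaf contributes the full
    residue alphabet and never forces a substitution.  Leaves absent from
    the column are likewise treated as missing.  The count is independent of
    the root placement (unordered-tree parsimony).
    """
    leaves = tree.leaf_labels()
    extra = set(column) - leaves
    if extra:
        raise MappingError(f"species {sorted(extra)} not in tree")

    count = 0
    states: dict[int, frozenset | None] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            residue = column.get(node.taxon.label)
            if residue is None or residue in GAP_CHARS:
                states[id(node)] = None  # wildcard
            else:
                states[id(node)] = frozenset((residue,))
        else:
            acc: frozenset | None = None
            for child in node.child_nodes():
                s = states[id(child)]
                if s is None:
                    continue
                if acc is None:
                    acc = s
                else:
                    inter = acc & s
                    if inter:
                        acc = inter
                    else:
                        acc = acc | s
                        count += 1
            states[id(node)] = acc
    return count


def site_rate(substitutions: int, tree: PhyloTree) -> float:
    """Substitution rate in s/bys: count / total tree branch length."""
    total = tree.total_branch_length
    if total <= 0:
        raise ValidationError(f"total branch length must be > 0, got {total}")
    return substitutions / total


def compute_site_rates(msa: SpeciesAlignment, tree: PhyloTree) -> dict[int, float]:
    """Per-reference-position rates for one gene (positions are 1-based)."""
    projected = msa if msa.column_map is not None else project_to_reference(msa)
    total = tree.total_branch_length
    if total <= 0:
        raise ValidationError(f"total branch length must be > 0, got {total}")
    rates: dict[int, float] = {}
    for pos in range(projected.n_columns):
        subs = fitch_site_substitutions(projected.column(pos), tree)
        rates[pos + 1] = subs / total
    return rates


class RateFeatures(NamedTuple):
    e_gene: float
    e_summit: float
    imputed: bool


def gene_rate_features(
    rates: Mapping[int, float],
    mutations: Iterable[MutationRecord],
    impute_value: float = 1.0,
) -> RateFeatures:
    """E.gene and E.summit for one gene.

    E.gene averages rates over *distinct* mutated positions; E.summit is the
    rate at the position carrying the most coding mutations (ties broken
    toward the lowest position).  When no mutated position has rate
    coverage, both features fall back to ``impute_value`` with a warning.
    """
    counts: dict[int, int] = {}
    for rec in mutations:
        if rec.is_coding:
            counts[rec.protein_pos] = counts.get(rec.protein_pos, 0) + 1
    covered = [p for p in counts if p in rates]
    if not covered:
        logger.warning("no mutated position has rate coverage; imputing %.4g", impute_value)
        return RateFeatures(impute_value, impute_value, True)
    e_gene = sum(rates[p] for p in covered) / len(covered)
    summit = min(covered, key=lambda p: (-counts[p], p))
    return RateFeatures(e_gene, rates[summit], False)
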