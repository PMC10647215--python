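"""Synthetic data generators: every input the tool needs, without downloads.

The generators emulate the study conditions end to end: coding sequences,
per-gene somatic mutation sets sampled under specified selection (the
selection model run forward), labeled source-domain and covariate-shifted
unlabeled target-domain feature tables built through the real feature
extraction code, and toy alignments + dated trees for the long-term rate
machinery.  Every generator is a pure function of its scenario and seed.

Class archetypes (defaults, all configurable through the scenario):

* OG  — log ω ~ N(3.5, 1) truncated to [−5, 5], log φ ~ N(−3.5, 1),
  hotspot fraction h = 0.5 (half the missense mutations land on one site);
* TSG — log φ ~ N(3.5, 1), log ω ~ N(0.5, 1), truncating mutations biased
  to the first 40% of the protein;
* PG  — both logs ~ N(0, 0.5), no hotspot.

Long-term rate features are drawn directly from class-conditional
distributions (drivers at conserved, low-rate sites) rather than simulated
through alignments — the alignment path has its own generator
(:func:`gen_toy_phylo`) and the classifier consumes the rates as plain
columns either way.  Mutation counts per gene follow a shifted negative
binomial with minimum 5, matching the gene inclusion filter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, build_feature_matrix
from .io_formats import (
    FRAMESHIFT,
    MISSENSE,
    NONSENSE,
    SYNONYMOUS,
    MutationRecord,
    MutationTable,
    ValidationError,
)
from .long_term import PhyloTree, SpeciesAlignment
from .selection import (
    MIS,
    STOP_CODONS,
    SYN,
    TRUNC,
    MutationCounts,
    SaturatedExpectation,
    SelectionEstimate,
    enumerate_saturated_mutations,
    estimate_selection,
)

logger = logging.getLogger("driversel")

BASES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Scenario
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassArchetype:
    """Parameter distributions generating one gene class."""

    log_omega_mu: float
    log_omega_sd: float
    log_phi_mu: float
    log_phi_sd: float
    hotspot_fraction: float  # fraction h of missense mutations at one site
    trunc_early_frac: float | None  # truncations restricted to this leading protein fraction
    e_gene_mu: float  # long-term rate location (s/bys)
    e_gene_sd: float
    summit_rate_range: tuple[float, float]  # E_summit = E_gene × U(range)


DEFAULT_ARCHETYPES: dict[str, ClassArchetype] = {
    "OG": ClassArchetype(3.5, 1.0, -3.5, 1.0, 0.5, None, 0.4, 0.15, (0.2, 0.8)),
    "TSG": ClassArchetype(0.5, 1.0, 3.5, 1.0, 0.0, 0.4, 0.4, 0.15, (0.2, 0.8)),
    "PG": ClassArchetype(0.0, 0.5, 0.0, 0.5, 0.0, None, 1.2, 0.4, (0.5, 1.5)),
}


@dataclass(frozen=True)
class SyntheticScenario:
    """Everything that determines a generated source/target dataset.

    The seed is mandatory; all distributions are fully specified here.
    """

    seed: int
    n_source_per_class: int = 150
    n_target_per_class: int = 60
    archetypes: dict[str, ClassArchetype] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )
    shift_features: tuple[str, ...] = ("E_gene", "R_peak", "C_summit")
    shift_sd: float = 0.5  # target location shift, in source-SD units
    n_codons_range: tuple[int, int] = (200, 600)
    gc_fraction: float = 0.45
    mutations_nb_r: float = 2.0  # negative-binomial shape of extra mutations
    mutations_nb_mean: float = 7.0  # mean extra mutations beyond the minimum
    min_mutations: int = 5
    n_samples: int = 50
    frameshift_fraction: float = 0.25  # of truncating mutations, labeled frameshift


# ---------------------------------------------------------------------------
# CDS and mutation-set generators
# ---------------------------------------------------------------------------


def gen_cds(n_codons: int, gc_fraction: float, rng: np.random.Generator) -> str:
    """Random CDS: ATG start, stop end, no internal stops, base composition
    tuned to ``gc_fraction``.  ``n_codons`` counts start + internal + stop."""
    if n_codons < 2:
        raise ValidationError(f"n_codons must be >= 2, got {n_codons}")
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )  # A C G T
    bases = "ACGT"
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        codon = "".join(rng.choice(list(bases), size=3, p=p))
        if codon not in STOP_CODONS:
            codons.append(codon)
    codons.append(str(rng.choice(sorted(STOP_CODONS))))
    return "".join(codons)


def _sample_positions(
    weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """k codon indices (0-based) drawn proportionally to per-site weights."""
    total = weights.sum()
    if total <= 0:
        return rng.integers(0, weights.shape[0], size=k)
    return rng.choice(weights.shape[0], size=k, p=weights / total)


def gen_mutations(
    cds: str,
    expectation: SaturatedExpectation,
    log_omega: float,
    log_phi: float,
    h: float,
    n_mutations: int,
    rng: np.random.Generator,
    gene: str = "gene",
    trunc_early_frac: float | None = None,
    hotspot_pos: int | None = None,
    n_samples: int = 50,
    frameshift_fraction: float = 0.0,
) -> list[MutationRecord]:
    """Sample one gene's mutation set under specified selection.

    Class counts come from the multinomial with probabilities proportional
    to (p_syn, e^{log ω}·p_mis, e^{log φ}·p_trunc); positions follow the
    per-site neutral weights, except a fraction ``h`` of missense mutations
    pinned to one hotspot position and, optionally, truncating positions
    restricted to the leading ``trunc_early_frac`` of the protein.
    """
    if n_mutations < 1:
        raise ValidationError(f"n_mutations must be >= 1, got {n_mutations}")
    probs = np.array(
        [
            expectation.p_syn,
            math.exp(log_omega) * expectation.p_mis,
            math.exp(log_phi) * expectation.p_trunc,
        ]
    )
    probs /= probs.sum()
    n_syn, n_mis, n_trunc = rng.multinomial(n_mutations, probs)
    w = expectation.site_weights
    n_codons = expectation.n_codons

    positions: list[tuple[int, str]] = []
    for pos in _sample_positions(w[:, SYN], int(n_syn), rng):
        positions.append((int(pos), SYNONYMOUS))

    if n_mis > 0:
        n_hot = int(rng.binomial(n_mis, h)) if 0 < h < 1 else (int(n_mis) if h >= 1 else 0)
        if n_hot > 0 and hotspot_pos is None:
            hotspot_pos = int(_sample_positions(w[:, MIS], 1, rng)[0])
        for _ in range(n_hot):
            positions.append((int(hotspot_pos), MISSENSE))
        for pos in _sample_positions(w[:, MIS], int(n_mis) - n_hot, rng):
            positions.append((int(pos), MISSENSE))

    if n_trunc > 0:
        trunc_w = w[:, TRUNC].copy()
        if trunc_early_frac is not None:
            cut = max(1, int(n_codons * trunc_early_frac))
            trunc_w[cut:] = 0.0
            if trunc_w.sum() <= 0:
                trunc_w[:cut] = 1.0
        for pos in _sample_positions(trunc_w, int(n_trunc), rng):
            label = (
                FRAMESHIFT if rng.random() < frameshift_fraction else NONSENSE
            )
            positions.append((int(pos), label))

    return [
        MutationRecord(
            gene=gene,
            sample=f"s{int(rng.integers(0, n_samples)):03d}",
            protein_pos=pos + 1,
            consequence=cons,
        )
        for pos, cons in positions
    ]


# ---------------------------------------------------------------------------
# Domain tables
# ---------------------------------------------------------------------------


@dataclass
class DomainTables:
    """Source features (+ labels) and target features (+ hidden labels).

    Hidden target labels exist only for evaluation; the adaptation path
    never sees them.  ``target_mutations`` carries the raw target mutation
    records so frequency-rule baselines can run on the same genes.
    """

    source_features: pd.DataFrame  # 10 features + "label"
    target_features: pd.DataFrame  # 10 features (+ imputed_rates flag)
    target_labels: pd.Series
    target_mutations: MutationTable


def _truncated_normal(
    mu: float, sd: float, lo: float, hi: float, rng: np.random.Generator
) -> float:
    for _ in range(100):
        x = rng.normal(mu, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(rng.normal(mu, sd), lo, hi))


def _gen_gene_set(
    scenario: SyntheticScenario,
    n_per_class: int,
    rng: np.random.Generator,
    prefix: str,
) -> tuple[pd.DataFrame, pd.Series, MutationTable]:
    """One domain's genes: features via the real extraction pipeline."""
    records: list[MutationRecord] = []
    lengths: dict[str, int] = {}
    estimates: dict[str, SelectionEstimate] = {}
    e_rows: dict[str, tuple[float, float]] = {}
    labels: dict[str, str] = {}
    p_extra = scenario.mutations_nb_r / (scenario.mutations_nb_r + scenario.mutations_nb_mean)

    i = 0
    for cls, arch in scenario.archetypes.items():
        for _ in range(n_per_class):
            gene = f"{prefix}{i:04d}"
            i += 1
            n_codons = int(rng.integers(*scenario.n_codons_range))
            cds = gen_cds(n_codons, scenario.gc_fraction, rng)
            expectation = enumerate_saturated_mutations(cds)
            lw = _truncated_normal(arch.log_omega_mu, arch.log_omega_sd, -5, 5, rng)
            lp = _truncated_normal(arch.log_phi_mu, arch.log_phi_sd, -5, 5, rng)
            n_mut = scenario.min_mutations + int(
                rng.negative_binomial(scenario.mutations_nb_r, p_extra)
            )
            gene_records = gen_mutations(
                cds,
                expectation,
                lw,
                lp,
                arch.hotspot_fraction,
                n_mut,
                rng,
                gene=gene,
                trunc_early_frac=arch.trunc_early_frac,
                n_samples=scenario.n_samples,
                frameshift_fraction=scenario.frameshift_fraction,
            )
            records.extend(gene_records)
            lengths[gene] = expectation.n_codons
            estimates[gene] = estimate_selection(
                MutationCounts.from_records(gene_records), expectation
            )
            e_gene = max(float(rng.normal(arch.e_gene_mu, arch.e_gene_sd)), 0.01)
            e_summit = e_gene * float(rng.uniform(*arch.summit_rate_range))
            e_rows[gene] = (e_gene, e_summit)
            labels[gene] = cls

    table = MutationTable(records=records, gene_lengths=lengths)
    from .long_term import RateFeatures

    rates = {g: RateFeatures(eg, es, False) for g, (eg, es) in e_rows.items()}
    feats = build_feature_matrix(table, estimates, rates)
    label_series = pd.Series({g: labels[g] for g in feats.index}, name="label")
    return feats, label_series, table


def gen_domain_tables(scenario: SyntheticScenario) -> DomainTables:
    """Generate the labeled source domain and the shifted unlabeled target.

    The covariate shift adds ``shift_sd`` source standard deviations to the
    configured target feature columns, emulating the accelerated,
    genetically engineered tumorigenesis of the target domain.
    """
    if len(scenario.archetypes) < 2:
        raise ValidationError("source domain needs >= 2 classes to train on")
    rng = np.random.default_rng(scenario.seed)
    src_feats, src_labels, _ = _gen_gene_set(
        scenario, scenario.n_source_per_class, rng, "hs"
    )
    tgt_feats, tgt_labels, tgt_table = _gen_gene_set(
        scenario, scenario.n_target_per_class, rng, "mm"
    )
    for f in scenario.shift_features:
        tgt_feats[f] = tgt_feats[f] + scenario.shift_sd * src_feats[f].std()

    source = src_feats.copy()
    source["label"] = src_labels
    return DomainTables(
        source_features=source,
        target_features=tgt_feats,
        target_labels=tgt_labels,
        target_mutations=tgt_table,
    )


# ---------------------------------------------------------------------------
# Toy alignment + dated tree
# ---------------------------------------------------------------------------


def gen_toy_phylo(
    n_species: int,
    depth_bys: float,
    rate_profile: np.ndarray,
    rng: np.random.Generator,
) -> tuple[SpeciesAlignment, PhyloTree]:
    """Simulate residue columns down a random dated tree.

    Per column c, substitutions occur along each branch of length b as a
    Poisson process with rate ``rate_profile[c]`` (s/bys); each event draws
    a new residue uniformly from the 19 alternatives.  Returns the leaf
    alignment (reference = first species) and the tree.
    """
    rate_profile = np.asarray(rate_profile, dtype=float)
    species = [f"sp{i + 1}" for i in range(n_species)]

    # random bifurcating topology by sequential joining
    nodes: list[tuple] = [(sp,) for sp in species]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        nodes = [n for k, n in enumerate(nodes) if k not in (int(i), int(j))]
        nodes.append((a, b))
    topo = nodes[0]

    def newick(node, length: float) -> str:
        if len(node) == 1:
            return f"{node[0]}:{length:.6f}"
        l = float(rng.uniform(0.2, 1.0)) * depth_bys / max(1, int(np.log2(n_species)) or 1)
        r = float(rng.uniform(0.2, 1.0)) * depth_bys / max(1, int(np.log2(n_species)) or 1)
        return f"({newick(node[0], l)},{newick(node[1], r)}):{length:.6f}"

    tree = PhyloTree.from_newick(newick(topo, 0.0) + ";")

    n_cols = rate_profile.shape[0]
    seqs = {sp: [""] * n_cols for sp in species}
    for c, rate in enumerate(rate_profile):
        root_res = str(rng.choice(list(AMINO_ACIDS)))

        def evolve(node, residue) -> None:
            for child in node.child_nodes():
                res = residue
                n_events = int(rng.poisson(rate * (child.edge.length or 0.0)))
                for _ in range(n_events):
                    res = str(rng.choice([a for a in AMINO_ACIDS if a != res]))
                if child.is_leaf():
                    seqs[child.taxon.label][c] = res
                else:
                    evolve(child, res)

        root = tree.tree.seed_node
        if root.is_leaf():
            seqs[root.taxon.label][c] = root_res
        else:
            evolve(root, root_res)

    alignment = SpeciesAlignment(
        sequences={sp: "".join(chars) for sp, chars in seqs.items()},
        reference_species=species[0],
    )
    return alignment, tree
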