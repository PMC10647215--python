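"""Readers and writers for every external representation the tool touches.

The universal interchange object is the :class:`MutationTable`: per-sample,
per-gene coding mutation records in protein coordinates.  The primary input
format is a MAF-like tab-separated table of pre-annotated somatic mutations;
annotated VCF ingestion is a convenience layer that trusts the existing
SnpEff/VEP consequence annotations rather than re-annotating.

Also implemented here: the versioned JSON model file for (adapted) random
forests, and the tab-separated prediction report whose first line always
carries the "accuracy unknown" caveat — classifier accuracy in the unlabeled
target domain cannot be measured directly, and the report says so.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("driversel")

# ---------------------------------------------------------------------------
# Consequence vocabulary
# ---------------------------------------------------------------------------

SYNONYMOUS = "synonymous"
MISSENSE = "missense"
NONSENSE = "nonsense"
FRAMESHIFT = "frameshift"
OTHER = "other"

CONSEQUENCES = (SYNONYMOUS, MISSENSE, NONSENSE, FRAMESHIFT, OTHER)

#: coding consequences that enter every computation; ``other`` is carried
#: through tables but excluded everywhere
CODING_CONSEQUENCES = frozenset({SYNONYMOUS, MISSENSE, NONSENSE, FRAMESHIFT})
TRUNCATING_CONSEQUENCES = frozenset({NONSENSE, FRAMESHIFT})
NONSYNONYMOUS_CONSEQUENCES = frozenset({MISSENSE, NONSENSE, FRAMESHIFT})

#: Total alias map over the documented consequence vocabulary.  Any input
#: term outside it maps to ``other`` — never silently to a coding class.
CONSEQUENCE_ALIASES: Mapping[str, str] = {
    SYNONYMOUS: SYNONYMOUS,
    "synonymous_variant": SYNONYMOUS,
    "silent": SYNONYMOUS,
    "stop_retained_variant": SYNONYMOUS,
    MISSENSE: MISSENSE,
    "missense_variant": MISSENSE,
    "nonsynonymous_snv": MISSENSE,
    NONSENSE: NONSENSE,
    "stop_gained": NONSENSE,
    "stopgain": NONSENSE,
    FRAMESHIFT: FRAMESHIFT,
    "frameshift_variant": FRAMESHIFT,
    "frameshift_indel": FRAMESHIFT,
    "frameshift_insertion": FRAMESHIFT,
    "frameshift_deletion": FRAMESHIFT,
    OTHER: OTHER,
}


class FormatError(ValueError):
    """Malformed input file (missing column, bad header, bad annotation)."""


class ValidationError(ValueError):
    """Input violates a domain invariant (e.g. position beyond protein end)."""


class ModelVersionError(ValueError):
    """Model file written by an incompatible schema version."""


def normalize_consequence(term: str) -> str:
    """Map an annotation term onto the five-way consequence vocabulary.

    Unknown terms map to ``other`` with a logged warning; they never reach a
    coding class by accident.
    """
    key = term.strip().lower()
    if key in CONSEQUENCE_ALIASES:
        return CONSEQUENCE_ALIASES[key]
    logger.warning("unknown consequence term %r mapped to 'other'", term)
    return OTHER


# ---------------------------------------------------------------------------
# Mutation records and tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationRecord:
    """One observed somatic mutation in protein coordinates (1-based)."""

    gene: str
    sample: str
    protein_pos: int
    consequence: str
    aa_change: str | None = None

    def __post_init__(self) -> None:
        if self.protein_pos < 1:
            raise ValidationError(
                f"protein_pos must be >= 1, got {self.protein_pos} ({self.gene})"
            )
        if self.consequence not in CONSEQUENCES:
            raise ValidationError(
                f"consequence {self.consequence!r} not in {CONSEQUENCES}"
            )

    @property
    def is_coding(self) -> bool:
        return self.consequence in CODING_CONSEQUENCES


@dataclass
class MutationTable:
    """Ordered mutation records plus per-gene protein lengths (amino acids).

    Duplicate records are meaningful: each row is one observed mutation.
    """

    records: list[MutationRecord]
    gene_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for i, rec in enumerate(self.records):
            length = self.gene_lengths.get(rec.gene)
            if length is None:
                raise ValidationError(f"gene {rec.gene} has no protein length entry")
            if rec.protein_pos > length:
                raise ValidationError(
                    f"row {i}: gene {rec.gene} protein_pos {rec.protein_pos} "
                    f"exceeds protein length {length}"
                )

    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.gene, None)
        return list(seen)

    def for_gene(self, gene: str) -> list[MutationRecord]:
        return [r for r in self.records if r.gene == gene]

    def coding_for_gene(self, gene: str) -> list[MutationRecord]:
        return [r for r in self.records if r.gene == gene and r.is_coding]

    def subset(self, genes: Iterable[str]) -> "MutationTable":
        keep = set(genes)
        return MutationTable(
            records=[r for r in self.records if r.gene in keep],
            gene_lengths={g: l for g, l in self.gene_lengths.items() if g in keep},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [r.gene for r in self.records],
                "sample": [r.sample for r in self.records],
                "protein_pos": [r.protein_pos for r in self.records],
                "consequence": [r.consequence for r in self.records],
                "protein_length": [self.gene_lengths[r.gene] for r in self.records],
                "aa_change": [r.aa_change or "" for r in self.records],
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MutationTable):
            return NotImplemented
        return (
            self.records == other.records and self.gene_lengths == other.gene_lengths
        )


REQUIRED_TABLE_COLUMNS = ("gene", "sample", "protein_pos", "consequence", "protein_length")


def read_mutation_table(path: str | Path) -> MutationTable:
    """Read the MAF-like tab-separated mutation table.

    Required columns: gene, sample, protein_pos, consequence, protein_length.
    Consequence strings run through the alias map; duplicate rows are kept
    (each one is an observed mutation).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in REQUIRED_TABLE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"mutation table {path} is missing column {col!r}")
    records: list[MutationRecord] = []
    gene_lengths: dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        gene = str(row.gene)
        length = int(row.protein_length)
        prev = gene_lengths.setdefault(gene, length)
        if prev != length:
            raise ValidationError(
                f"gene {gene} has inconsistent protein_length ({prev} vs {length})"
            )
        pos = int(row.protein_pos)
        if pos > length:
            raise ValidationError(
                f"row {i}: gene {gene} protein_pos {pos} exceeds protein_length {length}"
            )
        aa = getattr(row, "aa_change", None)
        if aa is None or (isinstance(aa, float) and pd.isna(aa)) or str(aa) in ("", "nan"):
            aa = None
        records.append(
            MutationRecord(
                gene=gene,
                sample=str(row.sample),
                protein_pos=pos,
                consequence=normalize_consequence(str(row.consequence)),
                aa_change=aa,
            )
        )
    return MutationTable(records=records, gene_lengths=gene_lengths)


def write_mutation_table(table: MutationTable, path: str | Path) -> None:
    """Inverse of :func:`read_mutation_table` (lossless round-trip)."""
    table.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Annotated VCF ingestion
# ---------------------------------------------------------------------------

# matches p.Val600Glu, p.(S108*), p.Ter123Leu ...
_HGVS_P_RE = re.compile(r"p\.\(?(?:[A-Za-z]{1,3}|\*)(\d+)")


def _annotation_field_names(vcf, annotation_field: str) -> list[str]:
    try:
        header = vcf.get_header_type(annotation_field)
    except KeyError as exc:
        raise FormatError(
            f"VCF header does not define INFO field {annotation_field!r}"
        ) from exc
    desc = header.get("Description", "")
    if "Format:" in desc:  # VEP-style: "... Format: Allele|Consequence|..."
        fmt = desc.split("Format:", 1)[1]
    elif ":" in desc and "|" in desc:  # SnpEff-style: "Functional annotations: 'Allele | ...'"
        fmt = desc.split(":", 1)[1]
    else:
        return []
    return [f.strip(" '\"") for f in fmt.split("|")]


def _lookup(names: list[str], entry: list[str], candidates: Sequence[str]) -> str | None:
    for cand in candidates:
        if cand in names:
            idx = names.index(cand)
            if idx < len(entry):
                return entry[idx]
    return None


def read_vcf_annotated(
    path: str | Path,
    annotation_field: str = "ANN",
    gene_lengths: Mapping[str, int] | None = None,
) -> MutationTable:
    """Read somatic mutations from an annotated VCF (SnpEff ANN / VEP CSQ).

    Only the FIRST annotation entry per record is used (annotation tools
    order entries by putative impact).  Records lacking a parsable protein
    position are skipped, with a logged count.  VCF carries no protein
    lengths; pass ``gene_lengths`` or the per-gene maximum observed position
    is used as a lower-bound stand-in (logged).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    names = _annotation_field_names(vcf, annotation_field)
    sample = vcf.samples[0] if vcf.samples else Path(path).stem

    records: list[tuple[str, int, str, str | None]] = []
    n_skipped = 0
    for variant in vcf:
        raw = variant.INFO.get(annotation_field)
        if raw is None:
            n_skipped += 1
            continue
        entry = str(raw).split(",")[0].split("|")
        gene = _lookup(names, entry, ("Gene_Name", "SYMBOL", "Gene"))
        term = _lookup(names, entry, ("Annotation", "Consequence"))
        if not gene or not term:
            n_skipped += 1
            continue
        term = term.split("&")[0]
        pos: int | None = None
        hgvs_p = _lookup(names, entry, ("HGVS.p", "HGVSp"))
        if hgvs_p:
            m = _HGVS_P_RE.search(hgvs_p)
            if m:
                pos = int(m.group(1))
        if pos is None:
            raw_pos = _lookup(names, entry, ("Protein_position", "AA.pos / AA.length"))
            if raw_pos:
                m = re.match(r"(\d+)", raw_pos.split("/")[0].strip())
                if m:
                    pos = int(m.group(1))
        if pos is None:
            n_skipped += 1
            continue
        records.append((gene, pos, normalize_consequence(term), hgvs_p))
    if n_skipped:
        logger.info("skipped %d VCF records without usable annotation", n_skipped)

    if gene_lengths is None:
        lengths: dict[str, int] = {}
        for gene, pos, _, _ in records:
            lengths[gene] = max(lengths.get(gene, 0), pos)
        logger.info(
            "no protein lengths supplied; using per-gene max observed position"
        )
    else:
        lengths = dict(gene_lengths)
    return MutationTable(
        records=[
            MutationRecord(gene=g, sample=sample, protein_pos=p, consequence=c, aa_change=a)
            for g, p, c, a in records
        ],
        gene_lengths=lengths,
    )


# ---------------------------------------------------------------------------
# Prediction report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PredictionRecord:
    """Final per-gene call with its class probability and selection logs."""

    gene: str
    class_label: str
    probability: float
    log_omega: float
    log_phi: float
    feature_vector: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValidationError(f"probability {self.probability} outside [0, 1]")
        if self.class_label not in ("OG", "TSG", "PG"):
            raise ValidationError(f"unknown class label {self.class_label!r}")
        if self.class_label in ("OG", "TSG") and self.probability <= 0.5:
            raise ValidationError(
                f"{self.class_label} call requires probability > 0.5, "
                f"got {self.probability}"
            )


ACCURACY_UNKNOWN_NOTICE = (
    "# accuracy unknown: classifier adapted to an unlabeled target domain; "
    "interpret predictions with caution"
)


def _fmt(x: float) -> str:
    return format(float(x), ".6g")


def write_predictions(records: Iterable[PredictionRecord], path: str | Path) -> None:
    """Write the prediction report.

    The first line always contains the literal "accuracy unknown" notice:
    there is no labeled target-domain data against which the adapted
    classifier could have been validated.
    """
    with open(path, "w") as fh:
        fh.write(ACCURACY_UNKNOWN_NOTICE + "\n")
        fh.write("Symbol\tlog(omega)\tlog(phi)\tClass\tProb.\n")
        for rec in records:
            fh.write(
                f"{rec.gene}\t{_fmt(rec.log_omega)}\t{_fmt(rec.log_phi)}\t"
                f"{rec.class_label}\t{_fmt(rec.probability)}\n"
            )


def read_predictions(path: str | Path) -> list[PredictionRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        PredictionRecord(
            gene=str(row["Symbol"]),
            class_label=str(row["Class"]),
            probability=float(row["Prob."]),
            log_omega=float(row["log(omega)"]),
            log_phi=float(row["log(phi)"]),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Versioned model files
# ---------------------------------------------------------------------------

MODEL_FORMAT = "driversel-forest"
MODEL_VERSION = 1


def _node_to_dict(node) -> dict:
    out = {"dist": [float(p) for p in node.dist], "n": int(node.n)}
    if not node.is_leaf:
        out["feature"] = int(node.feature)
        out["threshold"] = float(node.threshold)
        out["left"] = _node_to_dict(node.left)
        out["right"] = _node_to_dict(node.right)
    return out


def _node_from_dict(d: dict):
    from .forest import Node

    dist = np.asarray(d["dist"], dtype=float)
    if "feature" in d:
        return Node(
            feature=int(d["feature"]),
            threshold=float(d["threshold"]),
            left=_node_from_dict(d["left"]),
            right=_node_from_dict(d["right"]),
            dist=dist,
            n=int(d["n"]),
        )
    return Node(feature=None, threshold=None, left=None, right=None, dist=dist, n=int(d["n"]))


def save_model(forest, path: str | Path) -> None:
    """Serialize a forest to the versioned JSON model schema (diffable text)."""
    from .forest import Forest  # noqa: F401  (type documented here)

    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "kind": forest.kind,
        "config": dataclasses.asdict(forest.config) if forest.config else None,
        "standardization": (
            {
                "center": [float(c) for c in forest.standardization.center],
                "scale": [float(s) for s in forest.standardization.scale],
            }
            if forest.standardization is not None
            else None
        ),
        "trees": [
            {"variant": t.variant, "root": _node_to_dict(t.root)} for t in forest.trees
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path: str | Path):
    from .forest import DecisionTree, Forest, TrainConfig
    from .transfer import StandardizationParams

    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != MODEL_FORMAT or payload.get("version") != MODEL_VERSION:
        raise ModelVersionError(
            f"model file {path} has format/version "
            f"{payload.get('format')!r}/{payload.get('version')!r}; "
            f"expected {MODEL_FORMAT!r}/{MODEL_VERSION}"
        )
    config = TrainConfig(**payload["config"]) if payload.get("config") else None
    std = None
    if payload.get("standardization"):
        std = StandardizationParams(
            center=np.asarray(payload["standardization"]["center"], dtype=float),
            scale=np.asarray(payload["standardization"]["scale"], dtype=float),
        )
    trees = [
        DecisionTree(root=_node_from_dict(t["root"]), variant=t["variant"])
        for t in payload["trees"]
    ]
    return Forest(trees=trees, kind=payload["kind"], config=config, standardization=std)
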