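"""Per-omics signature sets and their harmonization.

A signature set is a named collection of gene symbols flagged as
disease-associated on one omics level (transcriptome, genome, proteome, or
metabolome-derived).  Symbols are uppercased and deduplicated so that gene
symbols can serve as the integration key across data sources.  Metabolite
signatures are converted to genes through a scored metabolite-reaction-
protein table; a strict confidence-score cutoff (> 4 by default) keeps only
high-confidence metabolite-protein links.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "LEVELS",
    "SignatureSet",
    "load_signature",
    "metabolite_to_genes",
    "cross_level_overlap",
    "protein_level_union",
]

logger = logging.getLogger(__name__)

LEVELS = ("transcriptome", "genome", "proteome", "metabolome_derived")


@dataclass
class SignatureSet:
    level: str
    genes: set[str]
    direction: dict[str, str] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")
        normalized = {g.strip().upper() for g in self.genes}
        normalized.discard("")
        if not all(normalized):
            raise ValueError("gene symbols must be non-empty")
        self.genes = normalized
        self.direction = {
            g.strip().upper(): d for g, d in self.direction.items()
        }

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes


def load_signature(path, level: str) -> SignatureSet:
    """Load a signature gene list (one symbol per line, or TSV with a
    ``gene`` column and optional ``direction`` column).

    Symbols are uppercased; duplicates are collapsed and the collapse count
    is logged.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"signature file {path} is empty")
    first = text.splitlines()[0]
    direction: dict[str, str] = {}
    if "\t" in first or first.lower().startswith("gene"):
        df = pd.read_csv(path, sep="\t")
        if "gene" not in df.columns:
            # single-column file whose header happened to contain no tab
            df = pd.read_csv(path, sep="\t", header=None, names=["gene"])
        raw = [str(g) for g in df["gene"]]
        if "direction" in df.columns:
            direction = dict(zip(raw, df["direction"].astype(str)))
    else:
        raw = []
        for i, line in enumerate(text.splitlines(), start=1):
            sym = line.strip()
            if not sym:
                continue
            if any(ch.isspace() for ch in sym):
                raise ValueError(f"{path}: unparseable line {i}: {line!r}")
            raw.append(sym)
    genes = {g.strip().upper() for g in raw}
    n_dup = len(raw) - len(genes)
    if n_dup:
        logger.info("%s: collapsed %d duplicate symbol(s)", path.name, n_dup)
    return SignatureSet(level=level, genes=genes, direction=direction,
                        provenance=str(path))


def metabolite_to_genes(
    metabolites,
    reactions: pd.DataFrame,
    min_score: float = 4.0,
) -> SignatureSet:
    """Map disease-associated metabolites to genes through scored reactions.

    Keeps proteins whose reaction confidence score is strictly greater than
    ``min_score`` for any listed metabolite, then collapses to unique gene
    symbols.  Metabolites absent from the table are logged, not fatal; rows
    with an empty gene mapping are dropped with a log entry.
    """
    required = {"metabolite", "protein", "confidence_score", "gene"}
    if not required <= set(reactions.columns):
        raise ValueError(f"reaction table needs columns {sorted(required)}")
    metabolites = list(metabolites)
    present = set(reactions["metabolite"])
    for m in metabolites:
        if m not in present:
            logger.warning("metabolite %s absent from reaction table", m)
    hits = reactions[
        reactions["metabolite"].isin(metabolites)
        & (reactions["confidence_score"] > min_score)
    ]
    unmapped = hits["gene"].isna() | (hits["gene"].astype(str).str.strip() == "")
    if unmapped.any():
        logger.warning(
            "%d high-scoring protein(s) had no gene mapping and were dropped",
            int(unmapped.sum()),
        )
    genes = {str(g).upper() for g in hits.loc[~unmapped, "gene"]}
    return SignatureSet(
        level="metabolome_derived",
        genes=genes,
        provenance=f"reactions with confidence_score > {min_score}",
    )


def cross_level_overlap(sets: list[SignatureSet]):
    """Membership of every gene across signature levels.

    Returns ``(membership, region_counts, multi_level)``: a boolean
    DataFrame gene x level, counts per exact intersection region (keyed by
    the tuple of member levels, as in a Venn diagram), and the sorted list
    of genes present on more than one level.
    """
    if len(sets) < 2:
        raise ValueError("need >= 2 signature sets")
    levels = [s.level for s in sets]
    if len(set(levels)) != len(levels):
        raise ValueError("signature levels must be distinct")
    union = sorted(set().union(*(s.genes for s in sets)))
    membership = pd.DataFrame(
        {s.level: [g in s.genes for g in union] for s in sets}, index=union
    )
    region_counts: dict[tuple[str, ...], int] = {}
    for _, row in membership.iterrows():
        key = tuple(lv for lv in levels if row[lv])
        region_counts[key] = region_counts.get(key, 0) + 1
    multi_level = sorted(membership.index[membership.sum(axis=1) >= 2])
    return membership, region_counts, multi_level


def protein_level_union(
    proteome: SignatureSet, metabolome_derived: SignatureSet
) -> SignatureSet:
    """Union of proteome and metabolome-derived signatures.

    This is the protein-level source set of the distance model: proteins
    flagged directly by proteomics plus proteins reached from
    disease-associated metabolites.
    """
    if proteome.level != "proteome":
        raise ValueError("first argument must be the proteome set")
    if metabolome_derived.level != "metabolome_derived":
        raise ValueError("second argument must be the metabolome-derived set")
    direction = dict(metabolome_derived.direction)
    direction.update(proteome.direction)
    return SignatureSet(
        level="proteome",
        genes=proteome.genes | metabolome_derived.genes,
        direction=direction,
        provenance="proteome ∪ metabolome_derived",
    )
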