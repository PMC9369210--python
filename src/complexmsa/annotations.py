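"""Metadata tables that drive pairing: gene locations, taxonomy, network links.

The pipeline consumes pre-extracted TSV tables (one accession per line)
rather than raw genome/taxonomy/interaction-network dumps; the mapping
logic, not the download, is what matters here.  A missing annotation is
data, never an error: lookups on absent accessions return ``None`` and the
corresponding hit simply cannot participate in that pairing stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .msa_io import MonomerMSA

logger = logging.getLogger(__name__)


class TableFormatError(ValueError):
    """An annotation table violates the expected format."""


@dataclass(frozen=True)
class GeneLocation:
    """Ordinal position of a gene along a genome/contig.

    ``gene_index`` is a 0-based gene rank, not a base-pair coordinate:
    the gene-distance unit used by neighbourhood pairing is a difference
    of ranks.
    """

    accession: str
    genome_id: str
    gene_index: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.gene_index < 0:
            raise ValueError(f"gene_index must be >= 0, got {self.gene_index}")
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"strand must be '+', '-' or 'unknown', got {self.strand!r}")


@dataclass(frozen=True)
class TaxonAssignment:
    accession: str
    taxid: int
    species_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.taxid <= 0:
            raise ValueError(f"taxid must be positive, got {self.taxid}")


@dataclass(frozen=True)
class InteractionLink:
    """An undirected interaction-network edge with an integrated confidence
    on the 0-1000 scale.  Endpoints are stored in lexicographic order."""

    protein1: str
    protein2: str
    combined_score: int

    def __post_init__(self) -> None:
        if self.protein1 == self.protein2:
            raise ValueError(f"self-link on {self.protein1!r}")
        if not 0 <= self.combined_score <= 1000:
            raise ValueError(f"combined_score out of [0,1000]: {self.combined_score}")
        if self.protein1 > self.protein2:
            p1, p2 = self.protein1, self.protein2
            object.__setattr__(self, "protein1", p2)
            object.__setattr__(self, "protein2", p1)

    @staticmethod
    def make(p1: str, p2: str, score: int) -> "InteractionLink":
        a, b = sorted((p1, p2))
        return InteractionLink(a, b, score)


@dataclass
class AnnotationBundle:
    """Aggregated lookup tables keyed by hit accession, plus network links."""

    gene_table: dict[str, GeneLocation] = field(default_factory=dict)
    taxon_table: dict[str, TaxonAssignment] = field(default_factory=dict)
    netid_table: dict[str, str] = field(default_factory=dict)
    links: dict[tuple[str, str], int] = field(default_factory=dict)

    def gene(self, accession: str) -> Optional[GeneLocation]:
        return self.gene_table.get(accession)

    def taxon(self, accession: str) -> Optional[TaxonAssignment]:
        return self.taxon_table.get(accession)

    def netid(self, accession: str) -> Optional[str]:
        return self.netid_table.get(accession)

    def has_link(self, p1: str, p2: str) -> bool:
        return tuple(sorted((p1, p2))) in self.links

    def link_score(self, p1: str, p2: str) -> Optional[int]:
        return self.links.get(tuple(sorted((p1, p2))))

    def add_link(self, p1: str, p2: str, score: int) -> None:
        if p1 == p2:
            logger.warning("dropping self-link on %s", p1)
            return
        key = tuple(sorted((p1, p2)))
        self.links[key] = max(score, self.links.get(key, 0))


def _read_tsv(path: Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: empty table") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")
    return df


def load_gene_locations(path: str | Path) -> dict[str, GeneLocation]:
    """Load the gene-location TSV (accession, genome_id, gene_index, strand).

    Duplicate accessions keep the last occurrence, with a logged warning.
    """
    path = Path(path)
    df = _read_tsv(path, ["accession", "genome_id", "gene_index"])
    table: dict[str, GeneLocation] = {}
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            gene_index = int(row.gene_index)
        except (TypeError, ValueError):
            raise TableFormatError(
                f"{path}: line {lineno}: gene_index {row.gene_index!r} is not an integer"
            ) from None
        strand = getattr(row, "strand", "unknown") or "unknown"
        if row.accession in table:
            logger.warning(
                "%s: duplicate accession %s, keeping last", path, row.accession
            )
        try:
            table[row.accession] = GeneLocation(
                accession=row.accession,
                genome_id=row.genome_id,
                gene_index=gene_index,
                strand=strand,
            )
        except ValueError as exc:
            raise TableFormatError(f"{path}: line {lineno}: {exc}") from None
    return table


def load_taxonomy(path: str | Path) -> dict[str, TaxonAssignment]:
    """Load the taxonomy TSV (accession, taxid[, species_name])."""
    path = Path(path)
    df = _read_tsv(path, ["accession", "taxid"])
    table: dict[str, TaxonAssignment] = {}
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            taxid = int(row.taxid)
        except (TypeError, ValueError):
            raise TableFormatError(
                f"{path}: line {lineno}: taxid {row.taxid!r} is not an integer"
            ) from None
        if row.accession in table:
            logger.warning(
                "%s: duplicate accession %s, keeping last", path, row.accession
            )
        species = getattr(row, "species_name", None) or None
        try:
            table[row.accession] = TaxonAssignment(
                accession=row.accession, taxid=taxid, species_name=species
            )
        except ValueError as exc:
            raise TableFormatError(f"{path}: line {lineno}: {exc}") from None
    return table


def load_network_ids(path: str | Path) -> dict[str, str]:
    """Load the accession -> network-id TSV (accession, string_id)."""
    path = Path(path)
    df = _read_tsv(path, ["accession", "string_id"])
    table: dict[str, str] = {}
    for row in df.itertuples(index=False):
        if row.accession in table:
            logger.warning(
                "%s: duplicate accession %s, keeping last", path, row.accession
            )
        table[row.accession] = row.string_id
    return table


def load_interaction_links(
    path: str | Path, min_score: int = 0
) -> dict[tuple[str, str], int]:
    """Load whitespace-delimited interaction links (protein1 protein2 score).

    A header line is tolerated.  Links below ``min_score`` are dropped;
    symmetric duplicates collapse keeping the maximum score; self-links are
    dropped with a warning.  Links are keyed by lexicographically ordered
    endpoints, so lookups are direction-independent.
    """
    path = Path(path)
    links: dict[tuple[str, str], int] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise TableFormatError(
                    f"{path}: line {lineno}: expected 3 fields, got {len(parts)}"
                )
            p1, p2, raw_score = parts
            try:
                score = int(raw_score)
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise TableFormatError(
                    f"{path}: line {lineno}: combined_score {raw_score!r} "
                    "is not an integer"
                ) from None
            if not 0 <= score <= 1000:
                raise TableFormatError(
                    f"{path}: line {lineno}: combined_score {score} out of [0,1000]"
                )
            if p1 == p2:
                logger.warning("%s: line %d: dropping self-link on %s", path, lineno, p1)
                continue
            if score < min_score:
                continue
            key = tuple(sorted((p1, p2)))
            links[key] = max(score, links.get(key, 0))
    return links


def load_bundle(
    gene_path: Optional[str | Path] = None,
    taxonomy_path: Optional[str | Path] = None,
    netid_path: Optional[str | Path] = None,
    links_path: Optional[str | Path] = None,
    min_score: int = 0,
) -> AnnotationBundle:
    """Assemble an :class:`AnnotationBundle` from whichever tables exist."""
    return AnnotationBundle(
        gene_table=load_gene_locations(gene_path) if gene_path else {},
        taxon_table=load_taxonomy(taxonomy_path) if taxonomy_path else {},
        netid_table=load_network_ids(netid_path) if netid_path else {},
        links=load_interaction_links(links_path, min_score) if links_path else {},
    )


@dataclass
class AnnotatedMSA:
    """A monomer MSA with per-row annotation lookups resolved.

    Absent annotations are ``None``; the row is then invisible to the
    corresponding pairing stage.
    """

    msa: MonomerMSA
    gene: dict[str, GeneLocation]
    taxon: dict[str, TaxonAssignment]
    netid: dict[str, str]

    @property
    def L(self) -> int:
        return self.msa.L

    @property
    def hits(self):
        return self.msa.hits


def annotate(msa: MonomerMSA, bundle: AnnotationBundle) -> AnnotatedMSA:
    """Tag every hit row with its gene location, taxon and network id.

    Counts of rows left unannotated per source are logged; nothing fails.
    """
    gene = {}
    taxon = {}
    netid = {}
    for row in msa.hits:
        loc = bundle.gene(row.accession)
        if loc is not None:
            gene[row.accession] = loc
        tax = bundle.taxon(row.accession)
        if tax is not None:
            taxon[row.accession] = tax
        nid = bundle.netid(row.accession)
        if nid is not None:
            netid[row.accession] = nid
    n = len(msa.hits)
    logger.info(
        "chain %s: %d hits; unannotated gene=%d taxon=%d netid=%d",
        msa.chain_label, n, n - len(gene), n - len(taxon), n - len(netid),
    )
    return AnnotatedMSA(msa=msa, gene=gene, taxon=taxon, netid=netid)
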