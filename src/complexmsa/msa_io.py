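"""Reading, normalising and writing monomer and complex alignments.

Monomer alignments arrive in A3M or aligned FASTA (HH-suite dialect:
lowercase letters are insertions relative to the query's match states,
``-`` is a deletion).  Normalisation strips insertion columns so that every
row has exactly the query's match-column length; pairwise identity between
aligned rows is computed here and reused by the pairing stages and the
effective-sequence statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Optional

from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover - type-only import, avoids a cycle
    from .pairing import ComplexMSA

logger = logging.getLogger(__name__)

GAP = "-"
WILDCARD = "X"


class MSAFormatError(ValueError):
    """An alignment file violates the expected format."""


@dataclass
class AlignedSequence:
    """One row of a monomer MSA over the query's match columns.

    ``matched`` holds only uppercase residues and ``-``; its length equals
    the query length.  ``identity_to_query`` is a fraction in [0, 1].
    """

    accession: str
    matched: str
    identity_to_query: float = 1.0
    evalue: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_to_query <= 1.0:
            raise ValueError(
                f"identity_to_query must be in [0,1], got {self.identity_to_query!r}"
            )
        if self.evalue is not None and self.evalue < 0:
            raise ValueError(f"evalue must be non-negative, got {self.evalue!r}")
        bad = set(self.matched) - set("ABCDEFGHIJKLMNOPQRSTUVWXYZ-")
        if bad:
            raise MSAFormatError(
                f"row {self.accession!r} contains invalid characters {sorted(bad)!r}"
            )


@dataclass
class MonomerMSA:
    """A single chain's alignment: the query plus its hits.

    ``rows[0]`` is the query; all rows share the query's match-column
    length ``L``.
    """

    chain_label: str
    query: AlignedSequence
    rows: list[AlignedSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if GAP in self.query.matched:
            raise MSAFormatError(
                f"query {self.query.accession!r} must be gapless over match columns"
            )
        if not self.rows or self.rows[0] is not self.query:
            self.rows = [self.query] + [r for r in self.rows if r is not self.query]
        L = len(self.query.matched)
        for row in self.rows:
            if len(row.matched) != L:
                raise MSAFormatError(
                    f"row {row.accession!r} has length {len(row.matched)}, "
                    f"expected query length {L}"
                )

    @property
    def L(self) -> int:
        return len(self.query.matched)

    @property
    def hits(self) -> list[AlignedSequence]:
        """All rows except the query."""
        return self.rows[1:]

    def __len__(self) -> int:
        return len(self.rows)


def normalize_a3m_row(raw: str) -> str:
    """Project an A3M row onto match columns.

    Lowercase letters are insertions and are deleted; ``.`` (an explicit
    insert-state gap) is removed as well.  Idempotent on normalised rows.
    """
    return "".join(c for c in raw if not c.islower() and c != ".").upper()


def pairwise_identity(x: str, y: str, mode: str = "both_ungapped") -> float:
    """Fraction of identical residues between two equal-length aligned strings.

    ``both_ungapped`` divides by the number of columns where both rows carry
    a residue (0 if there is no such column); ``full_length`` divides by the
    alignment length.  ``X`` never matches anything; a column gapped in both
    rows contributes to neither count.
    """
    if len(x) != len(y):
        raise ValueError(f"aligned strings differ in length: {len(x)} vs {len(y)}")
    if mode not in ("both_ungapped", "full_length"):
        raise ValueError(f"unknown identity mode {mode!r}")
    if not x:
        return 0.0
    matches = 0
    both = 0
    for a, b in zip(x, y):
        if a != GAP and b != GAP:
            both += 1
            if a == b and a != WILDCARD:
                matches += 1
    if mode == "full_length":
        return matches / len(x)
    return matches / both if both else 0.0


def read_a3m(path: str | Path, chain_label: str = "A") -> MonomerMSA:
    """Read an A3M / aligned-FASTA file; the first record is the query.

    Rows are normalised to match columns and ``identity_to_query`` is
    computed for every row.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise MSAFormatError(f"{path}: empty alignment file")
    query = AlignedSequence(
        accession=records[0].id,
        matched=normalize_a3m_row(str(records[0].seq)),
        identity_to_query=1.0,
    )
    L = len(query.matched)
    rows = [query]
    for rec in records[1:]:
        matched = normalize_a3m_row(str(rec.seq))
        if len(matched) != L:
            raise MSAFormatError(
                f"{path}: row {rec.id!r} normalises to length {len(matched)}, "
                f"expected {L}"
            )
        rows.append(
            AlignedSequence(
                accession=rec.id,
                matched=matched,
                identity_to_query=pairwise_identity(matched, query.matched),
            )
        )
    return MonomerMSA(chain_label=chain_label, query=query, rows=rows)


def write_complex_alignment(
    cpx: "ComplexMSA", path: str | Path, format: str = "a3m"
) -> None:
    """Write a complex alignment as ``a3m`` (headers ``accA|accB|stage``)
    or ``aln`` (one concatenated sequence per line, no headers).

    The query pair is the first row in either format.
    """
    if format not in ("a3m", "aln"):
        raise ValueError(f"unknown format {format!r}")
    if not cpx.rows:
        raise ValueError("cannot write an empty complex alignment")
    L = cpx.L
    for row in cpx.rows:
        if len(row.concatenated) != L:
            raise ValueError(
                f"row ({row.accession_A},{row.accession_B}) has length "
                f"{len(row.concatenated)}, expected {L}"
            )
    path = Path(path)
    with path.open("w") as fh:
        for row in cpx.rows:
            if format == "a3m":
                fh.write(f">{row.accession_A}|{row.accession_B}|{row.stage}\n")
            fh.write(row.concatenated + "\n")


def read_complex_a3m(path: str | Path, L_A: int) -> "ComplexMSA":
    """Read a complex alignment written by :func:`write_complex_alignment`.

    ``L_A`` declares where to split each concatenated row back into chains.
    """
    from .pairing import ComplexMSA, PairedRow

    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise MSAFormatError(f"{path}: empty complex alignment")
    rows = []
    for rec in records:
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise MSAFormatError(
                f"{path}: header {rec.id!r} is not 'accA|accB|stage'"
            )
        acc_a, acc_b, stage = parts
        seq = str(rec.seq)
        if len(seq) <= L_A:
            raise MSAFormatError(
                f"{path}: row {rec.id!r} shorter than declared L_A={L_A}"
            )
        rows.append(
            PairedRow(
                accession_A=acc_a,
                accession_B=acc_b,
                seq_A=seq[:L_A],
                seq_B=seq[L_A:],
                stage=stage,
                detail={},
            )
        )
    return ComplexMSA(query_pair=rows[0], rows=rows)


def read_complex_aln(path: str | Path, L_A: int) -> "ComplexMSA":
    """Read an ``aln`` complex alignment (one concatenated row per line).

    Rows carry no accessions; synthetic ones (``row0`` ...) are assigned so
    downstream statistics can run.
    """
    from .pairing import ComplexMSA, PairedRow

    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise MSAFormatError(f"{path}: empty aln file")
    rows = []
    for i, line in enumerate(lines):
        if len(line) <= L_A:
            raise MSAFormatError(
                f"{path}: line {i + 1} shorter than declared L_A={L_A}"
            )
        rows.append(
            PairedRow(
                accession_A=f"row{i}_A",
                accession_B=f"row{i}_B",
                seq_A=line[:L_A],
                seq_B=line[L_A:],
                stage="query" if i == 0 else "unknown",
                detail={},
            )
        )
    return ComplexMSA(query_pair=rows[0], rows=rows)
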