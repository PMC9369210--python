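"""Stage selection: escalate pairing strategies until the alignment is deep
enough, then strip redundant rows.

The three strategies are tried in order of pairing confidence: genomic
neighbourhood first, then per-species rank matching, then network links.
After each step the effective-sequence statistic of the merged alignment is
computed; as soon as it reaches the configured requirement the cascade
stops.  The stage-3 merge is returned even when still below the
requirement — there is no further fallback.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

from .annotations import AnnotatedMSA, AnnotationBundle, annotate
from .effective_sequences import compute_necs
from .msa_io import MonomerMSA, pairwise_identity
from .pairing import ComplexMSA, PairedRow, pair_genomic, pair_phylogeny, pair_string

logger = logging.getLogger(__name__)

STAGE_NAMES = {1: "genomic", 2: "phylogeny", 3: "string"}


@dataclass
class CascadeReport:
    """What the cascade did: stages kept, depth reached at each step,
    per-stage row counts, and how many duplicate rows the merges removed."""

    chosen_stages: tuple[int, ...]
    necs_per_step: list[tuple[tuple[int, ...], float]]
    rows_per_stage: dict[str, Optional[int]]
    duplicates_removed: int
    necs_threshold: float
    scaling: str
    query_only: bool = False

    def to_dict(self) -> dict:
        return {
            "chosen_stages": list(self.chosen_stages),
            "necs_per_step": [
                {"stages": list(st), "necs": v} for st, v in self.necs_per_step
            ],
            "rows_per_stage": self.rows_per_stage,
            "duplicates_removed": self.duplicates_removed,
            "necs_threshold": self.necs_threshold,
            "scaling": self.scaling,
            "query_only": self.query_only,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def merge_and_dedupe(
    stage_outputs: list[list[PairedRow]], query_pair: PairedRow
) -> ComplexMSA:
    """Concatenate stage outputs behind the query pair, removing duplicates.

    A row is a duplicate if its concatenated sequence OR its accession pair
    was already seen; the earliest stage's copy is kept and within a stage
    the original order is preserved.  Idempotent.
    """
    la, lb = len(query_pair.seq_A), len(query_pair.seq_B)
    seen_seq = {query_pair.concatenated}
    seen_acc = {(query_pair.accession_A, query_pair.accession_B)}
    rows = [query_pair]
    for stage_rows in stage_outputs:
        for row in stage_rows:
            if len(row.seq_A) != la or len(row.seq_B) != lb:
                raise ValueError(
                    f"row ({row.accession_A},{row.accession_B}) has chain lengths "
                    f"({len(row.seq_A)},{len(row.seq_B)}), expected ({la},{lb})"
                )
            acc = (row.accession_A, row.accession_B)
            if row.concatenated in seen_seq or acc in seen_acc:
                continue
            seen_seq.add(row.concatenated)
            seen_acc.add(acc)
            rows.append(row)
    return ComplexMSA(query_pair=query_pair, rows=rows)


def select_cpxmsa(
    msaA: MonomerMSA | AnnotatedMSA,
    msaB: MonomerMSA | AnnotatedMSA,
    bundle: AnnotationBundle,
    necs_threshold: float = 128.0,
    min_d: int = 1,
    max_d: int = 20,
    string_min_score: int = 0,
    identity_threshold: float = 0.8,
    scaling: str = "inv_sqrt_L",
    identity_mode: str = "both_ungapped",
    count_mode: str = "necs",
) -> tuple[ComplexMSA, CascadeReport]:
    """Build the complex alignment, escalating stages until deep enough.

    ``count_mode="necs"`` (default) judges depth by the effective-sequence
    statistic; ``"rows"`` uses the raw row count instead.
    """
    if not isinstance(msaA, AnnotatedMSA):
        msaA = annotate(msaA, bundle)
    if not isinstance(msaB, AnnotatedMSA):
        msaB = annotate(msaB, bundle)
    if count_mode not in ("necs", "rows"):
        raise ValueError(f"unknown count_mode {count_mode!r}")

    query_pair = PairedRow(
        accession_A=msaA.msa.query.accession,
        accession_B=msaB.msa.query.accession,
        seq_A=msaA.msa.query.matched,
        seq_B=msaB.msa.query.matched,
        stage="query",
    )

    def depth(cpx: ComplexMSA) -> float:
        if count_mode == "rows":
            return float(len(cpx))
        return compute_necs(
            cpx, threshold=identity_threshold, scaling=scaling,
            identity_mode=identity_mode,
        ).necs

    stage_outputs: list[list[PairedRow]] = []
    rows_per_stage: dict[str, Optional[int]] = {
        "genomic": None, "phylogeny": None, "string": None,
    }
    necs_per_step: list[tuple[tuple[int, ...], float]] = []

    builders = {
        1: lambda: pair_genomic(msaA, msaB, min_d=min_d, max_d=max_d),
        2: lambda: pair_phylogeny(msaA, msaB),
        3: lambda: pair_string(msaA, msaB, bundle.links, min_score=string_min_score),
    }

    cpx = None
    chosen: tuple[int, ...] = ()
    for stage in (1, 2, 3):
        out = builders[stage]()
        rows_per_stage[STAGE_NAMES[stage]] = len(out)
        stage_outputs.append(out)
        cpx = merge_and_dedupe(stage_outputs, query_pair)
        chosen = tuple(range(1, stage + 1))
        d = depth(cpx)
        necs_per_step.append((chosen, d))
        logger.info("stages %s: %d rows, depth %.3f", chosen, len(cpx), d)
        if d >= necs_threshold:
            break

    duplicates_removed = sum(len(o) for o in stage_outputs) + 1 - len(cpx)
    report = CascadeReport(
        chosen_stages=chosen,
        necs_per_step=necs_per_step,
        rows_per_stage=rows_per_stage,
        duplicates_removed=duplicates_removed,
        necs_threshold=necs_threshold,
        scaling=scaling,
        query_only=len(cpx) == 1,
    )
    if report.query_only:
        logger.warning("all pairing stages empty: query-only alignment")
    return cpx, report


def remove_redundant(cpx: ComplexMSA, max_id: float = 1.0) -> ComplexMSA:
    """Drop redundant rows; the query pair is never dropped.

    With ``max_id = 1.0`` only byte-identical concatenated duplicates go.
    With ``max_id < 1`` a row is also dropped when the harmonic mean of its
    per-chain identities to any kept earlier row reaches ``max_id``.
    Idempotent: its output is a fixed point.
    """
    if not 0.0 < max_id <= 1.0:
        raise ValueError(f"max_id must be in (0,1], got {max_id}")
    kept: list[PairedRow] = [cpx.query_pair]
    seen = {cpx.query_pair.concatenated}
    for row in cpx.rows[1:]:
        if row.concatenated in seen:
            continue
        if max_id < 1.0:
            from .effective_sequences import harmonic_pair_identity

            redundant = False
            for prev in kept:
                sa = pairwise_identity(row.seq_A, prev.seq_A)
                sb = pairwise_identity(row.seq_B, prev.seq_B)
                if harmonic_pair_identity(sa, sb) >= max_id:
                    redundant = True
                    break
            if redundant:
                continue
        seen.add(row.concatenated)
        kept.append(row)
    return ComplexMSA(query_pair=cpx.query_pair, rows=kept)
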