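"""The three pairing strategies that join rows of two monomer MSAs.

Each strategy proposes candidate (chain A hit, chain B hit) pairs from a
different evidence source — gene-neighbourhood distance on a shared genome,
per-species similarity rank, or an interaction-network link — and resolves
conflicts into a deterministic one-to-one matching.  The matching is greedy
over a total candidate ordering (primary stage criterion, then descending
mean identity to the queries, then lexicographic accessions), so identical
inputs always give identical output regardless of row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Optional

from .annotations import AnnotatedMSA
from .msa_io import AlignedSequence

logger = logging.getLogger(__name__)

STAGES = ("query", "genomic", "phylogeny", "string", "unknown")


@dataclass
class PairedRow:
    """One row of a complex alignment: two concatenated chain segments with
    provenance (which stage produced the pair, and why)."""

    accession_A: str
    accession_B: str
    seq_A: str
    seq_B: str
    stage: str
    detail: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def concatenated(self) -> str:
        return self.seq_A + self.seq_B


@dataclass
class ComplexMSA:
    """A paired (complex) alignment: the query pair first, then hit pairs.

    No two rows share the same (accession_A, accession_B); every row's
    concatenated length is L_A + L_B.
    """

    query_pair: PairedRow
    rows: list[PairedRow]

    def __post_init__(self) -> None:
        if not self.rows or self.rows[0] is not self.query_pair:
            self.rows = [self.query_pair] + [
                r for r in self.rows if r is not self.query_pair
            ]
        la, lb = self.L_A, self.L_B
        seen: set[tuple[str, str]] = set()
        for row in self.rows:
            if len(row.seq_A) != la or len(row.seq_B) != lb:
                raise ValueError(
                    f"row ({row.accession_A},{row.accession_B}) has chain lengths "
                    f"({len(row.seq_A)},{len(row.seq_B)}), expected ({la},{lb})"
                )
            key = (row.accession_A, row.accession_B)
            if key in seen:
                raise ValueError(f"duplicate accession pair {key}")
            seen.add(key)

    @property
    def L_A(self) -> int:
        return len(self.query_pair.seq_A)

    @property
    def L_B(self) -> int:
        return len(self.query_pair.seq_B)

    @property
    def L(self) -> int:
        return self.L_A + self.L_B

    def __len__(self) -> int:
        return len(self.rows)


def _greedy_one_to_one(candidates: list[tuple[tuple, AlignedSequence, AlignedSequence]]):
    """Greedy matching over a totally ordered candidate list.

    ``candidates`` holds (sort_key, rowA, rowB); keys must be unique
    (they end in the accession pair).  Picks candidates in key order,
    skipping any whose A or B accession is already used.
    """
    chosen = []
    used_a: set[str] = set()
    used_b: set[str] = set()
    for key, ra, rb in sorted(candidates, key=lambda c: c[0]):
        if ra.accession in used_a or rb.accession in used_b:
            continue
        used_a.add(ra.accession)
        used_b.add(rb.accession)
        chosen.append((key, ra, rb))
    return chosen


def pair_genomic(
    msaA: AnnotatedMSA,
    msaB: AnnotatedMSA,
    min_d: int = 1,
    max_d: int = 20,
    method: str = "greedy",
) -> list[PairedRow]:
    """Pair hits that sit close together on the same genome.

    A candidate is an (A hit, B hit) pair annotated to the same genome with
    gene-rank distance Δgene in [min_d, max_d]; the default window 1..20
    targets operon-scale neighbourhoods.  Candidates are resolved one-to-one
    greedily by ascending Δgene (ties: descending mean identity to query,
    then lexicographic accessions).  ``method="optimal"`` instead solves the
    minimum-total-Δgene assignment exactly.
    """
    candidates = []
    for ra in msaA.hits:
        loc_a = msaA.gene.get(ra.accession)
        if loc_a is None:
            continue
        for rb in msaB.hits:
            loc_b = msaB.gene.get(rb.accession)
            if loc_b is None or loc_b.genome_id != loc_a.genome_id:
                continue
            d = abs(loc_a.gene_index - loc_b.gene_index)
            if min_d <= d <= max_d:
                key = (
                    d,
                    -(ra.identity_to_query + rb.identity_to_query) / 2.0,
                    ra.accession,
                    rb.accession,
                )
                candidates.append((key, ra, rb))
    if method == "greedy":
        chosen = _greedy_one_to_one(candidates)
    elif method == "optimal":
        chosen = _optimal_assignment(candidates)
    else:
        raise ValueError(f"unknown matching method {method!r}")
    return [
        PairedRow(
            accession_A=ra.accession,
            accession_B=rb.accession,
            seq_A=ra.matched,
            seq_B=rb.matched,
            stage="genomic",
            detail={"dgene": key[0]},
        )
        for key, ra, rb in chosen
    ]


def pair_phylogeny(msaA: AnnotatedMSA, msaB: AnnotatedMSA) -> list[PairedRow]:
    """Pair hits by per-species similarity rank.

    Within each taxid present in both MSAs, hits are sorted by identity to
    the query (descending; ties by ascending e-value when present, then
    accession) and the i-th ranked A hit is paired with the i-th ranked
    B hit, for i up to the smaller count.
    """

    def by_taxid(msa: AnnotatedMSA) -> dict[int, list[AlignedSequence]]:
        groups: dict[int, list[AlignedSequence]] = {}
        for row in msa.hits:
            tax = msa.taxon.get(row.accession)
            if tax is not None:
                groups.setdefault(tax.taxid, []).append(row)
        return groups

    def rank_key(row: AlignedSequence):
        ev = row.evalue if row.evalue is not None else float("inf")
        return (-row.identity_to_query, ev, row.accession)

    groups_a = by_taxid(msaA)
    groups_b = by_taxid(msaB)
    pairs: list[PairedRow] = []
    for taxid in sorted(set(groups_a) & set(groups_b)):
        ranked_a = sorted(groups_a[taxid], key=rank_key)
        ranked_b = sorted(groups_b[taxid], key=rank_key)
        for rank, (ra, rb) in enumerate(zip(ranked_a, ranked_b), start=1):
            pairs.append(
                PairedRow(
                    accession_A=ra.accession,
                    accession_B=rb.accession,
                    seq_A=ra.matched,
                    seq_B=rb.matched,
                    stage="phylogeny",
                    detail={"taxid": taxid, "rank": rank},
                )
            )
    return pairs


def pair_string(
    msaA: AnnotatedMSA,
    msaB: AnnotatedMSA,
    links: dict[tuple[str, str], int],
    min_score: int = 0,
    method: str = "greedy",
) -> list[PairedRow]:
    """Pair hits whose network ids share an interaction link.

    Candidates are (A hit, B hit) pairs whose network ids have a link with
    combined score >= ``min_score``, resolved one-to-one greedily by
    descending combined score (ties: descending mean identity, then
    lexicographic accessions).
    """
    candidates = []
    for ra in msaA.hits:
        nid_a = msaA.netid.get(ra.accession)
        if nid_a is None:
            continue
        for rb in msaB.hits:
            nid_b = msaB.netid.get(rb.accession)
            if nid_b is None:
                continue
            score = links.get(tuple(sorted((nid_a, nid_b))))
            if score is None or score < min_score:
                continue
            key = (
                -score,
                -(ra.identity_to_query + rb.identity_to_query) / 2.0,
                ra.accession,
                rb.accession,
            )
            candidates.append((key, ra, rb))
    if method == "greedy":
        chosen = _greedy_one_to_one(candidates)
    elif method == "optimal":
        chosen = _optimal_assignment(candidates)
    else:
        raise ValueError(f"unknown matching method {method!r}")
    return [
        PairedRow(
            accession_A=ra.accession,
            accession_B=rb.accession,
            seq_A=ra.matched,
            seq_B=rb.matched,
            stage="string",
            detail={"combined_score": -key[0]},
        )
        for key, ra, rb in chosen
    ]


def _optimal_assignment(candidates):
    """Exact assignment minimising the summed primary key over a
    maximum-cardinality matching (alternative to the default greedy rule)."""
    import numpy as np
    from scipy.optimize import linear_sum_assignment

    if not candidates:
        return []
    accs_a = sorted({ra.accession for _, ra, _ in candidates})
    accs_b = sorted({rb.accession for _, _, rb in candidates})
    ia = {a: i for i, a in enumerate(accs_a)}
    ib = {b: i for i, b in enumerate(accs_b)}
    # large-but-finite cost for non-candidates keeps the assignment feasible
    # while never preferring a forbidden pair over any real candidate
    span = max(abs(float(k[0])) for k, _, _ in candidates) + 1.0
    big = span * (len(accs_a) + len(accs_b) + 1)
    cost = np.full((len(accs_a), len(accs_b)), big)
    by_cell = {}
    for key, ra, rb in candidates:
        i, j = ia[ra.accession], ib[rb.accession]
        if float(key[0]) < cost[i, j]:
            cost[i, j] = float(key[0])
            by_cell[(i, j)] = (key, ra, rb)
    rows, cols = linear_sum_assignment(cost)
    chosen = [
        by_cell[(i, j)] for i, j in zip(rows, cols) if (i, j) in by_cell
    ]
    return sorted(chosen, key=lambda c: c[0])
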