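"""Synthetic homolog families with planted ground-truth pairings.

Generates a pair of monomer MSAs plus the full annotation bundle (gene
locations, taxonomy, network ids and links) such that every planted pair is
recoverable by each of the three pairing strategies: the two partners sit
on one genome within the gene-distance window, share a taxid, and carry an
interaction link.  Decoys are placed outside the window and orphans carry
no annotations at all, so negative controls are available too.

Rows are match-state only (no indels), which keeps identity arithmetic
exact; gap handling is exercised by dedicated tests, not by this generator.
All randomness flows through one seeded generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .annotations import AnnotationBundle, GeneLocation, TaxonAssignment
from .msa_io import AlignedSequence, MonomerMSA, pairwise_identity

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# planted-pair geometry: paralog blocks 100 gene ranks apart keep every
# cross-paralog distance far outside the 1..20 pairing window, and decoys
# sit 50 ranks from their block for the same reason
_BLOCK_SPACING = 100
_DECOY_OFFSET = 50
_DGENE_MAX = 20


@dataclass
class FamilyParams:
    """Generation parameters; the defaults are the reference conditions the
    test-bed exercises (10 single-genome species, one interacting pair per
    genome, 20% per-site divergence, no decoys or orphans)."""

    n_species: int = 10
    genomes_per_species: int = 1
    paralogs_per_genome: int = 1
    decoys_per_genome: int = 0
    orphan_fraction: float = 0.0
    substitution_rate: float = 0.2
    L_A: int = 80
    L_B: int = 70
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_species", "genomes_per_species", "paralogs_per_genome",
                     "decoys_per_genome"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("orphan_fraction", "substitution_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.L_A < 1 or self.L_B < 1:
            raise ValueError("chain lengths must be >= 1")


@dataclass
class SyntheticFamily:
    """A generated two-chain family with its annotations and the planted
    truth."""

    msaA: MonomerMSA
    msaB: MonomerMSA
    bundle: AnnotationBundle
    true_pairs: list[tuple[str, str]]
    params: FamilyParams


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each position independently with probability ``rate`` by a
    uniformly chosen different amino acid; length is preserved."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0,1], got {rate}")
    out = list(seq)
    mask = rng.random(len(seq)) < rate
    for i in np.flatnonzero(mask):
        choices = [a for a in AMINO_ACIDS if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def generate_family(params: FamilyParams | None = None, **overrides) -> SyntheticFamily:
    """Generate a two-chain homolog family with planted pairings.

    Per (species, genome, paralog) one interacting A/B pair is created by
    mutating the two query sequences; deeper paralogs diverge faster so the
    within-species similarity ranking is consistent across the two chains.
    Byte-identical output for identical parameters and seed.
    """
    if params is None:
        params = FamilyParams(**overrides)
    elif overrides:
        params = FamilyParams(**{**asdict(params), **overrides})
    params.validate()
    rng = np.random.default_rng(params.seed)

    query_a = AlignedSequence("queryA", random_sequence(params.L_A, rng), 1.0)
    query_b = AlignedSequence("queryB", random_sequence(params.L_B, rng), 1.0)
    rows_a: list[AlignedSequence] = [query_a]
    rows_b: list[AlignedSequence] = [query_b]
    bundle = AnnotationBundle()
    true_pairs: list[tuple[str, str]] = []

    def add_row(rows, query, acc, seq):
        rows.append(
            AlignedSequence(
                accession=acc,
                matched=seq,
                identity_to_query=pairwise_identity(seq, query.matched),
            )
        )

    for s in range(params.n_species):
        taxid = 1000 + s
        for g in range(params.genomes_per_species):
            genome_id = f"genome_s{s}g{g}"
            for p in range(params.paralogs_per_genome):
                # tiered divergence keeps the similarity ranking of paralogs
                # aligned between the two chains with high probability
                rate = min(params.substitution_rate * (1.0 + 0.5 * p), 0.75)
                acc_a = f"A_s{s}g{g}p{p}"
                acc_b = f"B_s{s}g{g}p{p}"
                seq_a = mutate_sequence(query_a.matched, rate, rng)
                seq_b = mutate_sequence(query_b.matched, rate, rng)
                add_row(rows_a, query_a, acc_a, seq_a)
                add_row(rows_b, query_b, acc_b, seq_b)
                base = _BLOCK_SPACING * p
                dgene = int(rng.integers(1, _DGENE_MAX + 1))
                bundle.gene_table[acc_a] = GeneLocation(acc_a, genome_id, base, "+")
                bundle.gene_table[acc_b] = GeneLocation(
                    acc_b, genome_id, base + dgene, "+"
                )
                bundle.taxon_table[acc_a] = TaxonAssignment(acc_a, taxid)
                bundle.taxon_table[acc_b] = TaxonAssignment(acc_b, taxid)
                net_a, net_b = f"net_{acc_a}", f"net_{acc_b}"
                bundle.netid_table[acc_a] = net_a
                bundle.netid_table[acc_b] = net_b
                bundle.add_link(net_a, net_b, 900)
                true_pairs.append((acc_a, acc_b))
            for d in range(params.decoys_per_genome):
                # decoys live on a real genome but outside the pairing
                # window of every planted block, with a private taxid and
                # an unlinked network id
                chain = "A" if d % 2 == 0 else "B"
                acc = f"D{chain}_s{s}g{g}d{d}"
                idx = (
                    _BLOCK_SPACING * (params.paralogs_per_genome - 1)
                    + _DECOY_OFFSET + d * (_DGENE_MAX + 5)
                )
                query, rows = (query_a, rows_a) if chain == "A" else (query_b, rows_b)
                seq = mutate_sequence(query.matched, params.substitution_rate, rng)
                add_row(rows, query, acc, seq)
                bundle.gene_table[acc] = GeneLocation(acc, genome_id, idx, "-")
                bundle.taxon_table[acc] = TaxonAssignment(acc, 900000 + s * 100 + d)
                bundle.netid_table[acc] = f"net_{acc}"

    n_orphans = int(round(params.orphan_fraction * len(true_pairs)))
    for o in range(n_orphans):
        seq_a = mutate_sequence(query_a.matched, params.substitution_rate, rng)
        seq_b = mutate_sequence(query_b.matched, params.substitution_rate, rng)
        add_row(rows_a, query_a, f"OA_{o}", seq_a)
        add_row(rows_b, query_b, f"OB_{o}", seq_b)

    msa_a = MonomerMSA(chain_label="A", query=query_a, rows=rows_a)
    msa_b = MonomerMSA(chain_label="B", query=query_b, rows=rows_b)
    return SyntheticFamily(
        msaA=msa_a, msaB=msa_b, bundle=bundle, true_pairs=true_pairs, params=params
    )


def write_family(family: SyntheticFamily, outdir: str | Path) -> dict[str, Path]:
    """Write the family as the pipeline's on-disk inputs.

    Produces msaA.a3m, msaB.a3m, genes.tsv, taxonomy.tsv, netids.tsv,
    links.txt, true_pairs.tsv and params.json in ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / fname for name, fname in [
        ("msaA", "msaA.a3m"), ("msaB", "msaB.a3m"), ("genes", "genes.tsv"),
        ("taxonomy", "taxonomy.tsv"), ("netids", "netids.tsv"),
        ("links", "links.txt"), ("true_pairs", "true_pairs.tsv"),
        ("params", "params.json"),
    ]}
    for key, msa in (("msaA", family.msaA), ("msaB", family.msaB)):
        with paths[key].open("w") as fh:
            for row in msa.rows:
                fh.write(f">{row.accession}\n{row.matched}\n")
    with paths["genes"].open("w") as fh:
        fh.write("accession\tgenome_id\tgene_index\tstrand\n")
        for loc in family.bundle.gene_table.values():
            fh.write(f"{loc.accession}\t{loc.genome_id}\t{loc.gene_index}\t{loc.strand}\n")
    with paths["taxonomy"].open("w") as fh:
        fh.write("accession\ttaxid\tspecies_name\n")
        for tax in family.bundle.taxon_table.values():
            fh.write(f"{tax.accession}\t{tax.taxid}\t{tax.species_name or ''}\n")
    with paths["netids"].open("w") as fh:
        fh.write("accession\tstring_id\n")
        for acc, nid in family.bundle.netid_table.items():
            fh.write(f"{acc}\t{nid}\n")
    with paths["links"].open("w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for (p1, p2), score in family.bundle.links.items():
            fh.write(f"{p1} {p2} {score}\n")
    with paths["true_pairs"].open("w") as fh:
        fh.write("accession_A\taccession_B\n")
        for a, b in family.true_pairs:
            fh.write(f"{a}\t{b}\n")
    with paths["params"].open("w") as fh:
        json.dump(asdict(family.params), fh, indent=2)
        fh.write("\n")
    return paths
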