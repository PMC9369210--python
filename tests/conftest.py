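import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from complexmsa import (
    AlignedSequence,
    AnnotatedMSA,
    ComplexMSA,
    MonomerMSA,
    PairedRow,
    annotate,
    generate_family,
)

AMINO = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def family():
    """The reference planted family: 10 species, one pair each, 20% divergence."""
    return generate_family(seed=0)


@pytest.fixture(scope="session")
def annotated(family):
    return (
        annotate(family.msaA, family.bundle),
        annotate(family.msaB, family.bundle),
    )


def random_rows(rng, n, l_a, l_b, n_groups=3):
    """Random complex rows drawn from a few mutation clusters so that the
    >= 0.8 identity threshold is actually crossed by some pairs."""
    ancestors = [
        (
            "".join(rng.choice(list(AMINO), size=l_a)),
            "".join(rng.choice(list(AMINO), size=l_b)),
        )
        for _ in range(n_groups)
    ]

    def mutate(seq, rate):
        out = list(seq)
        for i in np.flatnonzero(rng.random(len(seq)) < rate):
            out[i] = AMINO[rng.integers(20)]
        return "".join(out)

    rows = []
    for i in range(n):
        a, b = ancestors[rng.integers(n_groups)]
        rate = float(rng.choice([0.0, 0.05, 0.3]))
        rows.append((mutate(a, rate), mutate(b, rate)))
    return rows


def rows_to_cpx(rows):
    """Wrap raw (seq_A, seq_B) tuples as a ComplexMSA with opaque accessions."""
    paired = [
        PairedRow(
            accession_A=f"a{i}",
            accession_B=f"b{i}",
            seq_A=ra,
            seq_B=rb,
            stage="query" if i == 0 else "genomic",
        )
        for i, (ra, rb) in enumerate(rows)
    ]
    return ComplexMSA(query_pair=paired[0], rows=paired)


def make_annotated(chain, hit_specs, L=12, query_seq=None):
    """Build a tiny AnnotatedMSA from per-hit spec dicts.

    Each spec: {acc, identity (via mutation count), gene:(genome, idx),
    taxid, netid, evalue}.  Sequences are derived from the query with the
    requested number of substitutions so identity_to_query is exact.
    """
    query_seq = query_seq or ("ACDEFGHIKLMN"[:L] * ((L // 12) + 1))[:L]
    query = AlignedSequence(f"query{chain}", query_seq, 1.0)
    rows = [query]
    gene, taxon, netid = {}, {}, {}
    from complexmsa import GeneLocation, TaxonAssignment

    for spec in hit_specs:
        n_mut = spec.get("n_mut", 0)
        seq = list(query_seq)
        for i in range(n_mut):
            seq[i] = "W" if query_seq[i] != "W" else "Y"
        seq = "".join(seq)
        row = AlignedSequence(
            spec["acc"], seq, 1.0 - n_mut / L, evalue=spec.get("evalue")
        )
        rows.append(row)
        if "gene" in spec:
            genome, idx = spec["gene"]
            gene[spec["acc"]] = GeneLocation(spec["acc"], genome, idx)
        if "taxid" in spec:
            taxon[spec["acc"]] = TaxonAssignment(spec["acc"], spec["taxid"])
        if "netid" in spec:
            netid[spec["acc"]] = spec["netid"]
    msa = MonomerMSA(chain_label=chain, query=query, rows=rows)
    return AnnotatedMSA(msa=msa, gene=gene, taxon=taxon, netid=netid)
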