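"""Effective number of sequences of a complex alignment (Necs).

Rows of a paired alignment are down-weighted by how many near-duplicate
neighbours they have: two rows i, j are neighbours when the harmonic mean
of their chain-A and chain-B pairwise identities reaches a threshold
(default 0.8).  Each row's weight is 1/(1 + neighbour count) and the
weights are summed and scaled by the complex length L:

    Necs = scale(L) * sum_i 1 / (1 + sum_{j != i} [S_ij >= t])
    S_ij = 2 / (1/S_ij^A + 1/S_ij^B)

with scale(L) = 1/sqrt(L) by default (the alignment-depth convention of
monomer Nf statistics) or 1/L.  The harmonic mean punishes a pairing in
which only one chain is conserved: both chains must be similar for two
rows to count as redundant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .pairing import ComplexMSA

SCALINGS = ("inv_sqrt_L", "inv_L")


@dataclass
class NecsResult:
    """Effective-sequence statistic with the per-row weights behind it."""

    necs: float
    N: int
    L: int
    threshold: float
    scaling: str
    weights: np.ndarray

    def to_dict(self) -> dict:
        return {
            "necs": self.necs,
            "N": self.N,
            "L": self.L,
            "threshold": self.threshold,
            "scaling": self.scaling,
        }


def harmonic_pair_identity(sA: float, sB: float) -> float:
    """Harmonic mean 2/(1/sA + 1/sB) of two chain identities.

    Defined as 0 when either input is 0 (the continuous limit); symmetric.
    """
    if not (0.0 <= sA <= 1.0) or not (0.0 <= sB <= 1.0):
        raise ValueError(f"chain identities must be in [0,1], got ({sA}, {sB})")
    if sA == 0.0 or sB == 0.0:
        return 0.0
    return 2.0 / (1.0 / sA + 1.0 / sB)


def delta_indicator(s: float, threshold: float = 0.8) -> int:
    """1 iff the pair identity reaches the redundancy threshold."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"pair identity must be in [0,1], got {s}")
    return 1 if s >= threshold else 0


def _scale(L: int, scaling: str) -> float:
    if scaling == "inv_sqrt_L":
        return 1.0 / np.sqrt(L)
    if scaling == "inv_L":
        return 1.0 / L
    raise ValueError(f"unknown scaling {scaling!r}, expected one of {SCALINGS}")


def _encode(seqs: list[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
        len(seqs), -1
    )


def _identity_matrix(seqs: list[str], mode: str) -> np.ndarray:
    """All-vs-all pairwise identity for equal-length aligned strings.

    Vectorised: per-letter indicator matrices give the match counts via
    one matrix product per residue letter.
    """
    arr = _encode(seqs)
    n, L = arr.shape
    nongap = arr != ord("-")
    residue = nongap & (arr != ord("X"))
    matches = np.zeros((n, n))
    for letter in np.unique(arr[residue]) if residue.any() else []:
        ind = ((arr == letter) & residue).astype(np.float64)
        matches += ind @ ind.T
    if mode == "full_length":
        denom = np.full((n, n), float(L))
    elif mode == "both_ungapped":
        denom = nongap.astype(np.float64) @ nongap.astype(np.float64).T
    else:
        raise ValueError(f"unknown identity mode {mode!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        ident = np.where(denom > 0, matches / np.maximum(denom, 1e-300), 0.0)
    return ident


def pair_identity_matrix(
    cpx: "ComplexMSA", identity_mode: str = "both_ungapped"
) -> np.ndarray:
    """All-vs-all harmonic pair identity S_ij over the rows of a complex MSA."""
    sa = _identity_matrix([r.seq_A for r in cpx.rows], identity_mode)
    sb = _identity_matrix([r.seq_B for r in cpx.rows], identity_mode)
    with np.errstate(divide="ignore"):
        s = np.where((sa > 0) & (sb > 0), 2.0 / (1.0 / np.maximum(sa, 1e-300)
                                                 + 1.0 / np.maximum(sb, 1e-300)), 0.0)
    return s


def compute_necs(
    cpx: "ComplexMSA",
    threshold: float = 0.8,
    scaling: str = "inv_sqrt_L",
    identity_mode: str = "both_ungapped",
    include_query: bool = True,
) -> NecsResult:
    """Effective number of sequences of a complex alignment.

    All rows, including the query pair, count toward N by default;
    ``include_query=False`` drops the first row before weighting.
    """
    rows = cpx.rows if include_query else cpx.rows[1:]
    if not rows:
        raise ValueError("cannot compute Necs of an empty alignment")
    L = cpx.L
    sub = type(cpx)(query_pair=rows[0], rows=list(rows)) if not include_query else cpx
    s = pair_identity_matrix(sub, identity_mode)
    n = len(rows)
    close = s >= threshold
    np.fill_diagonal(close, False)
    neighbours = close.sum(axis=1)
    weights = 1.0 / (1.0 + neighbours)
    necs = float(_scale(L, scaling) * weights.sum())
    return NecsResult(
        necs=necs, N=n, L=L, threshold=threshold, scaling=scaling, weights=weights
    )
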