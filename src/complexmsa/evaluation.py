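"""Top-k inter-chain contact precision and relative-improvement arithmetic.

A contact predictor scores every inter-chain residue pair (i on chain A,
j on chain B); precision at k is the fraction of true contacts among the
k highest-scoring cells.  k may be given directly or as ``L/k`` where L is
the summed length of the two chains.  What counts as a true contact
(distance cutoff, atom choice) is the caller's business: the truth map is
an input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class ContactEval:
    """Predicted inter-chain score matrix (L_A x L_B) and the matching
    boolean truth map."""

    scores: np.ndarray
    truth: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.truth = np.asarray(self.truth, dtype=bool)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2-D matrix")
        if self.scores.shape != self.truth.shape:
            raise ValueError(
                f"shape mismatch: scores {self.scores.shape} vs truth {self.truth.shape}"
            )

    @property
    def L(self) -> int:
        """Total length of the two chains."""
        return self.scores.shape[0] + self.scores.shape[1]


def resolve_k(ev: ContactEval, k_spec: int | str) -> int:
    """Turn a k specification into a concrete count.

    ``k_spec`` is either a positive integer or a string ``"L/k"`` (e.g.
    ``"L/5"``); L/k uses floor division and is floored at 1.
    """
    if isinstance(k_spec, str):
        spec = k_spec.strip().upper().replace(" ", "")
        if not spec.startswith("L/"):
            raise ValueError(f"k spec {k_spec!r} is neither an integer nor 'L/k'")
        divisor = int(spec[2:])
        if divisor <= 0:
            raise ValueError(f"L/k divisor must be positive, got {divisor}")
        k = max(ev.L // divisor, 1)
    else:
        k = int(k_spec)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > ev.scores.size:
        raise ValueError(
            f"k={k} exceeds the {ev.scores.size} scored inter-chain cells"
        )
    return k


def topk_precision(ev: ContactEval, k_spec: int | str) -> float:
    """Fraction of true contacts among the k highest-scoring cells.

    Score ties are broken by ascending (i, j) so the ranking is total.
    """
    k = resolve_k(ev, k_spec)
    flat_scores = ev.scores.ravel()
    n = flat_scores.size
    ii, jj = np.unravel_index(np.arange(n), ev.scores.shape)
    order = np.lexsort((jj, ii, -flat_scores))
    top = order[:k]
    return float(ev.truth.ravel()[top].sum()) / k


def relative_improvement(a: float, b: float) -> float:
    """Percent improvement of a over baseline b: 100*(a-b)/b.

    Reported figures round this to one decimal.
    """
    if b <= 0:
        raise ValueError(f"baseline must be positive, got {b}")
    return 100.0 * (a - b) / b


def load_matrix(path: str | Path, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Load a score/truth matrix from text.

    Dense: a whitespace-delimited numeric matrix.  Sparse: three columns
    (i, j, value) with 0-based indices, requiring ``shape``; unlisted cells
    are 0.
    """
    path = Path(path)
    data = np.loadtxt(path, ndmin=2)
    if shape is not None:
        if data.shape[1] != 3:
            raise ValueError(
                f"{path}: sparse input must have 3 columns (i, j, value)"
            )
        out = np.zeros(shape)
        ii = data[:, 0].astype(int)
        jj = data[:, 1].astype(int)
        if (ii < 0).any() or (ii >= shape[0]).any() or (jj < 0).any() or (jj >= shape[1]).any():
            raise ValueError(f"{path}: sparse indices out of bounds for shape {shape}")
        out[ii, jj] = data[:, 2]
        return out
    return data
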