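"""Independent test oracles: brute-force implementations kept deliberately
separate from the library code paths they check."""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def enumerate_alignment_score(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Optimal global affine-gap score by exhaustive enumeration.

    Recursively enumerates every monotone alignment path (no memoization, no
    DP) and scores it with BLOSUM62 and gap runs costing
    ``open + (len - 1) * extend``.  Only practical for short sequences.
    """
    best = [-np.inf]

    def walk(i: int, j: int, score: float, last: str) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, score + _BLOSUM62[a[i], b[j]], "m")
        if i < len(a):
            cost = gap_extend if last == "x" else gap_open
            walk(i + 1, j, score - cost, "x")
        if j < len(b):
            cost = gap_extend if last == "y" else gap_open
            walk(i, j + 1, score - cost, "y")

    walk(0, 0, 0.0, "m")
    return float(best[0])


def brute_force_mask(rows: list[str], max_gap_fraction: float) -> list[str]:
    """Column-by-column recount of the gap-masking rule."""
    if not rows:
        return []
    ncol = len(rows[0])
    nrow = len(rows)
    keep = []
    for c in range(ncol):
        gaps = sum(1 for r in rows if r[c] == "-")
        if gaps / nrow <= max_gap_fraction:
            keep.append(c)
    return ["".join(r[c] for c in keep) for r in rows]


def random_msa(rng: np.random.Generator, nrow: int, ncol: int, gap_p: float = 0.3) -> list[str]:
    """A random gapped block (not a real alignment; exercises masking only)."""
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY-"))
    probs = np.full(21, (1.0 - gap_p) / 20.0)
    probs[-1] = gap_p
    return ["".join(rng.choice(alphabet, size=ncol, p=probs)) for _ in range(nrow)]
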