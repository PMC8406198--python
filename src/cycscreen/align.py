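"""Pairwise and progressive multiple alignment, masking, AAI and logos.

The pairwise aligner is affine-gap global Needleman-Wunsch over BLOSUM62
(delegated to Biopython's PairwiseAligner); the multiple aligner is a small
progressive aligner: UPGMA guide tree from k-mer distances, then
profile-profile merging with the same scoring scheme.  Alignment columns
with more than a configurable gap fraction (30% by default) can be masked
out, matching the tree-building convention for this protein family.

Amino-acid identity (AAI) is computed on fresh pairwise alignments by
default, before any masking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from ._dp import affine_align_matrix
from .screen import ProteinRecord, STANDARD_AA

__all__ = [
    "AlignParams",
    "PairwiseAlignment",
    "MSA",
    "MaskConfig",
    "LogoTable",
    "global_align",
    "percent_identity",
    "build_msa",
    "mask_msa",
    "aai_matrix",
    "consensus_logo",
    "read_msa_fasta",
    "write_msa_fasta",
]


@dataclass(frozen=True)
class AlignParams:
    """Scoring scheme; a gap of length L costs ``gap_open + (L-1)*gap_extend``."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")
        if any(a == "-" and b == "-" for a, b in zip(self.aligned_a, self.aligned_b)):
            raise ValueError("gap-gap columns are not allowed in a pairwise alignment")


@dataclass
class MSA:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("all rows must have equal length")

    @property
    def ncol(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def nrow(self) -> int:
        return len(self.rows)

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


@dataclass(frozen=True)
class MaskConfig:
    max_gap_fraction: float = 0.30

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_gap_fraction <= 1.0):
            raise ValueError("max_gap_fraction must be in [0, 1]")


@dataclass
class LogoTable:
    """Per-column residue frequencies, information content and consensus."""

    frequencies: pd.DataFrame  # ncol x 20, rows sum to 1 (or 0 for all-gap)
    information: np.ndarray  # bits, in [0, log2 20]
    consensus: list[str]  # per-column symbol, possibly "[A/B]", "X" or "-"

    @property
    def consensus_string(self) -> str:
        return "".join(self.consensus)


_ALIGNER_CACHE: dict[AlignParams, Align.PairwiseAligner] = {}


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    if params not in _ALIGNER_CACHE:
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load(params.matrix)
        aligner.mode = "global"
        aligner.open_gap_score = -params.gap_open
        aligner.extend_gap_score = -params.gap_extend
        _ALIGNER_CACHE[params] = aligner
    return _ALIGNER_CACHE[params]


def _for_matrix(seq: str, alphabet: str) -> str:
    """Map letters absent from the matrix onto its wildcard, if it has one."""
    out = []
    for ch in seq:
        if ch in alphabet:
            out.append(ch)
        elif "X" in alphabet:
            out.append("X")
        else:
            raise ValueError(f"residue {ch!r} not scorable by the matrix")
    return "".join(out)


def global_align(a: str, b: str, params: AlignParams | None = None) -> PairwiseAlignment:
    """Optimal affine-gap global alignment of two sequences.

    The pair is aligned in a canonical order so that the result (score and
    identity) is symmetric in its arguments even when co-optimal alignments
    exist.
    """
    params = params or AlignParams()
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    swapped = b < a
    x, y = (b, a) if swapped else (a, b)
    aligner = _aligner(params)
    alphabet = str(aligner.substitution_matrix.alphabet)
    aln = aligner.align(_for_matrix(x, alphabet), _for_matrix(y, alphabet))[0]
    gapped_x, gapped_y = _gapped_strings(x, y, aln.aligned)
    if swapped:
        gapped_x, gapped_y = gapped_y, gapped_x
    matches = sum(ca == cb and ca != "-" for ca, cb in zip(gapped_x, gapped_y))
    return PairwiseAlignment(
        aligned_a=gapped_x,
        aligned_b=gapped_y,
        score=float(aln.score),
        identity=matches / len(gapped_x),
    )


def _gapped_strings(a: str, b: str, aligned_blocks) -> tuple[str, str]:
    blocks_a, blocks_b = aligned_blocks
    out_a: list[str] = []
    out_b: list[str] = []
    pa = pb = 0
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        if pa < sa:
            out_a.append(a[pa:sa])
            out_b.append("-" * (sa - pa))
        if pb < sb:
            out_a.append("-" * (sb - pb))
            out_b.append(b[pb:sb])
        out_a.append(a[sa:ea])
        out_b.append(b[sb:eb])
        pa, pb = ea, eb
    if pa < len(a):
        out_a.append(a[pa:])
        out_b.append("-" * (len(a) - pa))
    if pb < len(b):
        out_a.append("-" * (len(b) - pb))
        out_b.append(b[pb:])
    return "".join(out_a), "".join(out_b)


def percent_identity(aln: PairwiseAlignment) -> float:
    """Matches over columns with at least one non-gap residue (all columns,
    pairwise)."""
    if len(aln.aligned_a) == 0:
        raise ValueError("zero-length alignment")
    matches = sum(a == b and a != "-" for a, b in zip(aln.aligned_a, aln.aligned_b))
    return matches / len(aln.aligned_a)


# ---------------------------------------------------------------------------
# progressive multiple alignment

_EXT_AA = STANDARD_AA + "BZX"  # columns scorable by BLOSUM62
_AA_INDEX = {aa: i for i, aa in enumerate(_EXT_AA)}


def _submatrix(params: AlignParams) -> np.ndarray:
    m = substitution_matrices.load(params.matrix)
    alpha = str(m.alphabet)
    S = np.zeros((len(_EXT_AA), len(_EXT_AA)))
    for i, a in enumerate(_EXT_AA):
        for j, b in enumerate(_EXT_AA):
            ka = a if a in alpha else "X"
            kb = b if b in alpha else "X"
            S[i, j] = m[ka, kb]
    return S


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    if len(a) < k or len(b) < k:
        return 1.0
    def counts(s: str) -> dict[str, int]:
        c: dict[str, int] = {}
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            c[w] = c.get(w, 0) + 1
        return c
    ca, cb = counts(a), counts(b)
    common = sum(min(n, cb.get(w, 0)) for w, n in ca.items())
    denom = min(len(a), len(b)) - k + 1
    return 1.0 - common / denom


def _profile_freqs(rows: Sequence[str]) -> np.ndarray:
    """(ncol, 21) frequency matrix; last column is the gap fraction.

    Residue frequencies are normalized by the number of rows, so gapped rows
    contribute nothing to the residue part (their weight sits in the gap
    column).
    """
    ncol = len(rows[0])
    F = np.zeros((ncol, len(_EXT_AA) + 1))
    for row in rows:
        for j, ch in enumerate(row):
            if ch == "-":
                F[j, -1] += 1.0
            else:
                F[j, _AA_INDEX.get(ch, _AA_INDEX["X"])] += 1.0
    return F / len(rows)


def _merge(rows_a: list[str], rows_b: list[str], S: np.ndarray, params: AlignParams):
    fa = _profile_freqs(rows_a)
    fb = _profile_freqs(rows_b)
    score_mat = fa[:, :-1] @ S @ fb[:, :-1].T
    _, path = affine_align_matrix(score_mat, params.gap_open, params.gap_extend)
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    i = j = 0
    for move in path:
        if move == 0:
            for r, row in enumerate(rows_a):
                out_a[r] += row[i]
            for r, row in enumerate(rows_b):
                out_b[r] += row[j]
            i += 1
            j += 1
        elif move == 1:
            for r, row in enumerate(rows_a):
                out_a[r] += row[i]
            for r in range(len(rows_b)):
                out_b[r] += "-"
            i += 1
        else:
            for r in range(len(rows_a)):
                out_a[r] += "-"
            for r, row in enumerate(rows_b):
                out_b[r] += row[j]
            j += 1
    return out_a, out_b


def build_msa(records: Sequence[ProteinRecord], params: AlignParams | None = None) -> MSA:
    """Progressive multiple alignment over a UPGMA guide tree.

    Guide distances are fractional 3-mer distances; profiles are merged with
    affine-gap Needleman-Wunsch on expected column-pair substitution scores.
    Row order matches the input record order.
    """
    params = params or AlignParams()
    if len(records) == 0:
        raise ValueError("need at least one record")
    if len(records) == 1:
        return MSA(ids=[records[0].id], rows=[records[0].seq])
    n = len(records)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _kmer_distance(records[i].seq, records[j].seq)
    Z = linkage(squareform(D, checks=False), method="average")
    S = _submatrix(params)

    def merge_node(node) -> tuple[list[int], list[str]]:
        if node.is_leaf():
            return [node.id], [records[node.id].seq]
        idx_l, rows_l = merge_node(node.left)
        idx_r, rows_r = merge_node(node.right)
        out_l, out_r = _merge(rows_l, rows_r, S, params)
        return idx_l + idx_r, out_l + out_r

    idx, rows = merge_node(to_tree(Z))
    order = np.argsort(idx)
    return MSA(ids=[records[idx[k]].id for k in order], rows=[rows[k] for k in order])


def mask_msa(msa: MSA, cfg: MaskConfig | None = None) -> MSA:
    """Remove columns whose gap fraction strictly exceeds the threshold.

    Terminal gaps count as gaps; a column with exactly the threshold gap
    fraction is retained.
    """
    cfg = cfg or MaskConfig()
    if msa.nrow == 0:
        return MSA(ids=[], rows=[])
    arr = np.array([list(r) for r in msa.rows])
    gap_frac = (arr == "-").mean(axis=0)
    keep = gap_frac <= cfg.max_gap_fraction
    rows = ["".join(row[keep]) for row in arr]
    return MSA(ids=list(msa.ids), rows=rows)


def aai_matrix(
    records: Sequence[ProteinRecord],
    params: AlignParams | None = None,
    mode: str = "pairwise",
    msa: MSA | None = None,
) -> pd.DataFrame:
    """Symmetric amino-acid identity matrix with unit diagonal.

    ``mode="pairwise"`` (default) computes identity on fresh global pairwise
    alignments; ``mode="msa"`` extracts each pair from a supplied unmasked
    MSA, dropping the pair's dual-gap columns first.
    """
    params = params or AlignParams()
    if len(records) < 2:
        raise ValueError("need at least two records")
    n = len(records)
    M = np.eye(n)
    if mode == "pairwise":
        for i in range(n):
            for j in range(i + 1, n):
                aln = global_align(records[i].seq, records[j].seq, params)
                M[i, j] = M[j, i] = percent_identity(aln)
    elif mode == "msa":
        if msa is None:
            raise ValueError("mode='msa' requires an msa")
        pos = {rid: k for k, rid in enumerate(msa.ids)}
        for i in range(n):
            for j in range(i + 1, n):
                ra = msa.rows[pos[records[i].id]]
                rb = msa.rows[pos[records[j].id]]
                cols = [(a, b) for a, b in zip(ra, rb) if not (a == "-" and b == "-")]
                matches = sum(a == b and a != "-" for a, b in cols)
                M[i, j] = M[j, i] = matches / len(cols)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    ids = [r.id for r in records]
    return pd.DataFrame(M, index=ids, columns=ids)


def consensus_logo(
    msa: MSA,
    tie_margin: float = 0.35,
    wildcard_below: float = 0.50,
    small_sample_correction: bool = False,
) -> LogoTable:
    """Column frequencies, information content (bits) and a consensus string.

    Information is ``log2(20) - H`` with H the Shannon entropy of the
    non-gap residue frequencies.  The consensus uses bracket notation
    ``[A/B]`` when the top two frequencies both reach ``tie_margin`` and a
    wildcard ``X`` when the modal frequency is below ``wildcard_below``.
    The optional small-sample correction subtracts the ``(s-1)/(2 ln2 n)``
    entropy bias term; it is off by default, appropriate for logos built
    from hundreds of sequences.
    """
    if msa.nrow == 0:
        raise ValueError("empty MSA")
    aa = list(STANDARD_AA)
    arr = np.array([list(r) for r in msa.rows])
    ncol = msa.ncol
    freqs = np.zeros((ncol, 20))
    info = np.zeros(ncol)
    consensus: list[str] = []
    max_bits = np.log2(20.0)
    for c in range(ncol):
        col = arr[:, c]
        residues = col[np.isin(col, aa)]
        if residues.size == 0:
            consensus.append("-")
            continue
        counts = np.array([(residues == a).sum() for a in aa], dtype=float)
        f = counts / counts.sum()
        freqs[c] = f
        nz = f[f > 0]
        h = -(nz * np.log2(nz)).sum()
        bits = max_bits - h
        if small_sample_correction:
            bits -= 19.0 / (2.0 * np.log(2.0) * residues.size)
        info[c] = max(bits, 0.0)
        # stable sort on descending frequency; the alphabet is already
        # alphabetical, so ties break alphabetically
        order = np.argsort(-f, kind="stable")
        top, second = order[0], order[1]
        if f[top] >= tie_margin and f[second] >= tie_margin:
            consensus.append(f"[{aa[top]}/{aa[second]}]")
        elif f[top] < wildcard_below:
            consensus.append("X")
        else:
            consensus.append(aa[top])
    return LogoTable(
        frequencies=pd.DataFrame(freqs, columns=aa),
        information=info,
        consensus=consensus,
    )


def read_msa_fasta(path: str | Path) -> MSA:
    """Read an aligned FASTA (gap character '-') into an MSA."""
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return MSA(ids=ids, rows=rows)


def write_msa_fasta(msa: MSA, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(msa.ids, msa.rows):
            fh.write(f">{rid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")
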