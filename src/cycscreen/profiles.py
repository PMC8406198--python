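"""Per-cluster position-specific profile models and cluster classification.

Each Cyc2 phylogenetic cluster gets a profile built from a training
alignment: match states are the well-occupied columns, emissions are
pseudocount-smoothed log-odds against the pooled training background, and
affine insert/delete penalties are derived from the observed gap structure.
Sequences are scored by Viterbi dynamic programming, global in the model and
local in the sequence, in bits.

Classification mirrors the published decision structure: a candidate without
a heme-binding CXXCH is excluded outright, as is anything shorter than the
minimum full-length cutoff; surviving candidates are assigned to the
highest-scoring cluster among those whose calibrated bit-score cutoff they
exceed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._dp import glocal_viterbi
from .align import MSA
from .screen import ProteinRecord, STANDARD_AA, find_heme_motifs

__all__ = [
    "ProfileModel",
    "ClusterCall",
    "build_profile",
    "score_sequence",
    "calibrate_cutoff",
    "classify",
]

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}

# penalty bounds (bits): penalties derived from observed gap frequencies are
# clipped so that gap-free training alignments still admit rare indels
_OPEN_FLOOR, _OPEN_CEIL = 2.0, 10.0
_EXT_FLOOR, _EXT_CEIL = 0.5, 4.0


@dataclass
class ProfileModel:
    cluster_label: str
    match_emissions: np.ndarray  # (L, 20) log-odds in bits
    background: np.ndarray  # (20,) frequencies
    insert_open: float
    insert_extend: float
    delete_open: float
    delete_extend: float
    cutoff_bits: float | None = None
    min_length: int = 365

    @property
    def length(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(STANDARD_AA[i] for i in self.match_emissions.argmax(axis=1))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cluster_label": self.cluster_label,
            "match_emissions_bits": self.match_emissions.tolist(),
            "background": self.background.tolist(),
            "insert_open": self.insert_open,
            "insert_extend": self.insert_extend,
            "delete_open": self.delete_open,
            "delete_extend": self.delete_extend,
            "cutoff_bits": self.cutoff_bits,
            "min_length": self.min_length,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProfileModel":
        d = json.loads(Path(path).read_text())
        return cls(
            cluster_label=d["cluster_label"],
            match_emissions=np.asarray(d["match_emissions_bits"], dtype=float),
            background=np.asarray(d["background"], dtype=float),
            insert_open=d["insert_open"],
            insert_extend=d["insert_extend"],
            delete_open=d["delete_open"],
            delete_extend=d["delete_extend"],
            cutoff_bits=d["cutoff_bits"],
            min_length=d["min_length"],
        )


@dataclass(frozen=True)
class ClusterCall:
    record_id: str
    scores_bits: dict[str, float]
    best_cluster: str | None
    excluded: bool
    exclusion_reason: str  # no_heme_motif | too_short | below_cutoff | none

    def __post_init__(self) -> None:
        if self.excluded and self.best_cluster is not None:
            raise ValueError("an excluded record cannot carry a best_cluster")


def build_profile(
    msa: MSA,
    label: str,
    pseudocount: float = 1.0,
    match_gap_threshold: float = 0.50,
) -> ProfileModel:
    """Build a profile from a training alignment.

    Match states are the columns with at most ``match_gap_threshold`` gaps.
    Emissions are ``(count + pseudocount) / (n + 20 * pseudocount)`` turned
    into log-odds (bits) against the pooled residue frequencies of the match
    columns.  Insert/delete penalties come from observed gap opening and
    extension frequencies, clipped into fixed bounds.
    """
    if msa.nrow < 2:
        raise ValueError("need an MSA with at least two rows")
    arr = np.array([list(r) for r in msa.rows])
    gap = arr == "-"
    match_cols = np.where(gap.mean(axis=0) <= match_gap_threshold)[0]
    if match_cols.size == 0:
        raise ValueError("no match columns at the given gap threshold")

    counts = np.zeros((match_cols.size, 20))
    for k, c in enumerate(match_cols):
        for ch in arr[:, c]:
            if ch in _AA_INDEX:
                counts[k, _AA_INDEX[ch]] += 1.0
    probs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 20.0 * pseudocount)
    pooled = counts.sum(axis=0) + pseudocount
    background = pooled / pooled.sum()
    emissions = np.log2(probs / background)

    # gap geometry over match columns only
    sub = gap[:, match_cols]
    opens = np.logical_and(sub[:, 1:], ~sub[:, :-1]).sum() + sub[:, 0].sum()
    extends = np.logical_and(sub[:, 1:], sub[:, :-1]).sum()
    total = sub.size
    f_open = opens / total
    f_ext = extends / max(total - msa.nrow, 1)
    delete_open = float(np.clip(-np.log2(f_open + 1e-9), _OPEN_FLOOR, _OPEN_CEIL))
    delete_extend = float(np.clip(-np.log2(f_ext + 1e-9), _EXT_FLOOR, _EXT_CEIL))

    # insert geometry: residues falling in non-match columns
    ins_mask = np.ones(arr.shape[1], dtype=bool)
    ins_mask[match_cols] = False
    ins_frac = (~gap[:, ins_mask]).sum() / max(arr.size, 1)
    insert_open = float(np.clip(-np.log2(ins_frac + 1e-9), _OPEN_FLOOR, _OPEN_CEIL))
    insert_extend = float(np.clip(insert_open / 4.0, _EXT_FLOOR, _EXT_CEIL))

    return ProfileModel(
        cluster_label=str(label),
        match_emissions=emissions,
        background=background,
        insert_open=insert_open,
        insert_extend=insert_extend,
        delete_open=delete_open,
        delete_extend=delete_extend,
    )


def score_sequence(profile: ProfileModel, seq: str) -> float:
    """Best glocal Viterbi score of ``seq`` against the profile, in bits.

    Unknown residues (X/B/Z/U) emit log-odds zero; flanking residues outside
    the matched window are free, so the score does not depend on them.
    """
    if len(seq) < 5:
        raise ValueError("sequence shorter than 5 residues cannot be scored")
    idx = np.array([_AA_INDEX.get(ch, -1) for ch in seq.upper()], dtype=np.int64)
    return float(
        glocal_viterbi(
            np.ascontiguousarray(profile.match_emissions),
            idx,
            profile.insert_open,
            profile.insert_extend,
            profile.delete_open,
            profile.delete_extend,
        )
    )


def calibrate_cutoff(
    profile: ProfileModel,
    positives: Sequence[ProteinRecord],
    negatives: Sequence[ProteinRecord],
) -> float:
    """Calibrate and store the profile's bit-score cutoff.

    When the score distributions separate, the cutoff is the midpoint of the
    gap between the highest negative and the lowest positive.  Otherwise it
    is the threshold maximizing F1 (accepted = score >= cutoff), ties broken
    toward the higher cutoff.
    """
    if not positives or not negatives:
        raise ValueError("both calibration sets must be non-empty")
    pos = np.array([score_sequence(profile, r.seq) for r in positives])
    neg = np.array([score_sequence(profile, r.seq) for r in negatives])
    if pos.min() > neg.max():
        cutoff = 0.5 * (pos.min() + neg.max())
    else:
        best_f1, cutoff = -1.0, float(np.concatenate([pos, neg]).max())
        for t in sorted(np.unique(np.concatenate([pos, neg]))):
            tp = int((pos >= t).sum())
            fp = int((neg >= t).sum())
            fn = int((pos < t).sum())
            f1 = 2.0 * tp / max(2.0 * tp + fp + fn, 1e-12)
            if f1 > best_f1 or (f1 == best_f1 and t > cutoff):
                best_f1, cutoff = f1, float(t)
    profile.cutoff_bits = float(cutoff)
    return profile.cutoff_bits


def classify(record: ProteinRecord, profiles: Sequence[ProfileModel]) -> ClusterCall:
    """Assign a record to a cluster, applying the guards first.

    Guard order: no CXXCH anywhere -> ``no_heme_motif``; shorter than the
    minimum full length -> ``too_short``.  Otherwise the record is scored
    against every profile and assigned to the highest-scoring cluster among
    those whose cutoff it meets; if none, it is excluded as
    ``below_cutoff``.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    if any(p.cutoff_bits is None for p in profiles):
        raise ValueError("all profiles must be calibrated before classification")
    min_length = min(p.min_length for p in profiles)
    if not find_heme_motifs(record.seq):
        return ClusterCall(record.id, {}, None, True, "no_heme_motif")
    if len(record) < min_length:
        return ClusterCall(record.id, {}, None, True, "too_short")
    scores = {p.cluster_label: score_sequence(p, record.seq) for p in profiles}
    eligible = [p for p in profiles if scores[p.cluster_label] >= p.cutoff_bits]
    if not eligible:
        return ClusterCall(record.id, scores, None, True, "below_cutoff")
    best = max(eligible, key=lambda p: (scores[p.cluster_label], p.cluster_label))
    return ClusterCall(record.id, scores, best.cluster_label, False, "none")
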