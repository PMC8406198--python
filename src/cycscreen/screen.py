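"""Sequence ingestion, Cyc2 motif screening and dereplication.

Cyc2 proteins are fused monoheme cytochrome-porins.  The cytochrome domain
carries a single c-type heme attachment site (CXXCH) flanked by two short
conserved motifs: a PXFAR[Q/K][T/Y] motif a few residues upstream and a PXL
motif a few residues downstream.  The screening rules implemented here keep
full-length candidates (>= 365 residues by default) that carry the CXXCH and
the upstream motif; dereplication removes near-identical entries the way
cd-hit does (identity over the aligned region, coverage of the shorter
sequence).

Coordinates are 0-based, half-open throughout.  A "spacer" is the number of
residues strictly between two motif spans.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: residues accepted in a ProteinRecord: the 20 standard letters plus
#: ambiguity codes (X any, B Asx, Z Glx) and selenocysteine (U).
ALLOWED_RESIDUES = frozenset(STANDARD_AA) | frozenset("XBZU")

CXXCH_PATTERN = re.compile(r"(?=(C[A-Z]{2}CH))")

__all__ = [
    "ProteinRecord",
    "MotifHit",
    "MotifAnnotation",
    "ScreenRules",
    "ScreenDecision",
    "DereplicationConfig",
    "read_fasta",
    "write_fasta",
    "find_heme_motifs",
    "find_cyc2_motifs",
    "screen_record",
    "screen_records",
    "dereplicate",
    "motif_to_regex",
]


class FastaFormatError(ValueError):
    """Raised when a FASTA file violates the format (e.g. empty sequence)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence flowing through the screen/align/classify stages."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(self.seq) - ALLOWED_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue(s) {sorted(bad)} "
                "(gap characters are not allowed in unaligned records)"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MotifHit:
    """A located motif occurrence; ``matched == seq[start:end]``."""

    name: str  # one of {"CXXCH", "UPSTREAM", "PXL"}
    start: int
    end: int
    matched: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("motif span must satisfy 0 <= start < end")
        if self.end - self.start != len(self.matched):
            raise ValueError("matched substring length must equal span length")


@dataclass(frozen=True)
class MotifAnnotation:
    """CXXCH plus flanking motifs with spacer measurements.

    Spacers count residues strictly between the motif spans:
    ``upstream_spacer = cxxch.start - upstream.end`` and
    ``downstream_spacer = downstream.start - cxxch.end``.
    """

    cxxch: MotifHit | None = None
    upstream: MotifHit | None = None
    downstream: MotifHit | None = None
    upstream_spacer: int | None = None
    downstream_spacer: int | None = None


@dataclass(frozen=True)
class ScreenRules:
    """The full-length-Cyc2 screening rules.

    ``upstream_pattern`` uses a simple motif syntax: plain letters are
    literals, ``X`` matches any residue, ``[QK]`` (also written ``[Q/K]``)
    matches alternatives.  An ``X`` in the *sequence* satisfies wildcard
    positions but never a literal.
    """

    min_length: int = 365
    require_cxxch: bool = True
    require_upstream: bool = True
    upstream_pattern: str = "PXFAR[QK][TY]"
    enforce_spacers: bool = False
    expected_upstream_spacer: int = 5
    expected_downstream_spacer: int = 4

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")


@dataclass(frozen=True)
class ScreenDecision:
    record_id: str
    passed: bool
    failed_rules: tuple[str, ...]
    annotation: MotifAnnotation

    def __post_init__(self) -> None:
        if self.passed != (len(self.failed_rules) == 0):
            raise ValueError("passed must be equivalent to empty failed_rules")


@dataclass(frozen=True)
class DereplicationConfig:
    """cd-hit-style dereplication: drop a sequence when a retained, longer or
    equal one matches it at ``identity_threshold`` over ``coverage_threshold``
    of the shorter sequence."""

    identity_threshold: float = 1.00
    coverage_threshold: float = 0.90

    def __post_init__(self) -> None:
        for name in ("identity_threshold", "coverage_threshold"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")


def motif_to_regex(pattern: str) -> re.Pattern[str]:
    """Compile the motif syntax (literals, X wildcard, [AB] alternatives)."""
    out: list[str] = []
    i = 0
    pattern = pattern.replace("-", "").replace("/", "")
    while i < len(pattern):
        ch = pattern[i]
        if ch == "X":
            out.append("[A-Z]")
            i += 1
        elif ch == "[":
            j = pattern.index("]", i)
            out.append(pattern[i : j + 1])
            i = j + 1
        elif ch.isalpha():
            out.append(ch)
            i += 1
        else:
            raise ValueError(f"bad motif character {ch!r} in {pattern!r}")
    return re.compile("".join(out))


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (optionally gzipped) protein FASTA into ProteinRecords.

    Order is preserved, wrapped sequence lines are concatenated and
    sequences are uppercased.  A header with an empty body raises
    :class:`FastaFormatError` naming the header.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[ProteinRecord] = []
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq)
            if not seq:
                raise FastaFormatError(f"empty sequence for header {rec.id!r}")
            records.append(ProteinRecord(id=rec.id, seq=seq, description=rec.description))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            if rec.description and rec.description != rec.id:
                desc = rec.description
                # SeqIO's record.description may already embed the id
                header = desc if desc.split()[0] == rec.id else f"{rec.id} {desc}"
            else:
                header = rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def find_heme_motifs(seq: str) -> list[MotifHit]:
    """All (possibly overlapping) CXXCH windows, left to right.

    The cysteines and histidine are literal; the two internal positions
    accept any residue letter (including X).
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    hits = []
    for m in CXXCH_PATTERN.finditer(seq):
        start = m.start()
        hits.append(MotifHit("CXXCH", start, start + 5, seq[start : start + 5]))
    return hits


def find_cyc2_motifs(record: ProteinRecord, rules: ScreenRules | None = None) -> MotifAnnotation:
    """Annotate the Cyc2 cytochrome motif architecture on one record.

    Anchors on the first (N-terminal-most) CXXCH; the upstream motif is the
    rightmost match of ``rules.upstream_pattern`` ending at or before the
    CXXCH start, the downstream motif is the first PXL starting at or after
    the CXXCH end.
    """
    rules = rules or ScreenRules()
    heme = find_heme_motifs(record.seq)
    if not heme:
        return MotifAnnotation()
    cxxch = heme[0]

    upstream = None
    up_re = motif_to_regex(rules.upstream_pattern)
    best = None
    for m in re.finditer(rf"(?=({up_re.pattern}))", record.seq[: cxxch.start]):
        end = m.start() + len(m.group(1))
        if end <= cxxch.start:
            best = m
    if best is not None:
        matched = best.group(1)
        upstream = MotifHit("UPSTREAM", best.start(), best.start() + len(matched), matched)

    downstream = None
    m = re.search(r"P[A-Z]L", record.seq[cxxch.end :])
    if m:
        start = cxxch.end + m.start()
        downstream = MotifHit("PXL", start, start + 3, record.seq[start : start + 3])

    return MotifAnnotation(
        cxxch=cxxch,
        upstream=upstream,
        downstream=downstream,
        upstream_spacer=(cxxch.start - upstream.end) if upstream else None,
        downstream_spacer=(downstream.start - cxxch.end) if downstream else None,
    )


def screen_record(record: ProteinRecord, rules: ScreenRules | None = None) -> ScreenDecision:
    """Apply the full-length-Cyc2 rules to one record.

    Passes iff the sequence is at least ``min_length`` residues, carries a
    CXXCH (when required) and carries the upstream motif before the first
    CXXCH (when required).  Every violated rule is listed.
    """
    rules = rules or ScreenRules()
    annotation = find_cyc2_motifs(record, rules)
    failed: list[str] = []
    if len(record) < rules.min_length:
        failed.append("min_length")
    if rules.require_cxxch and annotation.cxxch is None:
        failed.append("require_cxxch")
    if rules.require_upstream and annotation.upstream is None:
        failed.append("require_upstream")
    if rules.enforce_spacers:
        if annotation.upstream_spacer != rules.expected_upstream_spacer:
            failed.append("upstream_spacer")
        if annotation.downstream_spacer != rules.expected_downstream_spacer:
            failed.append("downstream_spacer")
    return ScreenDecision(
        record_id=record.id,
        passed=not failed,
        failed_rules=tuple(failed),
        annotation=annotation,
    )


def screen_records(
    records: Sequence[ProteinRecord], rules: ScreenRules | None = None
) -> list[ScreenDecision]:
    rules = rules or ScreenRules()
    return [screen_record(r, rules) for r in records]


def _redundant(shorter: ProteinRecord, longer: ProteinRecord, cfg: DereplicationConfig) -> bool:
    # identity over both-aligned columns, coverage relative to the shorter
    # sequence -- the cd-hit convention, distinct from whole-alignment AAI
    from .align import global_align

    aln = global_align(longer.seq, shorter.seq)
    pairs = matches = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca != "-" and cb != "-":
            pairs += 1
            if ca == cb:
                matches += 1
    if pairs == 0:
        return False
    identity = matches / pairs
    coverage = pairs / len(shorter)
    return identity >= cfg.identity_threshold and coverage >= cfg.coverage_threshold


def dereplicate(
    records: Sequence[ProteinRecord], cfg: DereplicationConfig | None = None
) -> list[ProteinRecord]:
    """Greedy longest-first dereplication; representatives in input order.

    Equal lengths tie-break on the lexicographically smaller id so the result
    is deterministic regardless of input order.
    """
    cfg = cfg or DereplicationConfig()
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("records must have unique ids")
    order = sorted(records, key=lambda r: (-len(r), r.id))
    retained: list[ProteinRecord] = []
    for rec in order:
        if not any(_redundant(rec, rep, cfg) for rep in retained):
            retained.append(rec)
    keep = {r.id for r in retained}
    return [r for r in records if r.id in keep]
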