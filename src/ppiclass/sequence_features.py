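"""Sequence-derived interaction features: linear-motif counts and
disordered-binding-region summaries.

Short linear motifs (ELMs) are described by regular expressions and
mediate many transient interactions; disordered binding regions are
segments predicted (externally, ANCHOR-style) to fold upon binding.
Per interaction the block has 7 values: elmA, elmB, DisRegionsA,
DisRegionsB, FracDisASA, FracDisASB, MaxDisLen — partner A being the
lexicographically smaller protein id, so the vector is independent of
the order in which the pair is written.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from Bio import SeqIO

from .network import EdgeRef

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinRecord",
    "ElmPatternSet",
    "DisorderAnnotation",
    "PairSequenceFeatures",
    "read_fasta",
    "read_elm_patterns",
    "read_disorder_table",
    "scan_elm",
    "merge_intervals",
    "disorder_summary",
    "pair_sequence_features",
    "SEQUENCE_FEATURE_NAMES",
]

SEQUENCE_FEATURE_NAMES = [
    "elmA", "elmB", "DisRegionsA", "DisRegionsB",
    "FracDisASA", "FracDisASB", "MaxDisLen",
]

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper()


class ElmPatternSet:
    """Motif id -> compiled regular expression.

    Every pattern is wrapped in a lookahead so that overlapping matches
    are counted at every start position ("all occurrences", not the
    regex engine's non-overlapping default).
    """

    def __init__(self, patterns: dict[str, str]):
        if len(set(patterns)) != len(patterns):
            raise ValueError("duplicate motif ids")
        self.raw: dict[str, str] = dict(patterns)
        self.compiled: dict[str, re.Pattern] = {}
        for mid, pat in patterns.items():
            try:
                self.compiled[mid] = re.compile(f"(?=({pat}))")
            except re.error as err:
                raise ValueError(f"motif {mid!r}: invalid regex {pat!r}: {err}")

    def __len__(self) -> int:
        return len(self.compiled)

    def __iter__(self):
        return iter(self.compiled)


@dataclass
class DisorderAnnotation:
    """Disordered binding regions of one protein, 1-based inclusive,
    merged so that touching/overlapping intervals become one region."""

    protein_id: str
    regions: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        for s, e in self.regions:
            if not 1 <= s <= e:
                raise ValueError(
                    f"{self.protein_id}: bad interval ({s}, {e})")
        self.regions = merge_intervals(self.regions)


@dataclass
class PairSequenceFeatures:
    elmA: int
    elmB: int
    DisRegionsA: int
    DisRegionsB: int
    FracDisASA: float
    FracDisASB: float
    MaxDisLen: int

    def as_list(self) -> list[float]:
        return [self.elmA, self.elmB, self.DisRegionsA, self.DisRegionsB,
                self.FracDisASA, self.FracDisASB, self.MaxDisLen]


def read_fasta(path) -> dict[str, ProteinRecord]:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = ProteinRecord(rec.id, str(rec.seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def read_elm_patterns(path) -> ElmPatternSet:
    """TSV of motif_id<TAB>regex ('#' comments allowed)."""
    patterns: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected motif_id<TAB>regex")
            if fields[0] in patterns:
                raise ValueError(f"{path}: line {lineno}: duplicate motif id {fields[0]!r}")
            patterns[fields[0]] = fields[1]
    return ElmPatternSet(patterns)


def read_disorder_table(path) -> dict[str, DisorderAnnotation]:
    """TSV of protein_id<TAB>start<TAB>end, 1-based inclusive."""
    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected protein_id<TAB>start<TAB>end")
            try:
                s, e = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-integer interval")
            raw.setdefault(fields[0], []).append((s, e))
    return {pid: DisorderAnnotation(pid, regions) for pid, regions in raw.items()}


def scan_elm(protein: ProteinRecord, patterns: ElmPatternSet) -> int:
    """Total motif matches in a sequence, summed over all motif classes.

    Matches of one motif may overlap: each start position counts.
    """
    if len(patterns) == 0:
        raise ValueError("pattern set is empty")
    seq = protein.sequence
    return sum(
        sum(1 for _ in rx.finditer(seq)) for rx in patterns.compiled.values()
    )


def merge_intervals(regions: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching 1-based inclusive intervals."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(regions):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def disorder_summary(ann: DisorderAnnotation | None,
                     seq_len: int) -> tuple[int, float, int]:
    """(number of regions, fraction of disordered residues, longest
    region length) for one protein.  ``None`` means no predicted
    regions, a legitimate outcome, summarized as (0, 0.0, 0)."""
    if seq_len <= 0:
        raise ValueError("sequence length must be positive")
    if ann is None or not ann.regions:
        return (0, 0.0, 0)
    for s, e in ann.regions:
        if e > seq_len:
            raise ValueError(
                f"{ann.protein_id}: interval ({s}, {e}) exceeds sequence "
                f"length {seq_len}")
    lengths = [e - s + 1 for s, e in ann.regions]
    return (len(ann.regions), sum(lengths) / seq_len, max(lengths))


def pair_sequence_features(
    edge: EdgeRef,
    proteins: dict[str, ProteinRecord],
    patterns: ElmPatternSet,
    disorder: dict[str, DisorderAnnotation],
    elm_cache: dict[str, int] | None = None,
) -> PairSequenceFeatures:
    """The 7 sequence features of one interaction.

    Partner A is the lexicographically smaller id (canonical edge
    order).  A protein missing from the FASTA is a hard error; one
    missing from the disorder table counts as having no regions (logged).
    """
    missing = [p for p in (edge.u, edge.v) if p not in proteins]
    if missing:
        raise KeyError(f"proteins without sequence: {missing}")
    a, b = edge.u, edge.v  # EdgeRef already canonicalizes u < v

    def elm_count(pid: str) -> int:
        if elm_cache is not None and pid in elm_cache:
            return elm_cache[pid]
        n = scan_elm(proteins[pid], patterns)
        if elm_cache is not None:
            elm_cache[pid] = n
        return n

    summaries = {}
    for pid in (a, b):
        if pid not in disorder:
            logger.debug("no disorder annotation for %s; assuming none", pid)
        summaries[pid] = disorder_summary(
            disorder.get(pid), len(proteins[pid].sequence))
    (nA, fracA, maxA) = summaries[a]
    (nB, fracB, maxB) = summaries[b]
    return PairSequenceFeatures(
        elmA=elm_count(a), elmB=elm_count(b),
        DisRegionsA=nA, DisRegionsB=nB,
        FracDisASA=fracA, FracDisASB=fracB,
        MaxDisLen=max(maxA, maxB),
    )
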