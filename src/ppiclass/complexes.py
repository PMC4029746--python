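"""Complex-level analysis of interaction-type composition.

Within a multi-protein complex the classified intra-complex
interactions define a four-way type mixture over the combinations
SP/obligate, SP/non-obligate, ME/obligate, ME/non-obligate.  Its
Shannon entropy H(c) (in bits) measures how mixed the complex is, and
the information content

    R(c) = log2(4) - H(c) = 2 - H(c)

is 2 bits when all interactions share one type and 0 bits when all four
types are equally represented.  A complex is *enriched* in a type when
that type makes up at least half of its classified intra-complex
interactions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .network import ComplexRecord, EdgeRef, InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "TYPE_COMBINATIONS",
    "ComplexTypeProfile",
    "filter_complexes",
    "information_content",
    "complex_type_profile",
    "enrichment_calls",
    "enrichment_fractions",
    "intra_inter_split",
    "annotate_interaction_go",
    "profile_table",
]

TYPE_COMBINATIONS = (
    "SP/obligate", "SP/non-obligate", "ME/obligate", "ME/non-obligate",
)


def filter_complexes(complexes: list[ComplexRecord], net: InteractionNetwork,
                     min_size: int = 4,
                     require_connected: bool = True) -> list[ComplexRecord]:
    """Keep complexes with >= *min_size* members whose members induce a
    connected subgraph of *net*."""
    kept = []
    for rec in complexes:
        if len(rec.members) < min_size:
            continue
        if require_connected:
            present = rec.members & set(net.nodes)
            if present != rec.members:
                continue
            sub = net.graph.subgraph(rec.members)
            if not nx.is_connected(sub):
                continue
        kept.append(rec)
    if not kept:
        logger.warning("no complex passed the filters")
    return kept


def information_content(type_counts: dict[str, int]) -> tuple[float, float]:
    """(H, R) of a four-way type mixture, in bits.

    H is the Shannon entropy of the type frequencies (zero-frequency
    types contribute nothing); R = 2 - H.  Requires at least one
    classified interaction.
    """
    total = sum(type_counts.values())
    if total == 0:
        raise ValueError("no classified interactions — information content undefined")
    H = 0.0
    for t, n in type_counts.items():
        if n:
            p = n / total
            H -= p * math.log2(p)
    return H, 2.0 - H


@dataclass
class ComplexTypeProfile:
    complex_id: str
    n_members: int
    type_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_classified(self) -> int:
        return sum(self.type_counts.values())

    def frequencies(self) -> dict[str, float]:
        n = self.n_classified
        return {t: (self.type_counts.get(t, 0) / n if n else math.nan)
                for t in TYPE_COMBINATIONS}

    def entropy(self) -> float:
        return information_content(self.type_counts)[0]

    def information_content(self) -> float:
        return information_content(self.type_counts)[1]


def complex_type_profile(rec: ComplexRecord,
                         preds: pd.DataFrame) -> ComplexTypeProfile:
    """Type mixture of one complex from joint predictions.

    *preds* is the frame produced by ``predict_types`` (indexed by
    canonical (u, v)); only decisive rows with both endpoints in the
    complex enter the counts.
    """
    counts = {t: 0 for t in TYPE_COMBINATIONS}
    for (u, v), row in preds.iterrows():
        if u in rec.members and v in rec.members:
            combo = row["combined"]
            if isinstance(combo, str):  # NaN = indecisive, excluded
                counts[combo] = counts.get(combo, 0) + 1
    return ComplexTypeProfile(rec.complex_id, len(rec.members), counts)


def enrichment_calls(profile: ComplexTypeProfile,
                     threshold: float = 0.5) -> list[str]:
    """Types making up at least *threshold* of classified interactions.

    At the default 0.5 two types can tie (both are reported); above 0.5
    at most one type can qualify.
    """
    if profile.n_classified == 0:
        return []
    freqs = profile.frequencies()
    return [t for t in TYPE_COMBINATIONS if freqs[t] >= threshold]


def enrichment_fractions(complexes: list[ComplexRecord], preds: pd.DataFrame,
                         threshold: float = 0.5) -> dict[str, float]:
    """Fraction of profiled complexes enriched in each type.

    A complex tied at exactly 50/50 counts once for each of the two
    tied types.  Complexes with no classified intra-complex interaction
    are excluded from the denominator.
    """
    n_profiled = 0
    counts = {t: 0 for t in TYPE_COMBINATIONS}
    for rec in complexes:
        prof = complex_type_profile(rec, preds)
        if prof.n_classified == 0:
            continue
        n_profiled += 1
        for t in enrichment_calls(prof, threshold):
            counts[t] += 1
    if n_profiled == 0:
        return {t: math.nan for t in TYPE_COMBINATIONS}
    return {t: counts[t] / n_profiled for t in TYPE_COMBINATIONS}


def intra_inter_split(complexes: list[ComplexRecord], preds: pd.DataFrame,
                      ) -> tuple[set[EdgeRef], set[EdgeRef]]:
    """Partition predicted interactions into intra- and inter-complex.

    An edge is intra-complex when both endpoints sit in one complex
    (counted as intra for each such complex when complexes overlap); it
    is inter-complex when its endpoints belong to different complexes
    only.  Edges touching no complex are in neither set.
    """
    membership: dict[str, set[str]] = {}
    for rec in complexes:
        for m in rec.members:
            membership.setdefault(m, set()).add(rec.complex_id)
    intra: set[EdgeRef] = set()
    inter: set[EdgeRef] = set()
    for (u, v) in preds.index:
        cu = membership.get(u, set())
        cv = membership.get(v, set())
        if cu & cv:
            intra.add(EdgeRef(u, v))
        elif cu and cv:
            inter.add(EdgeRef(u, v))
    return intra, inter


def annotate_interaction_go(termsA: set[str], termsB: set[str]) -> set[str]:
    """GO annotation of an interaction: the terms shared by both
    partners (set intersection of the raw annotated sets)."""
    return set(termsA) & set(termsB)


def profile_table(complexes: list[ComplexRecord], preds: pd.DataFrame,
                  threshold: float = 0.5) -> pd.DataFrame:
    """Per-complex profile frame: sizes, type frequencies, H, R, and
    enrichment flags.  Complexes with no classified intra-complex
    interaction get NaN entropy columns and no enrichment call."""
    rows = []
    for rec in sorted(complexes, key=lambda r: r.complex_id):
        prof = complex_type_profile(rec, preds)
        row = {
            "complex_id": prof.complex_id,
            "n_members": prof.n_members,
            "n_classified": prof.n_classified,
        }
        freqs = prof.frequencies()
        for t in TYPE_COMBINATIONS:
            row[f"P({t})"] = freqs[t]
        if prof.n_classified:
            row["H"], row["R"] = information_content(prof.type_counts)
        else:
            row["H"], row["R"] = math.nan, math.nan
        row["enriched_types"] = ";".join(enrichment_calls(prof, threshold))
        rows.append(row)
    return pd.DataFrame(rows)
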