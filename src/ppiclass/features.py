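"""Assembly of the 82-column interaction feature table.

Column order (fixed, documented): 7 sequence features, 71 network
features, 4 functional-similarity features —

    elmA elmB DisRegionsA DisRegionsB FracDisASA FracDisASB MaxDisLen
    Degree Betweeness APR orbit1 .. orbit68
    BP CC MF MeanSim

Features that cannot be computed for an interaction (e.g. a GO aspect
with no annotation for one partner) are NaN; the classifier imputes
them at training time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .go_similarity import (FUNSIM_FEATURE_NAMES, AnnotationMap,
                            OntologyGraph, aspect_features)
from .graphlets import OrbitCatalog, build_orbit_catalog
from .network import EdgeRef, InteractionNetwork
from .network_features import (NETWORK_FEATURE_NAMES, all_edge_betweenness,
                               network_feature_block)
from .sequence_features import (SEQUENCE_FEATURE_NAMES, DisorderAnnotation,
                                ElmPatternSet, ProteinRecord,
                                pair_sequence_features)

__all__ = ["FEATURE_NAMES", "FeatureSources", "assemble_features",
           "assemble_feature_table"]

FEATURE_NAMES: list[str] = (
    SEQUENCE_FEATURE_NAMES + NETWORK_FEATURE_NAMES + FUNSIM_FEATURE_NAMES
)
assert len(FEATURE_NAMES) == 82


@dataclass
class FeatureSources:
    """Everything needed to featurize interactions of one network."""

    net: InteractionNetwork
    proteins: dict[str, ProteinRecord]
    patterns: ElmPatternSet
    disorder: dict[str, DisorderAnnotation]
    onto: OntologyGraph
    annots: AnnotationMap
    catalog: OrbitCatalog | None = None
    apr_damping: float = 0.85
    apr_combine: str = "min"
    _betweenness: dict | None = field(default=None, repr=False)
    _elm_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.catalog is None:
            self.catalog = build_orbit_catalog()

    def betweenness(self) -> dict:
        if self._betweenness is None:
            self._betweenness = all_edge_betweenness(self.net)
        return self._betweenness


def assemble_features(sources: FeatureSources, e: EdgeRef) -> pd.Series:
    """One 82-value feature vector; NaN marks missing features."""
    if not sources.net.has_edge(e.u, e.v):
        raise ValueError(f"edge {e.u!r}-{e.v!r} not in network")
    seq = pair_sequence_features(
        e, sources.proteins, sources.patterns, sources.disorder,
        elm_cache=sources._elm_cache)
    block = network_feature_block(
        sources.net, e, sources.catalog,
        betweenness=sources.betweenness(),
        damping=sources.apr_damping, combine=sources.apr_combine)
    funsim = aspect_features(sources.onto, sources.annots, e)
    values = np.concatenate([seq.as_list(), block.as_array(), funsim])
    return pd.Series(values, index=FEATURE_NAMES, name=e.as_tuple())


def assemble_feature_table(sources: FeatureSources,
                           edges: list[EdgeRef] | None = None) -> pd.DataFrame:
    """Feature matrix for a list of edges (default: every network edge),
    indexed by the canonical (u, v) pair."""
    if edges is None:
        edges = sources.net.edge_refs()
    rows = [assemble_features(sources, e) for e in edges]
    df = pd.DataFrame(rows)
    df.index = pd.MultiIndex.from_tuples(
        [e.as_tuple() for e in edges], names=["u", "v"])
    return df
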