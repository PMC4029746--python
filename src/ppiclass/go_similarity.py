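"""Gene Ontology semantic similarity (Wang method) and the protein-pair
functional-similarity features.

The Wang measure scores two GO terms by how much of their weighted
ancestor graphs they share: every ancestor t of a term A receives an
S-value S_A(t), the maximal product of edge weights along a path from A
up to t (S_A(A) = 1), and

    sim(A, B) = sum over shared ancestors of (S_A(t) + S_B(t))
                / (SV(A) + SV(B)),       SV(X) = sum of all S_X(t).

Protein-pair similarity ("funsim") compares all terms of protein A with
all terms of protein B and averages the best match of every term:
the mean of the row maxima and column maxima of the cross-similarity
matrix.  It is computed per GO aspect (BP, CC, MF); MeanSim averages
the aspects for which both proteins are annotated.
"""

from __future__ import annotations

import math

import numpy as np

from .network import EdgeRef

__all__ = [
    "OntologyGraph",
    "AnnotationMap",
    "read_obo",
    "read_gaf",
    "term_similarity_wang",
    "protein_pair_funsim",
    "aspect_features",
    "FUNSIM_FEATURE_NAMES",
    "ASPECTS",
]

ASPECTS = ("BP", "CC", "MF")
FUNSIM_FEATURE_NAMES = ["BP", "CC", "MF", "MeanSim"]

_NAMESPACE_TO_ASPECT = {
    "biological_process": "BP",
    "cellular_component": "CC",
    "molecular_function": "MF",
}
_GAF_ASPECT = {"P": "BP", "C": "CC", "F": "MF"}

DEFAULT_EDGE_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


class OntologyGraph:
    """A GO-style DAG: terms with is_a / part_of edges to parents and a
    namespace (aspect) per term."""

    def __init__(self,
                 parents: dict[str, list[tuple[str, str]]],
                 namespace: dict[str, str]):
        # parents: term -> [(parent term, relation)], relation in
        # {"is_a", "part_of"}
        self.parents = {t: list(ps) for t, ps in parents.items()}
        self.namespace = dict(namespace)
        for t, ps in self.parents.items():
            for p, rel in ps:
                if rel not in ("is_a", "part_of"):
                    raise ValueError(f"unsupported relation {rel!r} on {t}")
                if p not in self.namespace:
                    raise ValueError(f"parent {p!r} of {t!r} is unknown")

    def __contains__(self, term: str) -> bool:
        return term in self.namespace

    def aspect(self, term: str) -> str:
        ns = self.namespace[term]
        return _NAMESPACE_TO_ASPECT.get(ns, ns)

    def ancestor_closure(self, term: str) -> set[str]:
        """The term and all its is_a/part_of ancestors."""
        seen = {term}
        stack = [term]
        while stack:
            t = stack.pop()
            for p, _rel in self.parents.get(t, ()):
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return seen

    def svalues(self, term: str,
                weights: dict[str, float] | None = None) -> dict[str, float]:
        """Wang S-values of every ancestor of *term* (incl. itself)."""
        if term not in self.namespace:
            raise KeyError(f"unknown GO term {term!r}")
        w = weights or DEFAULT_EDGE_WEIGHTS
        for rel, val in w.items():
            if not 0 < val <= 1:
                raise ValueError(f"edge weight for {rel} must be in (0, 1]")
        closure = self.ancestor_closure(term)
        S = {t: 0.0 for t in closure}
        S[term] = 1.0
        # relax child->parent edges in topological order (Kahn): every
        # node is finalized before its own out-edges are relaxed, so
        # S(parent) ends up as the max weight-product over paths.
        topo: list[str] = []
        indeg = {t: 0 for t in closure}
        for t in closure:
            for p, rel in self.parents.get(t, ()):
                if p in closure:
                    indeg[p] += 1
        stack = [t for t, d in indeg.items() if d == 0]
        while stack:
            t = stack.pop()
            topo.append(t)
            for p, rel in self.parents.get(t, ()):
                if p in closure:
                    S[p] = max(S[p], w[rel] * S[t])
                    indeg[p] -= 1
                    if indeg[p] == 0:
                        stack.append(p)
        if len(topo) != len(closure):
            raise ValueError(f"cycle detected in ontology above {term!r}")
        return S


def read_obo(path) -> OntologyGraph:
    """Load an OBO 1.2 ontology (is_a and part_of edges; obsolete terms
    excluded) via obonet."""
    import obonet

    g = obonet.read_obo(str(path))
    parents: dict[str, list[tuple[str, str]]] = {}
    namespace: dict[str, str] = {}
    for term, data in g.nodes(data=True):
        namespace[term] = data.get("namespace", "")
    for term in g.nodes:
        plist: list[tuple[str, str]] = []
        for _child, parent, rel in g.out_edges(term, keys=True):
            if rel in ("is_a", "part_of") and parent in namespace:
                plist.append((parent, rel))
        parents[term] = plist
    return OntologyGraph(parents, namespace)


class AnnotationMap:
    """Protein -> GO terms, split by aspect."""

    def __init__(self, terms_by_aspect: dict[str, dict[str, set[str]]]):
        # terms_by_aspect: protein -> {"BP": {...}, "CC": {...}, "MF": {...}}
        self.data = terms_by_aspect

    def terms(self, protein: str, aspect: str) -> set[str]:
        return self.data.get(protein, {}).get(aspect, set())

    def proteins(self) -> set[str]:
        return set(self.data)


def read_gaf(path, onto: OntologyGraph | None = None,
             evidence_filter: set[str] | None = None) -> AnnotationMap:
    """Load a GAF 2.x annotation file.

    Columns used: 2 (object id), 5 (GO id), 7 (evidence code), 9
    (aspect).  Evidence codes are kept wholesale unless an explicit
    *evidence_filter* is given.  Terms missing from *onto* (if provided)
    are dropped.
    """
    data: dict[str, dict[str, set[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}: line {lineno}: GAF rows need >=9 columns")
            pid, go_id, evidence, aspect_code = (
                fields[1], fields[4], fields[6], fields[8])
            if evidence_filter and evidence not in evidence_filter:
                continue
            aspect = _GAF_ASPECT.get(aspect_code)
            if aspect is None:
                raise ValueError(
                    f"{path}: line {lineno}: unknown aspect {aspect_code!r}")
            if onto is not None and go_id not in onto:
                continue
            data.setdefault(pid, {a: set() for a in ASPECTS})[aspect].add(go_id)
    return AnnotationMap(data)


def term_similarity_wang(onto: OntologyGraph, t1: str, t2: str,
                         weights: dict[str, float] | None = None) -> float:
    """Wang semantic similarity of two GO terms of the same aspect."""
    if t1 not in onto or t2 not in onto:
        missing = [t for t in (t1, t2) if t not in onto]
        raise KeyError(f"unknown GO terms: {missing}")
    if onto.aspect(t1) != onto.aspect(t2):
        raise ValueError(
            f"cannot compare terms across aspects: {t1} is {onto.aspect(t1)}, "
            f"{t2} is {onto.aspect(t2)}")
    s1 = onto.svalues(t1, weights)
    s2 = onto.svalues(t2, weights)
    shared = set(s1) & set(s2)
    denom = sum(s1.values()) + sum(s2.values())
    return sum(s1[t] + s2[t] for t in shared) / denom


def protein_pair_funsim(onto: OntologyGraph, termsA: set[str], termsB: set[str],
                        weights: dict[str, float] | None = None) -> float:
    """Best-match-average similarity of two same-aspect term sets.

    Builds the full i x j cross-similarity matrix and returns
    (sum of row maxima + sum of column maxima) / (i + j).
    An empty term set yields NaN — unknown, not dissimilar.
    """
    if not termsA or not termsB:
        return math.nan
    A, B = sorted(termsA), sorted(termsB)
    m = np.empty((len(A), len(B)))
    cache: dict[tuple[str, str], float] = {}
    for i, ta in enumerate(A):
        for j, tb in enumerate(B):
            key = (ta, tb) if ta <= tb else (tb, ta)
            if key not in cache:
                cache[key] = term_similarity_wang(onto, ta, tb, weights)
            m[i, j] = cache[key]
    return float((m.max(axis=1).sum() + m.max(axis=0).sum()) / (len(A) + len(B)))


def aspect_features(onto: OntologyGraph, annots: AnnotationMap, e: EdgeRef,
                    weights: dict[str, float] | None = None,
                    ) -> tuple[float, float, float, float]:
    """(BP, CC, MF, MeanSim) for one interaction.

    An aspect where either partner has no annotation is NaN and is
    excluded from MeanSim; MeanSim is NaN only when all aspects are.
    """
    values = []
    for aspect in ASPECTS:
        tA = annots.terms(e.u, aspect)
        tB = annots.terms(e.v, aspect)
        values.append(protein_pair_funsim(onto, tA, tB, weights))
    defined = [v for v in values if not math.isnan(v)]
    mean_sim = float(np.mean(defined)) if defined else math.nan
    return (values[0], values[1], values[2], mean_sim)
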