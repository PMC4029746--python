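"""Synthetic fixtures with planted ground truth.

Generates every input the pipeline consumes — networks with planted
topological structures, sequences with planted motifs, disorder tables,
a toy GO-style DAG with annotations, and labeled feature tables whose
class-conditional means follow the directions reported for real
interaction types (non-obligate partners: more disorder regions, more
linear motifs, lower functional similarity; mutually-exclusive
interactions: higher degree and bottleneck-orbit load).  Each generator
returns a manifest that makes the planted quantities assertable, and is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .go_similarity import ASPECTS, AnnotationMap, OntologyGraph
from .network import InteractionNetwork
from .sequence_features import (DisorderAnnotation, ElmPatternSet,
                                ProteinRecord)

__all__ = [
    "SyntheticSpec",
    "gen_network",
    "gen_sequences_and_annotations",
    "gen_labeled_dataset",
    "SequenceBundle",
    "OB_CLASS_MEANS",
    "SPME_CLASS_MEANS",
]

# Class-conditional means for the labeled-feature generator.  Values
# follow the reported per-class means of the strongest discriminating
# features (similarities and disorder for obligate/non-obligate; degree
# and bottleneck-type orbits for SP/ME); features not listed are
# uninformative noise.  kind: "poisson" (count), "frac" (truncated
# Gaussian in [0,1]), "pos" (truncated Gaussian >= 0).
OB_CLASS_MEANS: dict[str, tuple[float, float, str, float]] = {
    # feature: (mean obligate, mean non-obligate, kind, sd)
    "MeanSim":     (0.816, 0.63, "frac", 0.12),
    "CC":          (0.9, 0.748, "frac", 0.12),
    "BP":          (0.768, 0.517, "frac", 0.15),
    "MF":          (0.779, 0.626, "frac", 0.15),
    "DisRegionsA": (2.17, 7.27, "poisson", 0.0),
    "DisRegionsB": (2.17, 7.27, "poisson", 0.0),
    "FracDisASA":  (0.0737, 0.163, "frac", 0.06),
    "FracDisASB":  (0.0737, 0.163, "frac", 0.06),
    "MaxDisLen":   (17.5, 42.2, "pos", 16.0),
    "elmA":        (96.2, 151.0, "poisson", 0.0),
    "elmB":        (96.2, 151.0, "poisson", 0.0),
    "Betweeness":  (2463.0, 4315.0, "pos", 1800.0),
    "Degree":      (35.4, 59.0, "poisson", 0.0),
}

SPME_CLASS_MEANS: dict[str, tuple[float, float, str, float]] = {
    # feature: (mean SP, mean ME, kind, sd)
    "Degree":   (36.6, 86.9, "poisson", 0.0),
    "orbit57":  (0.00207, 0.00584, "frac", 0.002),
    "orbit43":  (0.00486, 0.0104, "frac", 0.004),
    "orbit45":  (0.006, 0.0113, "frac", 0.004),
    "orbit50":  (0.00407, 0.00853, "frac", 0.003),
    "orbit58":  (0.00211, 0.00563, "frac", 0.002),
    "orbit13":  (0.0895, 0.0552, "frac", 0.02),
    "orbit3":   (0.0556, 0.0363, "frac", 0.015),
    "orbit15":  (0.0871, 0.0558, "frac", 0.02),
    "orbit22":  (0.0491, 0.0344, "frac", 0.015),
    "orbit6":   (0.00608, 0.00917, "frac", 0.003),
}

# default class sizes: obligate/non-obligate 280/493; SP/ME 933/3680
_TASK_DEFAULTS = {
    "ob": (("obligate", "non-obligate"), (280, 493), OB_CLASS_MEANS),
    "spme": (("SP", "ME"), (933, 3680), SPME_CLASS_MEANS),
}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic universe."""

    seed: int = 0
    # network
    n_nodes: int = 60
    p_background: float = 0.05
    clique_sizes: tuple[int, ...] = (6,)
    hub_degrees: tuple[int, ...] = (12,)
    bridges: tuple[tuple[int, int], ...] = ((8, 8),)  # two clique sizes joined by a bridge edge
    # sequences
    n_proteins: int = 20
    seq_length: int = 200
    motif: str = "WCWHW"     # contains letters absent from the background alphabet
    planted_motif_counts: tuple[int, ...] = (0, 1, 2, 3, 5)
    # ontology
    onto_depth: int = 4
    onto_branching: int = 2
    # labeled dataset
    noise_sd_scale: float = 1.0

    def __post_init__(self):
        if self.n_nodes <= 0 or self.n_proteins <= 0 or self.seq_length <= 0:
            raise ValueError("all counts must be positive")
        if not 0 <= self.p_background <= 1:
            raise ValueError("p_background must be in [0, 1]")
        for s in self.clique_sizes:
            if s > self.n_nodes:
                raise ValueError(f"planted clique of size {s} exceeds n_nodes")


def _node_name(i: int) -> str:
    return f"P{i:04d}"


def gen_network(spec: SyntheticSpec) -> tuple[InteractionNetwork, dict]:
    """Random background network with planted cliques, hubs, and
    bridged cluster pairs.

    The manifest maps every planted structure to its edges, and lists
    the pure-background edges, so tests can compare planted vs
    background topology features.
    """
    rng = np.random.default_rng(spec.seed)
    G = nx.Graph()
    names = [_node_name(i) for i in range(spec.n_nodes)]
    G.add_nodes_from(names)
    manifest: dict = {"cliques": [], "hubs": [], "bridges": [],
                      "background_edges": []}
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        if cursor + n > len(names):
            raise ValueError(
                "planted structures need more nodes than n_nodes provides")
        block = names[cursor:cursor + n]
        cursor += n
        return block

    for size in spec.clique_sizes:
        members = take(size)
        edges = [(a, b) for i, a in enumerate(members)
                 for b in members[i + 1:]]
        G.add_edges_from(edges)
        manifest["cliques"].append({"members": members, "edges": edges})
    for degree in spec.hub_degrees:
        hub, *leaves = take(degree + 1)
        edges = [(hub, leaf) for leaf in leaves]
        G.add_edges_from(edges)
        manifest["hubs"].append({"hub": hub, "edges": edges})
    for s1, s2 in spec.bridges:
        m1, m2 = take(s1), take(s2)
        e1 = [(a, b) for i, a in enumerate(m1) for b in m1[i + 1:]]
        e2 = [(a, b) for i, a in enumerate(m2) for b in m2[i + 1:]]
        bridge = (m1[0], m2[0])
        G.add_edges_from(e1 + e2 + [bridge])
        manifest["bridges"].append(
            {"cliques": [m1, m2], "clique_edges": e1 + e2, "bridge": bridge})
    planted = {frozenset(e) for e in G.edges()}
    if spec.p_background > 0:
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if frozenset((a, b)) not in planted and (
                        rng.random() < spec.p_background):
                    G.add_edge(a, b)
                    manifest["background_edges"].append((a, b))
    return InteractionNetwork(G), manifest


_BACKGROUND_ALPHABET = "ADEFGIKLMNPQRSTVY"  # no W/C/H: planted motifs cannot arise by chance


@dataclass
class SequenceBundle:
    proteins: dict[str, ProteinRecord]
    patterns: ElmPatternSet
    disorder: dict[str, DisorderAnnotation]
    onto: OntologyGraph
    annots: AnnotationMap
    manifest: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        """Emit the bundle in the formats the pipeline readers consume."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "proteins.fasta", "w") as fh:
            for rec in self.proteins.values():
                fh.write(f">{rec.id}\n{rec.sequence}\n")
        with open(outdir / "elm_patterns.tsv", "w") as fh:
            for mid, pat in self.patterns.raw.items():
                fh.write(f"{mid}\t{pat}\n")
        with open(outdir / "disorder.tsv", "w") as fh:
            for ann in self.disorder.values():
                for s, e in ann.regions:
                    fh.write(f"{ann.protein_id}\t{s}\t{e}\n")
        with open(outdir / "ontology.obo", "w") as fh:
            fh.write("format-version: 1.2\n")
            for term, ns in sorted(self.onto.namespace.items()):
                fh.write(f"\n[Term]\nid: {term}\nname: {term}\n"
                         f"namespace: {ns}\n")
                for parent, rel in self.onto.parents.get(term, ()):
                    if rel == "is_a":
                        fh.write(f"is_a: {parent}\n")
                    else:
                        fh.write(f"relationship: part_of {parent}\n")
        with open(outdir / "annotations.gaf", "w") as fh:
            fh.write("!gaf-version: 2.1\n")
            aspect_code = {"BP": "P", "CC": "C", "MF": "F"}
            for pid in sorted(self.annots.proteins()):
                for aspect in ASPECTS:
                    for term in sorted(self.annots.terms(pid, aspect)):
                        cols = ["DB", pid, pid, "", term, "REF", "IEA", "",
                                aspect_code[aspect], "", "", "protein",
                                "taxon:0000", "20130101", "DB"]
                        fh.write("\t".join(cols) + "\n")


def _toy_ontology(depth: int, branching: int) -> OntologyGraph:
    """A complete tree DAG per aspect; is_a edges, one part_of per level
    for coverage of both relations."""
    parents: dict[str, list[tuple[str, str]]] = {}
    namespace: dict[str, str] = {}
    ns_of = {"BP": "biological_process", "CC": "cellular_component",
             "MF": "molecular_function"}
    counter = 0
    for aspect in ASPECTS:
        root = f"GO:{counter:07d}"
        counter += 1
        namespace[root] = ns_of[aspect]
        parents[root] = []
        level = [root]
        for d in range(depth):
            nxt = []
            for parent in level:
                for b in range(branching):
                    term = f"GO:{counter:07d}"
                    counter += 1
                    namespace[term] = ns_of[aspect]
                    rel = "part_of" if (d > 0 and b == branching - 1) else "is_a"
                    parents[term] = [(parent, rel)]
                    nxt.append(term)
            level = nxt
    return OntologyGraph(parents, namespace)


def gen_sequences_and_annotations(spec: SyntheticSpec,
                                  ) -> SequenceBundle:
    """Sequences with exactly the planted motif counts, disorder regions
    with known summaries, a toy ontology, and annotations.

    The motif alphabet is disjoint from the background alphabet, and
    every generated sequence is re-scanned to confirm the planted count
    (with redraws on the vanishingly unlikely failure).
    """
    rng = np.random.default_rng(spec.seed + 1)
    patterns = ElmPatternSet({"MOTIF_PLANTED": spec.motif})
    proteins: dict[str, ProteinRecord] = {}
    manifest: dict = {"motif_counts": {}, "disorder": {}}
    bg = np.array(list(_BACKGROUND_ALPHABET))
    for i in range(spec.n_proteins):
        pid = _node_name(i)
        planted = spec.planted_motif_counts[i % len(spec.planted_motif_counts)]
        for _attempt in range(100):
            seq = list(rng.choice(bg, size=spec.seq_length))
            # plant motifs at disjoint slots
            L = len(spec.motif)
            n_slots = spec.seq_length // (2 * L)
            if planted > n_slots:
                raise ValueError("sequence too short for planted motif count")
            slots = rng.choice(n_slots, size=planted, replace=False)
            for s in slots:
                start = int(s) * 2 * L
                seq[start:start + L] = list(spec.motif)
            rec = ProteinRecord(pid, "".join(seq))
            from .sequence_features import scan_elm
            if scan_elm(rec, patterns) == planted:
                break
        else:
            raise RuntimeError(
                f"could not plant {planted} motifs without background collision")
        proteins[pid] = rec
        manifest["motif_counts"][pid] = planted
        # disorder regions: i % 3 regions of length 10*(j+1)
        n_regions = i % 3
        regions = []
        pos = 1
        for j in range(n_regions):
            length = 10 * (j + 1)
            regions.append((pos, pos + length - 1))
            pos += length + 5
        manifest["disorder"][pid] = regions
    disorder = {pid: DisorderAnnotation(pid, regs)
                for pid, regs in manifest["disorder"].items() if regs}
    onto = _toy_ontology(spec.onto_depth, spec.onto_branching)
    # annotations: consecutive proteins share term sets -> funsim 1 pairs;
    # others get terms from distant branches
    leaves_by_aspect = {
        aspect: sorted(t for t in onto.namespace
                       if onto.aspect(t) == aspect and not any(
                           t == p for ps in onto.parents.values()
                           for p, _ in ps))
        for aspect in ASPECTS
    }
    data: dict[str, dict[str, set[str]]] = {}
    for i, pid in enumerate(proteins):
        data[pid] = {}
        for aspect in ASPECTS:
            leaves = leaves_by_aspect[aspect]
            # pair 2i/2i+1 share an identical single-leaf annotation
            data[pid][aspect] = {leaves[(i // 2) % len(leaves)]}
    annots = AnnotationMap(data)
    return SequenceBundle(proteins, patterns, disorder, onto, annots, manifest)


def gen_labeled_dataset(spec: SyntheticSpec, task: str = "ob",
                        preset: str = "strong",
                        n_per_class: tuple[int, int] | None = None,
                        ) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Draw a labeled 82-column feature table with planted class effects.

    preset ``strong`` plants the calibrated per-class mean shifts;
    preset ``null`` draws both classes from the pooled means (no signal).
    Counts are Poisson around the class mean, fractions truncated
    Gaussians in [0, 1], other positives truncated at 0.  Returns
    (X, y, manifest); the manifest lists the informative features.
    """
    if task not in _TASK_DEFAULTS:
        raise ValueError(f"unknown task {task!r} (expected 'ob' or 'spme')")
    if preset not in ("strong", "null"):
        raise ValueError(f"unknown preset {preset!r}")
    labels, default_n, class_means = _TASK_DEFAULTS[task]
    n0, n1 = n_per_class or default_n
    if n0 < 2 or n1 < 2:
        raise ValueError("need at least 2 rows per class")
    rng = np.random.default_rng(spec.seed + 2)
    n = n0 + n1
    y = np.array([labels[0]] * n0 + [labels[1]] * n1)
    X = pd.DataFrame(index=range(n), columns=FEATURE_NAMES, dtype=float)
    sd_scale = spec.noise_sd_scale
    for feat in FEATURE_NAMES:
        if feat in class_means:
            m0, m1, kind, sd = class_means[feat]
            if preset == "null":
                m0 = m1 = (m0 + m1) / 2.0
        elif feat.startswith("orbit"):
            m0 = m1 = 0.01
            kind, sd = "frac", 0.005
        elif feat in ("Degree",):
            m0 = m1 = 40.0
            kind, sd = "poisson", 0.0
        elif feat in ("Betweeness",):
            m0 = m1 = 3000.0
            kind, sd = "pos", 1500.0
        elif feat in ("APR",):
            m0 = m1 = 0.02
            kind, sd = "frac", 0.01
        elif feat in ("elmA", "elmB", "DisRegionsA", "DisRegionsB"):
            m0 = m1 = 50.0
            kind, sd = "poisson", 0.0
        elif feat in ("MaxDisLen",):
            m0 = m1 = 30.0
            kind, sd = "pos", 10.0
        else:
            m0 = m1 = 0.1
            kind, sd = "frac", 0.05
        means = np.where(y == labels[0], m0, m1)
        if kind == "poisson":
            vals = rng.poisson(means).astype(float)
        else:
            vals = rng.normal(means, sd * sd_scale)
            if kind == "frac":
                vals = np.clip(vals, 0.0, 1.0)
            else:
                vals = np.clip(vals, 0.0, None)
        X[feat] = vals
    manifest = {
        "task": task, "preset": preset, "labels": labels,
        "n_per_class": (n0, n1),
        "informative_features": (sorted(class_means) if preset == "strong"
                                 else []),
    }
    return X, pd.Series(y, name=f"label_{task}"), manifest
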