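"""GO-based pathway functional similarity and average-linkage clustering.

Pairwise similarity between two pathways defaults to the Jaccard index of
the unions of their member proteins' is_a-propagated annotation term sets,
computed per ontology namespace and averaged over the namespaces present
(roots excluded, so universally shared top terms never inflate scores). A
best-match-average variant over per-term ancestor-set Jaccard similarities
is selectable.

Clustering follows a correlation-profile design: the distance between two
pathways is 1 − Pearson correlation of their similarity-matrix rows (the two
self-columns excluded pairwise), agglomerated with average linkage; clusters
are the dendrogram cut at distance 1 − threshold. A direct ``1 − similarity``
distance mode is also available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_formats import AnnotationSet, OntologyGraph, PathwayCollection

__all__ = [
    "ClusterResult",
    "propagate_annotations",
    "pathway_similarity",
    "similarity_matrix",
    "cluster_pathways",
    "associated_pathways",
    "dendrogram_newick",
]


def propagate_annotations(ann: AnnotationSet, graph: OntologyGraph) -> AnnotationSet:
    """Close every protein's term set under is_a ancestors; roots excluded.

    Idempotent; raises KeyError if an annotated term is absent from the graph.
    """
    roots = graph.roots
    out: AnnotationSet = {}
    for protein, terms in ann.items():
        closed: set[str] = set()
        for term in terms:
            if term not in graph.terms:
                raise KeyError(f"annotated term {term!r} not in ontology")
            closed.add(term)
            closed |= graph.ancestors(term)
        out[protein] = closed - roots
    return out


def _pathway_terms(members, propagated: AnnotationSet) -> set[str]:
    terms: set[str] = set()
    annotated = False
    for m in members:
        if m in propagated and propagated[m]:
            annotated = True
            terms |= propagated[m]
    if not annotated:
        raise ValueError("pathway has no annotated member")
    return terms


def _jaccard(a: set, b: set) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def pathway_similarity(
    members1,
    members2,
    propagated: AnnotationSet,
    graph: OntologyGraph | None = None,
    method: str = "jaccard",
) -> float:
    """Functional similarity in [0, 1] between two pathways' member sets."""
    t1 = _pathway_terms(members1, propagated)
    t2 = _pathway_terms(members2, propagated)
    if graph is None:
        spaces = {"default"}
        ns = lambda t: "default"  # noqa: E731
    else:
        ns = graph.namespace
        spaces = {ns(t) for t in t1 | t2}
    sims = []
    for space in spaces:
        s1 = {t for t in t1 if ns(t) == space}
        s2 = {t for t in t2 if ns(t) == space}
        if method == "jaccard":
            sims.append(_jaccard(s1, s2))
        elif method == "best_match_average":
            sims.append(_best_match_average(s1, s2, graph))
        else:
            raise ValueError(f"unknown similarity method {method!r}")
    return float(np.mean(sims)) if sims else 0.0


def _best_match_average(s1: set[str], s2: set[str], graph: OntologyGraph | None) -> float:
    if not s1 or not s2:
        return 0.0
    if graph is None:
        raise ValueError("best_match_average requires the ontology graph")
    anc = {t: graph.ancestors(t) | {t} for t in s1 | s2}
    def best(t: str, others: set[str]) -> float:
        return max(_jaccard(anc[t], anc[o]) for o in others)
    fwd = np.mean([best(t, s2) for t in s1])
    rev = np.mean([best(t, s1) for t in s2])
    return float((fwd + rev) / 2)


def similarity_matrix(
    pathways: PathwayCollection,
    ann: AnnotationSet,
    graph: OntologyGraph,
    method: str = "jaccard",
    propagated: bool = False,
) -> pd.DataFrame:
    """Symmetric pathway × pathway similarity matrix with unit diagonal.

    Pathway ids are sorted lexicographically so downstream tie-breaking is
    deterministic. Pass ``propagated=True`` when *ann* is already closed
    under ancestors.
    """
    ids = sorted(pathways.ids())
    if len(ids) < 2:
        raise ValueError("similarity_matrix requires at least 2 pathways")
    prop = ann if propagated else propagate_annotations(ann, graph)
    mat = np.eye(len(ids))
    for i, pi in enumerate(ids):
        for j in range(i + 1, len(ids)):
            s = pathway_similarity(
                pathways[pi].members, pathways[ids[j]].members, prop, graph, method
            )
            mat[i, j] = mat[j, i] = s
    return pd.DataFrame(mat, index=ids, columns=ids)


@dataclass
class ClusterResult:
    """Partition of pathways plus the underlying average-linkage dendrogram."""

    labels: pd.Series          # pathway id → cluster number (1..n)
    linkage: np.ndarray        # scipy linkage matrix over sorted pathway ids
    ids: list[str]
    threshold: float

    @property
    def clusters(self) -> list[set[str]]:
        groups: dict[int, set[str]] = {}
        for pid, lab in self.labels.items():
            groups.setdefault(int(lab), set()).add(pid)
        return [groups[k] for k in sorted(groups)]

    def newick(self) -> str:
        return dendrogram_newick(self.linkage, self.ids)


def _profile_correlation_distance(sim: np.ndarray) -> np.ndarray:
    """1 − Pearson r of similarity rows, the two self-columns dropped pairwise."""
    n = sim.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = np.ones(n, dtype=bool)
            mask[[i, j]] = False
            x, y = sim[i, mask], sim[j, mask]
            if x.size == 0 or x.std() == 0 or y.std() == 0:
                r = 1.0 if np.allclose(x, y) else 0.0
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            dist[i, j] = dist[j, i] = max(0.0, 1.0 - r)
    return dist


def cluster_pathways(
    sim: pd.DataFrame,
    threshold: float = 0.5,
    profile: str = "correlation",
) -> ClusterResult:
    """Average-linkage clustering of the similarity matrix, cut at 1 − threshold.

    ``profile="correlation"`` (default) uses the correlation of similarity
    profiles as affinity; ``profile="direct"`` uses the similarity values
    themselves (distance 1 − s). Raising the threshold can only refine the
    partition. Singletons are allowed.
    """
    if sim.shape[0] < 2:
        raise ValueError("cluster_pathways requires at least 2 pathways")
    ids = list(sim.index)
    order = np.argsort(ids)
    ids_sorted = [ids[i] for i in order]
    mat = sim.to_numpy(dtype=float)[np.ix_(order, order)]
    if profile == "correlation":
        dist = _profile_correlation_distance(mat)
    elif profile == "direct":
        dist = 1.0 - mat
        np.fill_diagonal(dist, 0.0)
    else:
        raise ValueError(f"unknown profile mode {profile!r}")
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    flat = hierarchy.fcluster(z, t=1.0 - threshold, criterion="distance")
    labels = pd.Series(flat, index=ids_sorted, name="cluster")
    return ClusterResult(labels=labels, linkage=z, ids=ids_sorted, threshold=threshold)


def associated_pathways(
    query: str, sim: pd.DataFrame, threshold: float = 0.5
) -> list[tuple[str, float]]:
    """Pathways with similarity ≥ threshold to *query*, descending, self excluded."""
    if query not in sim.index:
        raise KeyError(f"unknown query pathway {query!r}")
    row = sim.loc[query].drop(index=query)
    hits = row[row >= threshold].sort_values(ascending=False)
    return list(hits.items())


def dendrogram_newick(linkage: np.ndarray, ids: list[str]) -> str:
    """Newick export of a scipy linkage tree with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def render(node, parent_dist: float) -> str:
        length = parent_dist - node.dist  # leaf dist is 0
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.6g}"
        return f"({render(node.left, node.dist)},{render(node.right, node.dist)}):{length:.6g}"

    if tree.is_leaf():
        return f"{ids[tree.id]}:0;"
    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"
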