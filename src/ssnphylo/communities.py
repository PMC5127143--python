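"""Communities, recursive sub-network analysis, and the sigma-height dendrogram.

In this pipeline a *community* is a connected component with at least two
members of the threshold network; singleton components are *isolated
nodes*.  Sweeping sigma upward, each component eventually breaks apart;
recording every split produces the merge tree of the threshold family -- a
dendrogram whose internal-node heights are sigma values (percent), not
evolutionary distances.  Taxa that separate jointly at one threshold form
a single multifurcation: joint separation reflects comparable similarity
decay, not necessarily a clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .delta import (
    CriticalThreshold,
    DeltaCurve,
    delta_curve,
    detect_critical_thresholds,
)
from .networks import SigmaGrid, ThresholdNetwork, build_network
from .similarity import SimilarityMatrix

__all__ = [
    "CommunityPartition",
    "DendrogramNode",
    "SubAnalysis",
    "components_at",
    "partition_at",
    "build_dendrogram",
    "cut_dendrogram",
    "analyze_subcommunity",
    "to_newick",
]


@dataclass
class CommunityPartition:
    """Connected components at one threshold, split into communities
    (>= 2 members) and isolated nodes."""

    sigma: float
    communities: list[frozenset[str]]
    isolates: list[str]

    @property
    def all_sets(self) -> list[frozenset[str]]:
        """Every component, singletons included, as frozensets."""
        return self.communities + [frozenset([x]) for x in self.isolates]

    def n_components(self) -> int:
        return len(self.communities) + len(self.isolates)


@dataclass
class DendrogramNode:
    """Node of the threshold-family merge tree.

    ``split_sigma`` is the first grid threshold at which this node's member
    set is no longer connected; it is ``None`` for terminal nodes (single
    sequences, or clusters still connected at the top of the grid).
    """

    members: frozenset[str]
    split_sigma: float | None = None
    children: list["DendrogramNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterable["DendrogramNode"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class SubAnalysis:
    """Delta scan of one community treated as an independent network."""

    members: list[str]
    submatrix: SimilarityMatrix
    curve: DeltaCurve
    thresholds: list[CriticalThreshold]
    partitions: list[CommunityPartition]  # one per detected threshold


def _component_labels(net: ThresholdNetwork) -> np.ndarray:
    if net.n == 0:
        return np.zeros(0, dtype=int)
    _, comp = connected_components(csr_matrix(net.adjacency), directed=False)
    return comp


def components_at(net: ThresholdNetwork) -> CommunityPartition:
    """Connected components of the network, as communities plus isolates."""
    comp = _component_labels(net)
    groups: dict[int, list[str]] = {}
    for lab, c in zip(net.labels, comp):
        groups.setdefault(int(c), []).append(lab)
    communities = [frozenset(g) for g in groups.values() if len(g) >= 2]
    isolates = sorted(g[0] for g in groups.values() if len(g) == 1)
    communities.sort(key=lambda s: (-len(s), sorted(s)))
    return CommunityPartition(
        sigma=net.sigma, communities=communities, isolates=isolates
    )


def partition_at(S: SimilarityMatrix, sigma: float) -> CommunityPartition:
    """Convenience: components of the threshold network built at sigma."""
    return components_at(build_network(S, sigma))


def build_dendrogram(S: SimilarityMatrix, grid: SigmaGrid) -> DendrogramNode:
    """Merge tree of the threshold family over the full grid.

    Sweeping sigma upward, whenever a current component splits into two or
    more parts an internal node is created at that sigma with the parts as
    children.  Simultaneous splits produce one multifurcation.  The result
    coincides with single-linkage clustering on dissimilarity 100 - s,
    discretised to the grid.
    """
    root = DendrogramNode(members=frozenset(S.labels))
    active: dict[frozenset[str], DendrogramNode] = {root.members: root}
    for sigma in grid.values:
        parts = partition_at(S, sigma).all_sets
        # group this sigma's components under the active node containing them
        by_node: dict[frozenset[str], list[frozenset[str]]] = {}
        for part in parts:
            probe = next(iter(part))
            for mem in active:
                if probe in mem:
                    by_node.setdefault(mem, []).append(part)
                    break
        for mem, sub_parts in by_node.items():
            if len(sub_parts) <= 1:
                continue
            node = active.pop(mem)
            node.split_sigma = float(sigma)
            node.children = [DendrogramNode(members=p) for p in sub_parts]
            for child in node.children:
                active[child.members] = child
    return root


def cut_dendrogram(root: DendrogramNode, sigma: float) -> list[frozenset[str]]:
    """Component sets the dendrogram implies at threshold sigma."""
    if root.split_sigma is not None and root.split_sigma <= sigma:
        out: list[frozenset[str]] = []
        for child in root.children:
            out.extend(cut_dendrogram(child, sigma))
        return out
    return [root.members]


def analyze_subcommunity(
    S: SimilarityMatrix,
    members: Iterable[str],
    grid: SigmaGrid,
    min_prominence_frac: float = 0.1,
) -> SubAnalysis:
    """Treat a community as an independent network and rerun the delta scan.

    Restricts S to ``members``, recomputes the delta-curve, detects its
    critical thresholds and reports the component partition at each one.
    This is the recursion step that peels sub-communities out of a
    community (e.g. primates out of mammals).
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("sub-community analysis needs at least 2 members")
    sub = S.submatrix(members)
    curve = delta_curve(sub, grid)
    thresholds = detect_critical_thresholds(curve, min_prominence_frac)
    partitions = [partition_at(sub, t.sigma_cst) for t in thresholds]
    return SubAnalysis(
        members=sub.labels,
        submatrix=sub,
        curve=curve,
        thresholds=thresholds,
        partitions=partitions,
    )


def _quote_label(label: str) -> str:
    if any(c in label for c in " \t()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick_node(
    node: DendrogramNode, parent_height: float, top: float
) -> str:
    if node.is_leaf:
        if len(node.members) == 1:
            (label,) = node.members
            return f"{_quote_label(label)}:{top - parent_height:.10g}"
        # unresolved cluster still connected at the top of the grid:
        # emit a polytomy of zero-length leaves at the grid top
        inner = ",".join(
            f"{_quote_label(lab)}:0" for lab in sorted(node.members)
        )
        return f"({inner}):{top - parent_height:.10g}"
    inner = ",".join(
        _newick_node(child, node.split_sigma, top)
        for child in sorted(node.children, key=lambda c: sorted(c.members))
    )
    return f"({inner}):{node.split_sigma - parent_height:.10g}"


def to_newick(root: DendrogramNode, height_mode: str = "similarity") -> str:
    """Serialise the dendrogram as Newick.

    ``similarity`` (default): ultrametric branch lengths on the percent
    scale -- a child's branch is ``child.split_sigma - parent.split_sigma``
    and every leaf extends to 100, so root-to-leaf path lengths are equal.
    ``topology``: no branch lengths.
    """
    if height_mode not in {"similarity", "topology"}:
        raise ValueError(f"unknown height_mode {height_mode!r}")
    if height_mode == "topology":

        def fmt(node: DendrogramNode) -> str:
            if node.is_leaf:
                if len(node.members) == 1:
                    return _quote_label(next(iter(node.members)))
                return "(" + ",".join(
                    _quote_label(x) for x in sorted(node.members)
                ) + ")"
            return "(" + ",".join(
                fmt(c) for c in sorted(node.children, key=lambda c: sorted(c.members))
            ) + ")"

        return fmt(root) + ";"
    top = 100.0
    if root.is_leaf and len(root.members) == 1:
        (label,) = root.members
        return f"{_quote_label(label)}:0;"
    base = root.split_sigma if root.split_sigma is not None else top
    return _newick_node(root, base, top) + ";"
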