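"""One-parameter family of threshold networks M(sigma).

A similarity threshold sigma (percent) acts as the family's control
parameter: nodes i and j are joined iff their pair is valid and
``s_ij >= sigma``.  Raising sigma only removes edges, so the family is
nested and components can only break apart as sigma grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .similarity import SimilarityMatrix

__all__ = ["SigmaGrid", "ThresholdNetwork", "build_network", "network_family",
           "write_edgelist"]


@dataclass(frozen=True)
class SigmaGrid:
    """Evenly spaced thresholds; the step doubles as the delta-scan's
    resolution.  The default integer-percent grid 0..100 matches how
    critical thresholds are conventionally reported."""

    start: float = 0.0
    stop: float = 100.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.stop <= 101):
            raise ValueError(
                f"require 0 <= start < stop <= 101, got [{self.start}, {self.stop}]"
            )
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def values(self) -> np.ndarray:
        return np.arange(self.start, self.stop + 0.5 * self.step, self.step)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ThresholdNetwork:
    """Undirected binary graph at one threshold: symmetric 0/1 adjacency,
    zero diagonal."""

    sigma: float
    labels: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)

    @property
    def n(self) -> int:
        return len(self.labels)

    def edges(self) -> list[tuple[str, str]]:
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return [(self.labels[i], self.labels[j]) for i, j in zip(ii, jj)]

    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def build_network(S: SimilarityMatrix, sigma: float) -> ThresholdNetwork:
    """Threshold S at sigma: edge iff the pair is valid and s_ij >= sigma.

    The boundary s_ij == sigma keeps its edge (the complementary rule is
    "no edge iff s_ij < sigma").
    """
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    adj = (S.effective() >= sigma) & S.valid
    np.fill_diagonal(adj, False)
    return ThresholdNetwork(sigma=float(sigma), labels=list(S.labels), adjacency=adj)


def network_family(S: SimilarityMatrix, grid: SigmaGrid) -> list[ThresholdNetwork]:
    """One network per grid point, ascending in sigma."""
    return [build_network(S, sigma) for sigma in grid.values]


def write_edgelist(net: ThresholdNetwork, path: str | Path) -> None:
    """Two-column TSV edge list for external visualisation tools."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for a, b in net.edges():
            fh.write(f"{a}\t{b}\n")
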