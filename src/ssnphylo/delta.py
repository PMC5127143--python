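"""Delta-distance between threshold networks and critical-threshold detection.

Two networks on the same node set are compared through their *neighborhood
matrices* -- all-pairs unweighted geodesic distances, with disconnected
pairs assigned a finite cap (``n`` by default, one more than any realisable
path length).  The delta-distance is the mean absolute entrywise difference
over ordered off-diagonal pairs:

    delta(A, B) = (1 / (n (n - 1))) * sum_{i != j} |D_A(i, j) - D_B(i, j)|

Scanning delta(sigma, sigma + step) along the threshold grid produces a
curve whose peaks mark the critical thresholds sigma_cst at which the
network's large-scale structure reorganises -- typically a community
breaking off.  Because the change happens between the two grid points, a
peak of the pair (sigma, sigma + step) is reported as
``sigma_cst = sigma + step``: the first threshold at which the new
structure exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .networks import SigmaGrid, ThresholdNetwork, network_family
from .similarity import SimilarityMatrix

__all__ = [
    "NeighborhoodMatrix",
    "DeltaCurve",
    "CriticalThreshold",
    "neighborhood_matrix",
    "delta",
    "delta_curve",
    "detect_critical_thresholds",
    "write_delta_tsv",
    "plot_delta_curve",
]


@dataclass
class NeighborhoodMatrix:
    """Geodesic distance matrix of one network; ``cap`` replaces infinity."""

    entries: np.ndarray
    cap: int


@dataclass
class DeltaCurve:
    """delta(sigma, sigma + step) sampled along a grid.

    ``sigmas`` holds the lower threshold of each compared pair, so the
    curve has one point fewer than the grid.
    """

    sigmas: np.ndarray
    deltas: np.ndarray
    step: float

    def __post_init__(self) -> None:
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.deltas = np.asarray(self.deltas, dtype=float)
        if self.sigmas.shape != self.deltas.shape:
            raise ValueError("sigma and delta arrays differ in length")
        if (self.deltas < 0).any():
            raise ValueError("delta values must be non-negative")


@dataclass(frozen=True)
class CriticalThreshold:
    """A peak of the delta-curve: the threshold where structure changes.

    ``sigma_cst`` is the upper end of the peak's grid interval (the first
    sigma at which the rearranged network exists); ``rank`` orders peaks by
    height, 1 being the dominant one.
    """

    sigma_cst: float
    peak_height: float
    rank: int


def _geodesics(adjacency: np.ndarray, cap: int) -> np.ndarray:
    if adjacency.shape[0] == 0:
        return np.zeros((0, 0))
    dist = shortest_path(csr_matrix(adjacency), method="D", unweighted=True)
    dist[np.isinf(dist)] = cap
    return dist


def neighborhood_matrix(
    net: ThresholdNetwork, cap: int | None = None
) -> NeighborhoodMatrix:
    """All-pairs shortest-path matrix; disconnected pairs get ``cap``
    (default n)."""
    cap = net.n if cap is None else cap
    return NeighborhoodMatrix(entries=_geodesics(net.adjacency, cap), cap=cap)


def delta(
    net_a: ThresholdNetwork, net_b: ThresholdNetwork, cap: int | None = None
) -> float:
    """Mean absolute difference of the two neighborhood matrices."""
    if net_a.labels != net_b.labels:
        raise ValueError("networks are defined on different node sets")
    n = net_a.n
    if n < 2:
        return 0.0
    da = neighborhood_matrix(net_a, cap).entries
    db = neighborhood_matrix(net_b, cap).entries
    return float(np.abs(da - db).sum() / (n * (n - 1)))


def delta_curve(
    S: SimilarityMatrix, grid: SigmaGrid, cap: int | None = None
) -> DeltaCurve:
    """delta between networks at successive grid thresholds."""
    nets = network_family(S, grid)
    cap_val = S.n if cap is None else cap
    dists = [_geodesics(net.adjacency, cap_val) for net in nets]
    n = S.n
    norm = n * (n - 1) if n > 1 else 1
    deltas = [
        float(np.abs(dists[k] - dists[k + 1]).sum() / norm)
        for k in range(len(nets) - 1)
    ]
    return DeltaCurve(
        sigmas=grid.values[:-1], deltas=np.array(deltas), step=grid.step
    )


def detect_critical_thresholds(
    curve: DeltaCurve, min_prominence_frac: float = 0.1
) -> list[CriticalThreshold]:
    """Local maxima of the delta-curve at least ``min_prominence_frac`` of
    its global maximum.

    Returns thresholds sorted by sigma; ``rank`` 1 is the global maximum,
    which is always included.  A flat zero curve yields an empty list.
    Plateaus of equal height count once, at their first grid point.
    """
    d = curve.deltas
    if len(d) == 0 or d.max() <= 0:
        return []
    floor = min_prominence_frac * d.max()
    candidates: list[int] = []
    for i in range(len(d)):
        if d[i] <= 0 or d[i] < floor:
            continue
        left_ok = i == 0 or d[i] >= d[i - 1]
        right_ok = i == len(d) - 1 or d[i] >= d[i + 1]
        if left_ok and right_ok:
            if candidates and d[candidates[-1]] == d[i] and all(
                d[k] == d[i] for k in range(candidates[-1], i)
            ):
                continue  # same plateau
            candidates.append(i)
    order = sorted(candidates, key=lambda i: (-d[i], curve.sigmas[i]))
    ranks = {i: r + 1 for r, i in enumerate(order)}
    return [
        CriticalThreshold(
            sigma_cst=float(curve.sigmas[i] + curve.step),
            peak_height=float(d[i]),
            rank=ranks[i],
        )
        for i in sorted(candidates)
    ]


def write_delta_tsv(curve: DeltaCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sigma\tdelta\n")
        for s, d in zip(curve.sigmas, curve.deltas):
            fh.write(f"{s:.10g}\t{d:.10g}\n")


def plot_delta_curve(curve: DeltaCurve, path: str | Path, title: str = "") -> None:
    """Simple line plot of the delta-curve (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.plot(curve.sigmas, curve.deltas, lw=1.2)
    ax.set_xlabel(r"similarity threshold $\sigma$ (%)")
    ax.set_ylabel(r"$\delta(\sigma, \sigma + \Delta\sigma)$")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
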