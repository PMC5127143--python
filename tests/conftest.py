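import numpy as np
import pytest

from ssnphylo.similarity import SimilarityMatrix


def random_similarity(rng: np.random.Generator, n: int,
                      invalid_frac: float = 0.0) -> SimilarityMatrix:
    """Random symmetric percent-similarity matrix for property tests."""
    vals = rng.uniform(0, 100, size=(n, n))
    vals = np.triu(vals, 1)
    vals = vals + vals.T
    valid = np.ones((n, n), dtype=bool)
    if invalid_frac > 0:
        mask = rng.random((n, n)) < invalid_frac
        mask = np.triu(mask, 1)
        mask = mask | mask.T
        valid &= ~mask
        vals = np.where(valid, vals, 0.0)
    np.fill_diagonal(vals, 100.0)
    labels = [f"t{i}" for i in range(n)]
    return SimilarityMatrix(labels=labels, values=vals, valid=valid)


def random_adjacency(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    a = rng.random((n, n)) < p
    a = np.triu(a, 1)
    a = a | a.T
    return a


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)

def floyd_warshall_oracle(adjacency: np.ndarray, cap: int) -> np.ndarray:
    """Brute-force all-pairs shortest paths; disconnected pairs -> cap."""
    n = adjacency.shape[0]
    INF = float("inf")
    d = [[0 if i == j else (1 if adjacency[i][j] else INF)
          for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    out = np.array([[cap if x == INF else x for x in row] for row in d],
                   dtype=float)
    return out


def union_find_components(adjacency: np.ndarray,
                          labels: list[str]) -> set[frozenset[str]]:
    """Connected components by a plain union-find."""
    parent = list(range(len(labels)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if adjacency[i][j]:
                parent[find(i)] = find(j)
    groups: dict[int, set[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(labels[i])
    return {frozenset(g) for g in groups.values()}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231117)
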