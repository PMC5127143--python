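"""Synthetic inputs with planted group structure.

Two generators cover the two entry points of the pipeline:

* :func:`planted_block_similarity` writes the block structure directly into
  a similarity matrix -- high within-group, low between-group percent
  similarity plus optional Gaussian noise.  This is the idealised shape a
  family of orthologous proteins leaves in S.
* :func:`simulate_protein_family` generates actual amino-acid sequences: a
  random root, one ancestor per group obtained by a Poisson number of
  uniform substitutions, and leaves obtained the same way from their group
  ancestor.  Feeding these through the alignment stage exercises the whole
  pipeline, including the E-value filter.

Both are deterministic given their seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .similarity import SequenceRecord, SimilarityMatrix

__all__ = [
    "PlantedDesign",
    "FamilyDesign",
    "OverlapWarning",
    "planted_block_similarity",
    "simulate_protein_family",
    "write_design_json",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


class OverlapWarning(UserWarning):
    """Within- and between-group similarity bands overlap under the noise."""


@dataclass(frozen=True)
class PlantedDesign:
    """Block-structured similarity matrix specification.

    ``s_between`` may be a single level or a symmetric K x K matrix of
    between-group levels (its diagonal is ignored).  Noise is Gaussian with
    standard deviation ``noise_sd`` (percent), applied symmetrically.
    """

    group_sizes: tuple[int, ...]
    s_within: float = 90.0
    s_between: float | tuple[tuple[float, ...], ...] = 20.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.group_sizes or any(g < 1 for g in self.group_sizes):
            raise ValueError("group sizes must all be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        bm = self.between_matrix()
        off = bm[~np.eye(bm.shape[0], dtype=bool)]
        if off.size and off.max() >= self.s_within:
            raise ValueError("s_between must be below s_within")

    def between_matrix(self) -> np.ndarray:
        k = len(self.group_sizes)
        if np.isscalar(self.s_between):
            out = np.full((k, k), float(self.s_between))
        else:
            out = np.asarray(self.s_between, dtype=float)
            if out.shape != (k, k):
                raise ValueError("between-group matrix must be K x K")
            if not np.allclose(out, out.T):
                raise ValueError("between-group matrix must be symmetric")
        np.fill_diagonal(out, self.s_within)
        return out


@dataclass(frozen=True)
class FamilyDesign:
    """Planted-group protein family specification.

    ``d_between`` / ``d_within`` are expected substitutions per site on the
    root-to-ancestor and ancestor-to-leaf branches respectively.
    """

    n_groups: int = 3
    seqs_per_group: int = 4
    seq_length: int = 250
    d_between: float = 1.5
    d_within: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.d_within < self.d_between <= 3):
            raise ValueError("require 0 <= d_within < d_between <= 3")
        if self.seq_length < 50:
            raise ValueError("seq_length must be >= 50")
        if self.n_groups < 1 or self.seqs_per_group < 1:
            raise ValueError("need at least one group and one sequence")

    def group_members(self) -> list[list[str]]:
        """Sequence ids per planted group, matching the generator output."""
        return [
            [f"G{g + 1}S{s + 1}" for s in range(self.seqs_per_group)]
            for g in range(self.n_groups)
        ]


def planted_block_similarity(design: PlantedDesign) -> SimilarityMatrix:
    """Block similarity matrix with additive truncated-Gaussian noise.

    All pairs are marked valid.  Noise is drawn on the upper triangle and
    mirrored, then values are clipped to [0, 100] so matrix invariants hold
    regardless of the noise level.  Warns if the +/-3 sd noise bands of the
    within and the highest between level overlap.
    """
    rng = np.random.default_rng(design.seed)
    sizes = design.group_sizes
    n = int(sum(sizes))
    group_of = np.repeat(np.arange(len(sizes)), sizes)
    between = design.between_matrix()
    values = between[np.ix_(group_of, group_of)].copy()
    if design.noise_sd > 0:
        off = np.asarray(between)[~np.eye(len(sizes), dtype=bool)]
        if off.size and off.max() + 3 * design.noise_sd > design.s_within - 3 * design.noise_sd:
            warnings.warn(
                "noise bands of within- and between-group similarity overlap; "
                "planted structure may not be recoverable",
                OverlapWarning,
                stacklevel=2,
            )
        noise = rng.normal(0.0, design.noise_sd, size=(n, n))
        upper = np.triu(noise, k=1)
        values = values + upper + upper.T
    values = np.clip(values, 0.0, 100.0)
    np.fill_diagonal(values, 100.0)
    labels = [
        f"g{g + 1}_s{s + 1}"
        for g, size in enumerate(sizes)
        for s in range(size)
    ]
    return SimilarityMatrix(
        labels=labels, values=values, valid=np.ones((n, n), dtype=bool)
    )


def _mutate(residues: np.ndarray, expected_hits: float, rng) -> np.ndarray:
    """Apply a Poisson number of uniform substitutions (sites may repeat)."""
    out = residues.copy()
    n_hits = rng.poisson(expected_hits)
    sites = rng.integers(0, len(out), size=n_hits)
    for site in sites:
        current = out[site]
        choices = AMINO_ACIDS[AMINO_ACIDS != current]
        out[site] = rng.choice(choices)
    return out


def simulate_protein_family(design: FamilyDesign) -> list[SequenceRecord]:
    """Planted-group sequences from a star-of-stars substitution process."""
    rng = np.random.default_rng(design.seed)
    L = design.seq_length
    root = rng.choice(AMINO_ACIDS, size=L)
    records: list[SequenceRecord] = []
    for g in range(design.n_groups):
        ancestor = _mutate(root, design.d_between * L, rng)
        for s in range(design.seqs_per_group):
            leaf = _mutate(ancestor, design.d_within * L, rng)
            records.append(
                SequenceRecord(
                    id=f"G{g + 1}S{s + 1}",
                    label=f"group {g + 1} sequence {s + 1}",
                    residues="".join(leaf),
                )
            )
    return records


def write_design_json(design: PlantedDesign | FamilyDesign, path: str | Path) -> None:
    """Serialise a design next to its generated data for provenance."""
    with open(path, "w") as fh:
        json.dump(
            {"design_type": type(design).__name__, **asdict(design)},
            fh,
            indent=2,
            default=list,
        )
        fh.write("\n")
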