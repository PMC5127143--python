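"""Pairwise percent-similarity matrices from local protein alignment.

The pipeline's only biological input is a symmetric matrix ``S`` of percent
similarities ``0 <= s_ij <= 100`` between protein sequences.  Each entry is
the mean of the two directed local-alignment scores for the ordered pairs
(i, j) and (j, i); a pair is *valid* only if the better of its two E-values
is at or below a cutoff (1.0 by default).  Invalid pairs are treated as
similarity 0 by every downstream stage, so they never produce an edge.

Two scoring engines are available:

``internal``
    Smith-Waterman local alignment (BLOSUM62, gap open 11 / extend 1 --
    blastp's defaults) via :class:`Bio.Align.PairwiseAligner`.  The percent
    score is, per configuration, the normalised bit score (default),
    percent positives or percent identity of the best local alignment.
    E-values come from the Karlin-Altschul formula with the standard
    gapped BLOSUM62 parameters.

``blastp``
    Delegates scoring to a local ``blastp`` binary when one is installed.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "SequenceRecord",
    "ScoringParams",
    "RawScores",
    "SimilarityMatrix",
    "SequenceError",
    "MatrixFormatError",
    "read_fasta",
    "write_fasta",
    "pairwise_scores",
    "symmetrize",
    "compute_similarity",
    "read_similarity_tsv",
    "write_similarity_tsv",
]

# 20 canonical residues plus the ambiguity codes BLOSUM62 carries.
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZU*")

#: Karlin-Altschul (lambda, K) for gapped BLOSUM62 with open 11 / extend 1,
#: the parameter set blastp reports for its default scoring scheme.
KARLIN_ALTSCHUL: dict[tuple[str, float, float], tuple[float, float]] = {
    ("BLOSUM62", 11.0, 1.0): (0.267, 0.041),
}


class SequenceError(ValueError):
    """Raised for empty sequences, bad residues or duplicate identifiers."""


class MatrixFormatError(ValueError):
    """Raised when a similarity matrix violates its invariants on I/O."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence: stable ``id``, display ``label``, residues."""

    id: str
    label: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} is empty")
        bad = set(self.residues.upper()) - AMINO_ALPHABET
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains non-amino-acid characters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ScoringParams:
    """How directed similarity scores and E-values are produced.

    metric
        ``bitscore`` (default: the pair's bit score normalised by the
        larger self bit score, times 100), ``positives`` (BLAST's
        similarity column: positive-scoring columns over alignment
        length) or ``identity`` (identical columns over alignment
        length).  The normalised bit score is the default because the
        per-alignment percentages are computed over the best local
        alignment only: for highly divergent pairs a short
        perfect-scoring segment can report 100% similarity between
        unrelated sequences, which breaks the premise that s ~ 100 means
        near-identity.  Length-normalised scores are the standard remedy
        in sequence-similarity-network practice.
    engine
        ``internal`` (Smith-Waterman in-process) or ``blastp``
        (external binary; requires blastp on PATH).
    """

    metric: str = "bitscore"
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    engine: str = "internal"

    def __post_init__(self) -> None:
        if self.metric not in {"positives", "identity", "bitscore"}:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.engine not in {"internal", "blastp"}:
            raise ValueError(f"unknown engine {self.engine!r}")

    @property
    def karlin_altschul(self) -> tuple[float, float]:
        key = (self.matrix, float(self.gap_open), float(self.gap_extend))
        try:
            return KARLIN_ALTSCHUL[key]
        except KeyError:
            raise ValueError(
                f"no Karlin-Altschul parameters tabulated for {key}; "
                "use the blastp engine for this scoring scheme"
            ) from None


@dataclass
class RawScores:
    """Directed scores: percent similarity and E-value for every (i, j)."""

    labels: list[str]
    score: np.ndarray   # (n, n) float, percent
    evalue: np.ndarray  # (n, n) float

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class SimilarityMatrix:
    """Symmetric percent-similarity matrix with a validity mask.

    ``values[i, j]`` is the mean of the two directed scores; ``valid[i, j]``
    is False when both directed E-values exceeded the cutoff.  Invalid
    entries take effective similarity 0 for all edge decisions.
    """

    labels: list[str]
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.labels)
        if self.values.shape != (n, n) or self.valid.shape != (n, n):
            raise MatrixFormatError("matrix shape does not match label count")
        if len(set(self.labels)) != n:
            raise MatrixFormatError("duplicate labels in similarity matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise MatrixFormatError("similarity values are not symmetric")
        if not np.array_equal(self.valid, self.valid.T):
            raise MatrixFormatError("validity mask is not symmetric")
        if self.values.min() < -1e-9 or self.values.max() > 100 + 1e-9:
            raise MatrixFormatError("similarities outside [0, 100]")
        np.fill_diagonal(self.values, 100.0)
        np.fill_diagonal(self.valid, True)

    @property
    def n(self) -> int:
        return len(self.labels)

    def effective(self) -> np.ndarray:
        """Similarities with invalid pairs zeroed -- what edges are cut on."""
        return np.where(self.valid, self.values, 0.0)

    def submatrix(self, members: list[str] | set[str]) -> "SimilarityMatrix":
        """Restriction of S to ``members``, preserving this matrix's order."""
        members = set(members)
        missing = members - set(self.labels)
        if missing:
            raise KeyError(f"labels not in matrix: {sorted(missing)}")
        idx = [i for i, lab in enumerate(self.labels) if lab in members]
        sub = np.ix_(idx, idx)
        return SimilarityMatrix(
            labels=[self.labels[i] for i in idx],
            values=self.values[sub].copy(),
            valid=self.valid[sub].copy(),
        )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read protein sequences; the description line is "id taxon name"."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        label = rec.description[len(rec.id):].strip() or rec.id
        records.append(
            SequenceRecord(id=rec.id, label=label, residues=str(rec.seq).upper())
        )
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if rec.label == rec.id else f"{rec.id} {rec.label}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i : i + 60] + "\n")


def _make_aligner(params: ScoringParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    # BLAST charges open + k*extend for a k-residue gap; PairwiseAligner
    # charges open_gap_score once plus extend for each further position.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _alignment_stats(
    alignment, seq_a: str, seq_b: str, matrix
) -> tuple[int, int, int]:
    """(identities, positives, alignment_length) of one local alignment."""
    identities = positives = length = 0
    prev_a = prev_b = None
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        if prev_a is not None:
            length += (a_start - prev_a) + (b_start - prev_b)  # gap columns
        for x, y in zip(seq_a[a_start:a_end], seq_b[b_start:b_end]):
            length += 1
            if x == y:
                identities += 1
            if matrix[x, y] > 0:
                positives += 1
        prev_a, prev_b = a_end, b_end
    return identities, positives, length


def _evalue(raw_score: float, m: int, n: int, lam: float, K: float) -> float:
    return K * m * n * math.exp(-lam * raw_score)


def _bit_score(raw_score: float, lam: float, K: float) -> float:
    return (lam * raw_score - math.log(K)) / math.log(2.0)


def _internal_scores(seqs: list[SequenceRecord], params: ScoringParams) -> RawScores:
    aligner = _make_aligner(params)
    matrix = aligner.substitution_matrix
    lam, K = params.karlin_altschul
    n = len(seqs)
    score = np.zeros((n, n))
    evalue = np.zeros((n, n))
    self_bits = [
        _bit_score(aligner.score(s.residues, s.residues), lam, K) for s in seqs
    ]
    for i in range(n):
        score[i, i] = 100.0
        for j in range(i + 1, n):
            a, b = seqs[i].residues, seqs[j].residues
            best = aligner.align(a, b)[0]
            identities, positives, length = _alignment_stats(best, a, b, matrix)
            if params.metric == "identity":
                pct = 100.0 * identities / length if length else 0.0
            elif params.metric == "positives":
                pct = 100.0 * positives / length if length else 0.0
            else:  # bitscore
                bits = _bit_score(best.score, lam, K)
                pct = 100.0 * bits / max(self_bits[i], self_bits[j])
            pct = float(np.clip(pct, 0.0, 100.0))
            e = _evalue(best.score, len(a), len(b), lam, K)
            # Smith-Waterman is symmetric: one alignment serves both
            # directed comparisons.
            score[i, j] = score[j, i] = pct
            evalue[i, j] = evalue[j, i] = e
    return RawScores(labels=[s.id for s in seqs], score=score, evalue=evalue)


def _blastp_scores(seqs: list[SequenceRecord], params: ScoringParams) -> RawScores:
    if shutil.which("blastp") is None or shutil.which("makeblastdb") is None:
        raise RuntimeError("blastp engine requested but blastp is not on PATH")
    n = len(seqs)
    score = np.zeros((n, n))
    evalue = np.full((n, n), np.inf)
    index = {s.id: k for k, s in enumerate(seqs)}
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "seqs.fasta"
        write_fasta(seqs, fasta)
        subprocess.run(
            ["makeblastdb", "-in", str(fasta), "-dbtype", "prot"],
            check=True,
            capture_output=True,
        )
        out = subprocess.run(
            [
                "blastp",
                "-query", str(fasta),
                "-db", str(fasta),
                "-evalue", "1000",
                "-gapopen", str(int(params.gap_open)),
                "-gapextend", str(int(params.gap_extend)),
                "-matrix", params.matrix,
                "-outfmt", "6 qseqid sseqid pident ppos bitscore evalue",
            ],
            check=True,
            capture_output=True,
            text=True,
        )
    for line in out.stdout.splitlines():
        q, s, pident, ppos, bits, ev = line.split("\t")
        i, j = index[q], index[s]
        ev = float(ev)
        if ev < evalue[i, j]:  # keep the top HSP only
            evalue[i, j] = ev
            if params.metric == "identity":
                score[i, j] = float(pident)
            elif params.metric == "positives":
                score[i, j] = float(ppos)
            else:
                score[i, j] = float(bits)
    if params.metric == "bitscore":
        selfbits = np.diag(score).copy()
        denom = np.maximum.outer(selfbits, selfbits)
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.clip(100.0 * score / denom, 0.0, 100.0)
    np.fill_diagonal(score, 100.0)
    np.fill_diagonal(evalue, 0.0)
    return RawScores(labels=[s.id for s in seqs], score=score, evalue=evalue)


def pairwise_scores(
    seqs: list[SequenceRecord], params: ScoringParams | None = None
) -> RawScores:
    """Directed percent-similarity scores and E-values for all ordered pairs.

    Self comparisons score 100 with E-value 0.  Raises
    :class:`SequenceError` for fewer than two sequences or duplicate ids.
    """
    params = params or ScoringParams()
    if len(seqs) < 2:
        raise SequenceError("need at least two sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise SequenceError("duplicate sequence ids")
    if params.engine == "blastp":
        return _blastp_scores(seqs, params)
    return _internal_scores(seqs, params)


def symmetrize(raw: RawScores, evalue_cutoff: float = 1.0) -> SimilarityMatrix:
    """Mean of the two directed scores; valid iff either E-value <= cutoff.

    Invalid pairs are stored as 0 outright -- downstream stages only ever
    use S to decide edges, and an invalid pair never yields one.
    """
    if raw.score.shape[0] != raw.score.shape[1]:
        raise MatrixFormatError("raw score matrix is not square")
    values = (raw.score + raw.score.T) / 2.0
    valid = np.minimum(raw.evalue, raw.evalue.T) <= evalue_cutoff
    values = np.where(valid, values, 0.0)
    return SimilarityMatrix(labels=list(raw.labels), values=values, valid=valid)


def compute_similarity(
    seqs: list[SequenceRecord],
    params: ScoringParams | None = None,
    evalue_cutoff: float = 1.0,
) -> SimilarityMatrix:
    """Full similarity stage: align all pairs, then symmetrize and filter."""
    return symmetrize(pairwise_scores(seqs, params), evalue_cutoff)


_INVALID_TOKEN = "NA"


def write_similarity_tsv(S: SimilarityMatrix, path: str | Path) -> None:
    """Tab-separated matrix; invalid pairs written as the sentinel ``NA``."""
    with open(path, "w") as fh:
        fh.write("\t".join([""] + S.labels) + "\n")
        for i, lab in enumerate(S.labels):
            cells = [
                f"{S.values[i, j]:.10g}" if S.valid[i, j] else _INVALID_TOKEN
                for j in range(S.n)
            ]
            fh.write("\t".join([lab] + cells) + "\n")


def read_similarity_tsv(path: str | Path) -> SimilarityMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise MatrixFormatError(f"{path}: empty similarity file")
    header = lines[0].split("\t")
    labels = header[1:]
    if not labels or any(not lab for lab in labels):
        raise MatrixFormatError(f"{path}: missing labels in header")
    n = len(labels)
    if len(lines) != n + 1:
        raise MatrixFormatError(f"{path}: expected {n} data rows")
    values = np.zeros((n, n))
    valid = np.ones((n, n), dtype=bool)
    for i, line in enumerate(lines[1:]):
        cells = line.split("\t")
        if len(cells) != n + 1:
            raise MatrixFormatError(f"{path}: row {i} has wrong width")
        if cells[0] != labels[i]:
            raise MatrixFormatError(
                f"{path}: row label {cells[0]!r} does not match header order"
            )
        for j, cell in enumerate(cells[1:]):
            if cell == _INVALID_TOKEN:
                valid[i, j] = False
                values[i, j] = 0.0
            else:
                values[i, j] = float(cell)
    if not np.allclose(values, values.T, atol=1e-9):
        raise MatrixFormatError(f"{path}: matrix is asymmetric")
    return SimilarityMatrix(labels=labels, values=values, valid=valid)
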