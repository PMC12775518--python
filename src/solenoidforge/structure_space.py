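"""Structure-space analytics over all-vs-all TM-score tables.

TM-scores from an external structural aligner (TM-align mode) are
ingested as a symmetric similarity matrix, converted to distances
(``d = 1 - TM``), embedded into 2D with metric MDS, and clustered with a
greedy representative scheme at a TM threshold.  Novelty is assessed
from each design's best match against reference sets: a best TM-score
below 0.5 marks a structurally novel fold, a best-hit E-value above
1e-5 marks a sequence without significant natural similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.manifold import smacof

from .errors import InvalidInputError

STRUCTURE_NOVELTY_TM = 0.5
SEQUENCE_NOVELTY_EVALUE = 1e-5
DEFAULT_CLUSTER_TM = 0.7


@dataclass(frozen=True)
class StructureSimilarityMatrix:
    """Symmetric all-vs-all TM-score matrix with unit diagonal."""

    ids: tuple[str, ...]
    tm: np.ndarray

    def __post_init__(self) -> None:
        tm = np.asarray(self.tm, dtype=float)
        n = len(self.ids)
        if tm.shape != (n, n):
            raise InvalidInputError(f"matrix shape {tm.shape} does not match {n} ids")
        if np.any((tm < 0) | (tm > 1)):
            raise InvalidInputError("TM-scores must lie in [0,1]")
        if not np.allclose(tm, tm.T, atol=1e-9):
            raise InvalidInputError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(tm), 1.0, atol=1e-9):
            raise InvalidInputError("diagonal must be 1 (self-similarity)")
        object.__setattr__(self, "tm", tm)
        object.__setattr__(self, "ids", tuple(self.ids))

    def subset(self, keep: Sequence[str]) -> "StructureSimilarityMatrix":
        idx = [self.ids.index(i) for i in keep]
        return StructureSimilarityMatrix(
            ids=tuple(keep), tm=self.tm[np.ix_(idx, idx)]
        )


@dataclass(frozen=True)
class Embedding2D:
    ids: tuple[str, ...]
    coords: np.ndarray  # (n, 2)
    stress: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "x": self.coords[:, 0], "y": self.coords[:, 1]}
        )


def read_tm_table(path) -> StructureSimilarityMatrix:
    """Read a tab-separated all-vs-all alignment table (query, target, TM).

    Asymmetric tables (query- vs target-length normalisation) are
    symmetrised by taking the larger of the two directions; the diagonal
    is forced to 1 and missing pairs default to 0.
    """
    table = pd.read_csv(
        path, sep="\t", header=None, names=["query", "target", "tm"], comment="#"
    )
    ids = sorted(set(table["query"]) | set(table["target"]))
    index = {name: i for i, name in enumerate(ids)}
    tm = np.zeros((len(ids), len(ids)))
    for q, t, s in table.itertuples(index=False):
        i, j = index[q], index[t]
        tm[i, j] = max(tm[i, j], float(s))
    tm = np.maximum(tm, tm.T)
    np.fill_diagonal(tm, 1.0)
    return StructureSimilarityMatrix(ids=tuple(ids), tm=tm)


def tm_to_distance(matrix: StructureSimilarityMatrix) -> np.ndarray:
    """Distance matrix ``d = 1 - TM``: zero diagonal, symmetric."""
    return 1.0 - matrix.tm


def mds_embed(distances: np.ndarray, seed: int = 0, ids: Sequence[str] | None = None) -> Embedding2D:
    """Metric MDS into 2D by SMACOF stress majorisation.

    Initialised from the classical (Torgerson) MDS solution, so
    configurations that are exactly embeddable in the plane are
    recovered at (numerically) zero stress; SMACOF then refines
    non-Euclidean inputs.  Seeded and deterministic.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InvalidInputError(f"distance matrix must be square, got {d.shape}")
    if np.any(d < 0):
        raise InvalidInputError("distances must be non-negative")
    if not np.allclose(d, d.T, atol=1e-9):
        raise InvalidInputError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-9):
        raise InvalidInputError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    if ids is None:
        ids = tuple(str(i) for i in range(n))
    if n == 1:
        return Embedding2D(tuple(ids), np.zeros((1, 2)), 0.0)
    # Classical MDS: double-centre the squared distances, take the top
    # two eigenvectors scaled by sqrt(eigenvalue).
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:2]
    init = evecs[:, order] * np.sqrt(np.maximum(evals[order], 0.0))
    coords, stress = smacof(
        d,
        n_components=2,
        init=init,
        n_init=1,
        max_iter=500,
        eps=1e-12,
        random_state=seed,
        normalized_stress=False,
    )
    return Embedding2D(tuple(ids), coords, float(stress))


def greedy_cluster(
    matrix: StructureSimilarityMatrix, threshold: float = DEFAULT_CLUSTER_TM
) -> dict[str, str]:
    """Greedy representative clustering at a TM-score threshold.

    Repeatedly picks the unassigned structure with the most unassigned
    neighbours at ``tm >= threshold`` as a cluster representative and
    assigns all such neighbours to it.  Returns a mapping
    ``id -> representative id``; every id is assigned exactly once and
    sits at ``tm >= threshold`` from its representative (representatives
    map to themselves).  Ties on neighbour count break toward the
    earlier id in the matrix ordering, keeping the partition
    deterministic.
    """
    n = len(matrix.ids)
    adjacent = matrix.tm >= threshold
    np.fill_diagonal(adjacent, True)
    unassigned = np.ones(n, dtype=bool)
    assignment: dict[str, str] = {}
    while unassigned.any():
        counts = (adjacent & unassigned).sum(axis=1)
        counts[~unassigned] = -1
        rep = int(np.argmax(counts))
        members = np.where(adjacent[rep] & unassigned)[0]
        for m in members:
            assignment[matrix.ids[m]] = matrix.ids[rep]
        unassigned[members] = False
    return assignment


def novelty_fractions(
    best_match_scores: Sequence[float], kind: str
) -> tuple[float, float]:
    """Fraction of designs novel relative to a reference set, plus median.

    ``kind='structure'``: scores are best-match TM-scores; novel means
    strictly below 0.5 (distinct fold).  ``kind='sequence'``: scores are
    best-hit E-values; novel means strictly above 1e-5 (no significant
    sequence similarity).
    """
    scores = np.asarray(best_match_scores, dtype=float)
    if scores.size == 0:
        raise InvalidInputError("need at least one best-match score")
    if kind == "structure":
        if np.any((scores < 0) | (scores > 1)):
            raise InvalidInputError("structure scores must be TM-scores in [0,1]")
        novel = scores < STRUCTURE_NOVELTY_TM
    elif kind == "sequence":
        if np.any(scores < 0):
            raise InvalidInputError("E-values must be non-negative")
        novel = scores > SEQUENCE_NOVELTY_EVALUE
    else:
        raise InvalidInputError(f"kind must be 'structure' or 'sequence', got {kind!r}")
    return float(novel.mean()), float(np.median(scores))


def compare_outcome_groups(
    success_values: Sequence[float], failure_values: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing successes with failures.

    Uses the exact null distribution when both samples are small
    (``n1 * n2 <= 400``) and tie-free; otherwise the normal
    approximation with tie correction.  Returns ``(U, p)`` with U the
    statistic of the first group.
    """
    x = np.asarray(success_values, dtype=float)
    y = np.asarray(failure_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidInputError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    small = x.size * y.size <= 400
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))
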