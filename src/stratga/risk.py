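"""Ternary chromosomes and rank-averaged patient risk scores.

A chromosome assigns each gene one of three states: +1 (selected, high
expression adverse), -1 (selected, low expression adverse) or 0 (unselected).
For every selected gene, patients are ranked by expression in the
direction-appropriate order (rank 1 = lowest predicted risk: for a +1 gene
the lowest expressor gets rank 1, for a -1 gene the highest expressor does).
A patient's risk score is the unweighted mean of their per-gene ranks; the
induced ascending order is the patient stratification everything downstream
scores.  Ranks are 1-based with average (fractional) ranks for ties, so each
gene's ranks sum to n(n+1)/2 and the mean risk score over patients is always
(n+1)/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy.stats import rankdata

if TYPE_CHECKING:
    from .cohort import Cohort


class EmptyGeneSetError(ValueError):
    """Raised when a chromosome selects no genes."""


@dataclass
class Chromosome:
    """Ternary gene vector over a fixed gene universe."""

    values: np.ndarray  # int8 in {-1, 0, +1}, length n_genes

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if not np.isin(self.values, (-1, 0, 1)).all():
            raise ValueError("chromosome values must be in {-1, 0, +1}")

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.values))

    def key(self) -> bytes:
        """Content key for fitness caching."""
        return self.values.tobytes()

    def copy(self) -> "Chromosome":
        return Chromosome(self.values.copy())


@dataclass
class RiskProfile:
    """Per-patient risk scores and the ordering they induce."""

    risk_score: np.ndarray          # length n_samples, each in [1, n_samples]
    order: np.ndarray               # sample indices, ascending risk
    n_selected: int

    @property
    def ranks(self) -> np.ndarray:
        """1-based rank of each sample in the induced ordering."""
        r = np.empty(len(self.order), dtype=np.int64)
        r[self.order] = np.arange(1, len(self.order) + 1)
        return r


def rank_patients_by_gene(expression: np.ndarray, direction: int) -> np.ndarray:
    """Direction-aware 1-based average ranks of one gene's expression column.

    direction +1: lowest expression -> rank 1 (high expression adverse);
    direction -1: highest expression -> rank 1 (low expression adverse).
    Ties receive the average of their rank span.
    """
    if direction not in (+1, -1):
        raise ValueError(f"direction must be +1 or -1, got {direction}")
    col = np.asarray(expression, dtype=float)
    return rankdata(col if direction == +1 else -col, method="average")


def ascending_rank_matrix(cohort: "Cohort") -> np.ndarray:
    """Average ranks of every gene column, ascending in expression.

    Shape (n_samples, n_genes).  Precomputed once per cohort: a -1 gene's
    ranks are ``n + 1 - ranks`` of this matrix, so risk scores for any
    chromosome reduce to one matrix-vector product.
    """
    return rankdata(cohort.expression, method="average", axis=0)


def risk_scores_from_ranks(values: np.ndarray, rank_matrix: np.ndarray) -> np.ndarray:
    """Risk scores for one chromosome given the ascending rank matrix."""
    values = np.asarray(values)
    m = int(np.count_nonzero(values))
    if m == 0:
        raise EmptyGeneSetError("empty gene set: chromosome selects no genes")
    n = rank_matrix.shape[0]
    n_neg = int(np.sum(values == -1))
    # +1 genes contribute r, -1 genes contribute (n+1) - r
    total = rank_matrix @ values.astype(float) + (n + 1.0) * n_neg
    return total / m


def compute_risk_scores(
    chromosome: Chromosome,
    cohort: "Cohort",
    rank_matrix: np.ndarray | None = None,
) -> RiskProfile:
    """Rank-averaged risk scores and patient ordering for one chromosome.

    Ordering ties are broken by sample position (clinical-table order) so the
    reported order is reproducible; the stratification score itself handles
    ties through tau-b and never depends on this tie-break.
    """
    if rank_matrix is None:
        rank_matrix = ascending_rank_matrix(cohort)
    scores = risk_scores_from_ranks(chromosome.values, rank_matrix)
    order = np.lexsort((np.arange(len(scores)), scores))
    return RiskProfile(risk_score=scores, order=order,
                       n_selected=chromosome.n_selected)
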