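"""Validation transfer and repeated-run aggregation.

`apply_gene_set` carries only the learned per-gene directions to an
independent cohort: ranks, risk scores, the stratification score, the
logistic group boundaries, the survival score and per-subtype k-group
log-rank p-values are all recomputed within that cohort, so no
discovery-cohort statistic leaks into validation.

`ensemble_runs` repeats the GA with derived seeds and aggregates (i) the
pairwise Spearman correlation of patient orderings — the stability readout —
and (ii) per-gene selection counts split by direction, from which
`frequent_genes` nominates recurrent markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .cohort import Cohort, GeneSetResult
from .fitness import (
    FitnessBreakdown,
    PairTerm,
    RiskGrouping,
    determine_boundaries,
    stratification_score,
    survival_score,
)
from .ga import GAConfig, GAState, run_ga
from .risk import Chromosome, RiskProfile, compute_risk_scores
from .survstats import logrank_k_group

logger = logging.getLogger(__name__)


@dataclass
class ValidationReport:
    """Scores of a learned gene set on one cohort."""

    stratification_score: float
    survival_score: float
    pair_terms: list[PairTerm]
    subtype_logrank_p: dict[str, float]   # k-group log-rank within each subtype
    profile: RiskProfile
    grouping: RiskGrouping
    n_genes_used: int
    n_genes_dropped: int

    @property
    def fitness(self) -> float:
        """Composite score at the lambda recorded by the caller (see apply)."""
        return self._fitness

    _fitness: float = 0.0


def chromosome_from_gene_set(result: GeneSetResult, cohort: Cohort) -> tuple[Chromosome, int]:
    """Map learned directions onto a cohort's gene universe.

    Genes absent from the cohort are dropped with a warning; zero overlap is
    a hard error.  Returns the chromosome and the number dropped.
    """
    index = {g: i for i, g in enumerate(cohort.gene_ids)}
    values = np.zeros(cohort.n_genes, dtype=np.int8)
    dropped = 0
    for gene, direction in result.directions.items():
        i = index.get(gene)
        if i is None:
            dropped += 1
        else:
            values[i] = direction
    if not values.any():
        raise ValueError("no genes of the gene set are present in the cohort")
    if dropped:
        logger.warning("%d gene(s) of the gene set absent from cohort; dropped", dropped)
    return Chromosome(values), dropped


def apply_gene_set(
    result: GeneSetResult,
    cohort: Cohort,
    lam: float = 0.5,
    b: float = 0.01,
) -> ValidationReport:
    """Score a learned gene set on a cohort, refitting everything locally."""
    chrom, dropped = chromosome_from_gene_set(result, cohort)
    profile = compute_risk_scores(chrom, cohort)
    strat = stratification_score(cohort.subtype_codes[profile.order])
    grouping = determine_boundaries(profile, cohort)
    surv, terms = survival_score(grouping, cohort, b=b)

    groups = np.asarray(grouping.groups)
    subtype_p: dict[str, float] = {}
    for name in cohort.subtype_order:
        mask = cohort.subtype == name
        labels = groups[mask]
        if len(np.unique(labels)) < 2:
            subtype_p[name] = float("nan")
            continue
        _, p, _ = logrank_k_group(cohort.os_time[mask], cohort.os_event[mask], labels)
        subtype_p[name] = p

    report = ValidationReport(
        stratification_score=strat,
        survival_score=surv,
        pair_terms=terms,
        subtype_logrank_p=subtype_p,
        profile=profile,
        grouping=grouping,
        n_genes_used=chrom.n_selected,
        n_genes_dropped=dropped,
    )
    report._fitness = strat + lam * surv
    return report


# ---------------------------------------------------------------------------
# repeated runs
# ---------------------------------------------------------------------------

@dataclass
class RunEnsemble:
    """Artifacts of repeated GA runs on one cohort."""

    results: list[GeneSetResult]
    risk_scores: list[np.ndarray]           # per run, per patient
    spearman: np.ndarray                    # n_runs x n_runs
    counts_pos: dict[str, int] = field(default_factory=dict)
    counts_neg: dict[str, int] = field(default_factory=dict)
    seeds: list[int] = field(default_factory=list)

    @property
    def n_runs(self) -> int:
        return len(self.results)

    def median_pairwise_spearman(self) -> float:
        iu = np.triu_indices(self.n_runs, k=1)
        return float(np.median(self.spearman[iu]))


def ensemble_runs(
    cohort: Cohort,
    config: GAConfig,
    n_runs: int,
    seed: int,
) -> RunEnsemble:
    """Run the GA ``n_runs`` times with seeds derived from ``seed``."""
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    root = np.random.default_rng(seed)
    seeds = [int(s) for s in root.integers(0, 2**31 - 1, size=n_runs)]
    results: list[GeneSetResult] = []
    scores: list[np.ndarray] = []
    counts_pos: dict[str, int] = {}
    counts_neg: dict[str, int] = {}
    for run_seed in seeds:
        cfg = GAConfig(**{**config.__dict__, "seed": run_seed})
        result, state = run_ga(cohort, cfg)
        results.append(result)
        chrom, _ = chromosome_from_gene_set(result, cohort)
        scores.append(compute_risk_scores(chrom, cohort).risk_score)
        for g, d in result.directions.items():
            if d == +1:
                counts_pos[g] = counts_pos.get(g, 0) + 1
            else:
                counts_neg[g] = counts_neg.get(g, 0) + 1
    mat = np.ones((n_runs, n_runs))
    for i in range(n_runs):
        for j in range(i + 1, n_runs):
            rho = spearmanr(scores[i], scores[j]).statistic
            mat[i, j] = mat[j, i] = rho
    return RunEnsemble(
        results=results, risk_scores=scores, spearman=mat,
        counts_pos=counts_pos, counts_neg=counts_neg, seeds=seeds,
    )


def frequent_genes(
    ensemble: RunEnsemble, min_count: int
) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """Genes selected at least ``min_count`` times, split by direction.

    Each list holds (gene, count) sorted by count descending, then gene id.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")

    def top(counts: dict[str, int]) -> list[tuple[str, int]]:
        return sorted(
            ((g, c) for g, c in counts.items() if c >= min_count),
            key=lambda gc: (-gc[1], gc[0]),
        )

    return top(ensemble.counts_pos), top(ensemble.counts_neg)


# ---------------------------------------------------------------------------
# tabular exports
# ---------------------------------------------------------------------------

def report_frame(report: ValidationReport) -> pd.DataFrame:
    rows = [("stratification_score", report.stratification_score),
            ("survival_score", report.survival_score),
            ("n_genes_used", report.n_genes_used),
            ("n_genes_dropped", report.n_genes_dropped)]
    rows += [(f"logrank_p[{k}]", v) for k, v in report.subtype_logrank_p.items()]
    return pd.DataFrame(rows, columns=["quantity", "value"])


def pair_terms_frame(terms: list[PairTerm]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair": [t.label for t in terms],
            "c": [t.c for t in terms],
            "l": [t.l for t in terms],
            "f": [t.f for t in terms],
            "degenerate": [t.degenerate for t in terms],
        }
    )


def frequency_frame(ensemble: RunEnsemble) -> pd.DataFrame:
    rows = [(g, "+1", c) for g, c in ensemble.counts_pos.items()]
    rows += [(g, "-1", c) for g, c in ensemble.counts_neg.items()]
    df = pd.DataFrame(rows, columns=["gene", "direction", "count"])
    return df.sort_values(["count", "gene"], ascending=[False, True]).reset_index(drop=True)


def spearman_frame(ensemble: RunEnsemble) -> pd.DataFrame:
    names = [f"run{i}" for i in range(ensemble.n_runs)]
    return pd.DataFrame(ensemble.spearman, index=names, columns=names)
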