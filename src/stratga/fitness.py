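"""Composite fitness: subtype concordance + weighted within-subtype prognosis.

The fitness of a chromosome is

    F = (stratification score) + lambda * (survival score)

The stratification score is Kendall's tau-b between the subtype sequence in
risk order (``sc``) and the same multiset of labels fully sorted into the
prognosis order (``s_ref``); tau-b's tie corrections make it well defined for
categorical sequences with many repeats.

The survival score asks whether, within each subtype, higher risk scores mean
worse survival.  Each subtype is cut into Low/(Intermediate)/High risk groups
at boundaries fitted by one-feature logistic regression between adjacent
subtypes (probability 0.5 point); end subtypes get 2 groups, interior
subtypes 3.  Every adjacent within-subtype group pair contributes
f = c * l, where c = +/-1 is the direction of the two-group Cox hazard ratio
and l = -log10(log-rank p), clipped at -log10(b); the survival score is the
mean of the 2K-2 pair terms.  With b = 0.01 each term lies in [-2, 2].

lambda = 0 skips the survival branch entirely (the activation schedule starts
there); lambda defaults to 0.5, b to 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy.stats import kendalltau

from .risk import Chromosome, RiskProfile, compute_risk_scores
from .survstats import cox_two_group, logistic_boundary, logrank_two_group

if TYPE_CHECKING:
    from .cohort import Cohort

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA = 0.5
DEFAULT_B = 0.01

GROUP_LOW, GROUP_INT, GROUP_HIGH = "L", "I", "H"


@dataclass
class PairTerm:
    """One adjacent-group survival comparison within a subtype."""

    label: str          # e.g. "LumB:L-I"
    c: int              # hazard-ratio direction, +1/-1 (0 if degenerate)
    l: float            # clipped -log10 log-rank p (0 if degenerate)
    f: float            # c * l
    degenerate: bool = False


@dataclass
class FitnessBreakdown:
    """Everything the fitness function computed for one chromosome."""

    stratification_score: float
    survival_score: float | None      # None when lambda = 0 (branch skipped)
    lambda_used: float
    fitness: float
    pair_terms: list[PairTerm] = field(default_factory=list)


@dataclass
class RiskGrouping:
    """Within-subtype risk groups and the boundaries that produced them."""

    boundaries: np.ndarray            # K-1 risk-score thresholds
    boundary_methods: list[str]       # fit branch per boundary
    groups: list[str]                 # per-sample "subtype:L/I/H" label
    empty_groups: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# stratification score
# ---------------------------------------------------------------------------

def stratification_score(sc_codes: np.ndarray) -> float:
    """Kendall tau-b between a subtype sequence and its fully sorted self.

    ``sc_codes`` are integer subtype positions (0 = best prognosis) in
    patient risk order; the reference sequence is the same values sorted
    ascending.  Returns 0.0 (with a warning) when fewer than two distinct
    subtypes are present, where tau-b's denominator vanishes.
    """
    sc = np.asarray(sc_codes)
    if sc.size == 0:
        raise ValueError("empty subtype sequence")
    if len(np.unique(sc)) < 2:
        logger.warning("single distinct subtype: stratification score defined as 0")
        return 0.0
    s_ref = np.sort(sc)
    tau = kendalltau(sc, s_ref, variant="b").statistic
    return float(tau)


# ---------------------------------------------------------------------------
# risk groups within subtypes
# ---------------------------------------------------------------------------

def determine_boundaries(profile: RiskProfile, cohort: "Cohort") -> RiskGrouping:
    """Fit one logistic boundary per adjacent subtype pair and group patients.

    For each adjacent pair (S_k, S_{k+1}) in prognosis order, a one-feature
    logistic regression (feature = risk score, label = membership of
    S_{k+1}) is fitted on the patients of those two subtypes only; the
    boundary is the risk score at predicted probability 0.5.  Each end
    subtype is split into 2 groups by its single adjacent boundary, interior
    subtypes into up to 3 by both.  Patients exactly on a boundary go to the
    lower-risk side.
    """
    K = cohort.n_subtypes
    codes = cohort.subtype_codes
    counts = np.bincount(codes, minlength=K)
    if (counts == 0).any():
        empty = [cohort.subtype_order[k] for k in np.flatnonzero(counts == 0)]
        raise ValueError(f"subtype(s) with zero patients: {empty}")
    if K < 2:
        raise ValueError("need at least 2 subtypes to fit boundaries")

    x = profile.risk_score
    boundaries = np.empty(K - 1)
    methods: list[str] = []
    for k in range(K - 1):
        mask = (codes == k) | (codes == k + 1)
        boundaries[k], method = logistic_boundary(x[mask], (codes[mask] == k + 1).astype(float))
        methods.append(method)

    groups: list[str] = []
    for i in range(cohort.n_samples):
        k = codes[i]
        name = cohort.subtype_order[k]
        if k == 0:
            g = GROUP_LOW if x[i] <= boundaries[0] else GROUP_HIGH
        elif k == K - 1:
            g = GROUP_LOW if x[i] <= boundaries[K - 2] else GROUP_HIGH
        else:
            if x[i] <= boundaries[k - 1]:
                g = GROUP_LOW
            elif x[i] <= boundaries[k]:
                g = GROUP_INT
            else:
                g = GROUP_HIGH
        groups.append(f"{name}:{g}")

    expected = set()
    for k, name in enumerate(cohort.subtype_order):
        tags = (GROUP_LOW, GROUP_HIGH) if k in (0, K - 1) else (GROUP_LOW, GROUP_INT, GROUP_HIGH)
        expected.update(f"{name}:{t}" for t in tags)
    empty_groups = sorted(expected - set(groups))
    return RiskGrouping(boundaries=boundaries, boundary_methods=methods,
                        groups=groups, empty_groups=empty_groups)


# ---------------------------------------------------------------------------
# survival score
# ---------------------------------------------------------------------------

def pair_term(
    time_a: np.ndarray, event_a: np.ndarray,
    time_b: np.ndarray, event_b: np.ndarray,
    b: float = DEFAULT_B, label: str = "",
) -> PairTerm:
    """f = c * l for one (lower-risk A, higher-risk B) group comparison.

    c = +1 iff the two-group Cox fit estimates hazard(B) > hazard(A);
    l = -log10(log-rank p), clipped at -log10(b).  A pair with an empty
    group, or a group with zero observed events, is degenerate and scores 0
    (prognosis-neutral), keeping imperfect chromosomes evaluable.
    """
    if len(time_a) == 0 or len(time_b) == 0 or event_a.sum() == 0 or event_b.sum() == 0:
        return PairTerm(label=label, c=0, l=0.0, f=0.0, degenerate=True)
    time = np.concatenate([time_a, time_b])
    event = np.concatenate([event_a, event_b])
    group = np.concatenate([np.zeros(len(time_a), int), np.ones(len(time_b), int)])
    beta = cox_two_group(time, event, group)
    c = 1 if beta > 0 else -1
    _, _, p = logrank_two_group(time, event, group)
    l = -np.log10(p) if p > b else -np.log10(b)
    return PairTerm(label=label, c=c, l=float(l), f=float(c * l))


def adjacent_group_pairs(subtype_order: list[str]) -> list[tuple[str, str]]:
    """The 2K-2 within-subtype (lower-risk, higher-risk) group pairs."""
    K = len(subtype_order)
    pairs: list[tuple[str, str]] = []
    for k, name in enumerate(subtype_order):
        if k in (0, K - 1):
            pairs.append((f"{name}:{GROUP_LOW}", f"{name}:{GROUP_HIGH}"))
        else:
            pairs.append((f"{name}:{GROUP_LOW}", f"{name}:{GROUP_INT}"))
            pairs.append((f"{name}:{GROUP_INT}", f"{name}:{GROUP_HIGH}"))
    return pairs


def survival_score(
    grouping: RiskGrouping, cohort: "Cohort", b: float = DEFAULT_B
) -> tuple[float, list[PairTerm]]:
    """Mean of the 2K-2 adjacent within-subtype pair terms."""
    groups = np.asarray(grouping.groups)
    terms: list[PairTerm] = []
    for ga, gb in adjacent_group_pairs(cohort.subtype_order):
        ma, mb = groups == ga, groups == gb
        terms.append(
            pair_term(
                cohort.os_time[ma], cohort.os_event[ma],
                cohort.os_time[mb], cohort.os_event[mb],
                b=b, label=f"{ga.split(':')[0]}:{ga.split(':')[1]}-{gb.split(':')[1]}",
            )
        )
    score = float(np.mean([t.f for t in terms]))
    return score, terms


# ---------------------------------------------------------------------------
# composite fitness
# ---------------------------------------------------------------------------

def evaluate_fitness(
    chromosome: Chromosome,
    cohort: "Cohort",
    lam: float = DEFAULT_LAMBDA,
    b: float = DEFAULT_B,
    rank_matrix: np.ndarray | None = None,
    profile: RiskProfile | None = None,
) -> FitnessBreakdown:
    """F = stratification + lambda * survival for one chromosome.

    With lambda = 0 the survival branch (boundary fitting, Cox and log-rank
    tests) is skipped entirely and ``survival_score`` is recorded as None.
    """
    if profile is None:
        profile = compute_risk_scores(chromosome, cohort, rank_matrix)
    sc_codes = cohort.subtype_codes[profile.order]
    strat = stratification_score(sc_codes)
    if lam == 0:
        return FitnessBreakdown(
            stratification_score=strat, survival_score=None,
            lambda_used=0.0, fitness=strat,
        )
    grouping = determine_boundaries(profile, cohort)
    surv, terms = survival_score(grouping, cohort, b=b)
    return FitnessBreakdown(
        stratification_score=strat, survival_score=surv,
        lambda_used=float(lam), fitness=strat + lam * surv, pair_terms=terms,
    )
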