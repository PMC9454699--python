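"""Synthetic cohorts with the structure the method assumes.

The generator emulates a bulk-RNA cohort of K ordered molecular subtypes in
which (i) subtype order correlates with outcome and (ii) some genes' high OR
low expression is adverse:

* subtype labels are drawn from configurable proportions (defaults echo a
  large breast-cancer cohort: 0.54 / 0.24 / 0.11 / 0.11 across four ordered
  subtypes);
* expression is lognormal (FPKM-like skew; the method is rank-based, so the
  family affects realism, not correctness);
* *subtype genes* shift their log-mean linearly along the subtype order and
  carry no hazard of their own;
* *prognostic genes* drive the hazard through their standardized
  log-expression — +1 genes adversely when high, -1 genes adversely when
  low — and also trend monotonically along the subtype order (+1 genes up,
  -1 genes down), mirroring real signatures (e.g. proliferation genes) that
  mark both worse subtypes and worse prognosis;
* *noise genes* are i.i.d. lognormal;
* survival is exponential with hazard
  ``baseline_hazards[subtype] * exp(eta)`` where
  ``eta = prognostic_effect * z_agg`` and ``z_agg`` is the direction-aligned
  sum of the planted genes' z-scores scaled by ``1/sqrt(n_prognostic)`` —
  so ``prognostic_effect`` is the log hazard per SD of the planted
  signature; censoring is independent exponential, with its rate calibrated
  by bisection to the requested expected censored fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .risk import Chromosome

ROLE_SUBTYPE = "subtype"
ROLE_PROG_POS = "prognostic+1"
ROLE_PROG_NEG = "prognostic-1"
ROLE_NOISE = "noise"


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 300
    subtype_order: tuple[str, ...] = ("LumA", "LumB", "Her2", "Basal")
    proportions: tuple[float, ...] = (0.54, 0.24, 0.11, 0.11)
    n_subtype_genes: int = 0
    n_prognostic_pos: int = 15
    n_prognostic_neg: int = 15
    n_noise_genes: int = 470
    subtype_effect: float = 0.3       # log-mean shift per subtype step, in within-group SD
    prognostic_effect: float = 1.0    # log hazard per SD of the planted signature
    baseline_hazards: tuple[float, ...] = (2.0e-4, 3.0e-4, 4.5e-4, 6.5e-4)  # per day
    censoring_rate: float = 0.4       # expected censored fraction
    weibull_shape: float = 1.0        # 1 = exponential; PH preserved for any shape
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("subtype proportions must sum to 1")
        if len(self.proportions) != len(self.subtype_order):
            raise ValueError("proportions and subtype_order length mismatch")
        if len(self.baseline_hazards) != len(self.subtype_order):
            raise ValueError("baseline_hazards and subtype_order length mismatch")
        if not all(a < b for a, b in zip(self.baseline_hazards, self.baseline_hazards[1:])):
            raise ValueError("baseline_hazards must be strictly increasing along subtype order")
        if not 0.0 < self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in (0, 1)")
        for name in ("n_samples",):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def n_genes(self) -> int:
        return (self.n_subtype_genes + self.n_prognostic_pos
                + self.n_prognostic_neg + self.n_noise_genes)


@dataclass
class GroundTruth:
    """What was planted: per-gene role and the per-sample latent log-hazard."""

    roles: list[str]                 # one of the ROLE_* constants per gene
    latent_risk: np.ndarray          # eta, the linear predictor of the hazard

    def planted_directions(self, gene_ids: list[str]) -> dict[str, int]:
        out: dict[str, int] = {}
        for g, r in zip(gene_ids, self.roles):
            if r == ROLE_PROG_POS:
                out[g] = +1
            elif r == ROLE_PROG_NEG:
                out[g] = -1
        return out


def _calibrate_censoring(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean_i c/(c+h_i) = target (bisection)."""
    lo, hi = 1e-12, float(hazards.max())

    def frac(c: float) -> float:
        return float(np.mean(c / (c + hazards)))

    while frac(hi) < target:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("censoring calibration infeasible")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(config: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Draw one cohort and its ground truth.  Same seed, same cohort."""
    rng = np.random.default_rng(config.seed)
    n, K = config.n_samples, len(config.subtype_order)
    codes = rng.choice(K, size=n, p=np.asarray(config.proportions))
    # centred subtype index so the overall expression scale is subtype-free
    centred = codes - (K - 1) / 2.0

    roles = (
        [ROLE_SUBTYPE] * config.n_subtype_genes
        + [ROLE_PROG_POS] * config.n_prognostic_pos
        + [ROLE_PROG_NEG] * config.n_prognostic_neg
        + [ROLE_NOISE] * config.n_noise_genes
    )
    n_genes = len(roles)
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    base_loc = 1.5  # log-FPKM-ish location

    log_expr = rng.normal(base_loc, 1.0, size=(n, n_genes))
    trend = np.zeros(n_genes)
    for j, r in enumerate(roles):
        if r == ROLE_SUBTYPE or r == ROLE_PROG_POS:
            trend[j] = config.subtype_effect
        elif r == ROLE_PROG_NEG:
            trend[j] = -config.subtype_effect
    log_expr += centred[:, None] * trend[None, :]
    expression = np.exp(log_expr)

    # latent log-hazard from the planted prognostic genes
    prog_cols = [j for j, r in enumerate(roles) if r in (ROLE_PROG_POS, ROLE_PROG_NEG)]
    if prog_cols:
        z = log_expr[:, prog_cols]
        z = (z - z.mean(axis=0)) / z.std(axis=0)
        signs = np.array([+1 if roles[j] == ROLE_PROG_POS else -1 for j in prog_cols])
        eta = config.prognostic_effect * (z @ signs) / np.sqrt(len(prog_cols))
    else:
        eta = np.zeros(n)

    hazards = np.asarray(config.baseline_hazards)[codes] * np.exp(eta)
    u = rng.random(n)
    # inverse-CDF Weibull with PH parameterisation: S(t) = exp(-h * t^shape)
    t_event = (-np.log(u) / hazards) ** (1.0 / config.weibull_shape)
    c_rate = _calibrate_censoring(hazards, config.censoring_rate)
    t_cens = rng.exponential(1.0 / c_rate, size=n) ** (1.0 / config.weibull_shape)
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)

    cohort = Cohort(
        sample_ids=[f"P{i:04d}" for i in range(n)],
        expression=expression,
        gene_ids=gene_ids,
        subtype=np.asarray(config.subtype_order, dtype=object)[codes],
        os_time=os_time,
        os_event=os_event,
        subtype_order=list(config.subtype_order),
    )
    return cohort, GroundTruth(roles=roles, latent_risk=eta)


def oracle_chromosome(truth: GroundTruth, include_subtype: bool = False) -> Chromosome:
    """The chromosome selecting exactly the planted prognostic genes.

    With ``include_subtype`` the subtype-only genes are added at +1 (their
    expression rises along the worsening subtype order).  Used as an upper
    reference for fitness in tests; raises if nothing was planted.
    """
    values = np.zeros(len(truth.roles), dtype=np.int8)
    for j, r in enumerate(truth.roles):
        if r == ROLE_PROG_POS:
            values[j] = +1
        elif r == ROLE_PROG_NEG:
            values[j] = -1
        elif include_subtype and r == ROLE_SUBTYPE:
            values[j] = +1
    if not values.any():
        raise ValueError("no planted genes in ground truth")
    return Chromosome(values)


def truth_frame(truth: GroundTruth, gene_ids: list[str]) -> pd.DataFrame:
    return pd.DataFrame({"gene": gene_ids, "role": truth.roles})
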