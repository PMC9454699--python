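"""Cohort container and TSV input/output.

A :class:`Cohort` bundles an FPKM-like expression matrix with the clinical
annotations the method needs: an ordered molecular-subtype label per sample
(the prognosis ordering ``subtype_order`` is the method's central premise),
an overall-survival time and an event indicator.  All downstream modules
operate on an aligned, validated ``Cohort``; this module owns every on-disk
format so the rest of the package never touches files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = ("sample_id", "subtype", "os_time", "os_event")


class CohortError(ValueError):
    """Raised for any cohort validation or file-format failure."""


@dataclass
class Cohort:
    """Aligned expression + clinical data over a fixed gene universe.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, in clinical-table order.
    expression
        Non-negative matrix of shape ``(n_samples, n_genes)``.
    gene_ids
        Unique gene symbols, one per expression column.
    subtype
        Per-sample subtype label; every label must occur in ``subtype_order``.
    os_time
        Per-sample overall-survival / censoring time (any consistent unit).
    os_event
        1 = death observed, 0 = censored.
    subtype_order
        The K distinct subtype labels ordered best -> worst prognosis.
    """

    sample_ids: list[str]
    expression: np.ndarray
    gene_ids: list[str]
    subtype: np.ndarray
    os_time: np.ndarray
    os_event: np.ndarray
    subtype_order: list[str]
    # per-sample integer position of the subtype in subtype_order
    subtype_codes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        self.gene_ids = list(map(str, self.gene_ids))
        self.subtype_order = list(map(str, self.subtype_order))
        self.expression = np.asarray(self.expression, dtype=float)
        self.subtype = np.asarray(self.subtype, dtype=object)
        self.os_time = np.asarray(self.os_time, dtype=float)
        self.os_event = np.asarray(self.os_event, dtype=int)
        self._validate()
        code_of = {s: i for i, s in enumerate(self.subtype_order)}
        self.subtype_codes = np.array([code_of[s] for s in self.subtype], dtype=np.int64)

    # -- validation -------------------------------------------------------
    def _validate(self) -> None:
        n, g = len(self.sample_ids), len(self.gene_ids)
        if self.expression.shape != (n, g):
            raise CohortError(
                f"expression shape {self.expression.shape} does not match "
                f"{n} samples x {g} genes"
            )
        _check_unique(self.sample_ids, "sample_ids")
        _check_unique(self.gene_ids, "gene_ids")
        _check_unique(self.subtype_order, "subtype_order")
        if np.isnan(self.expression).any():
            raise CohortError("expression contains missing values")
        if (self.expression < 0).any():
            raise CohortError("expression contains negative values")
        for arr, name in ((self.subtype, "subtype"), (self.os_time, "os_time"), (self.os_event, "os_event")):
            if len(arr) != n:
                raise CohortError(f"{name} length {len(arr)} != {n} samples")
        unknown = sorted(set(self.subtype) - set(self.subtype_order))
        if unknown:
            raise CohortError(
                f"unknown subtype labels {unknown}; allowed: {self.subtype_order}"
            )
        if (self.os_time < 0).any():
            raise CohortError("os_time contains negative values")
        bad_event = set(np.unique(self.os_event)) - {0, 1}
        if bad_event:
            raise CohortError(f"os_event values outside {{0,1}}: {sorted(bad_event)}")

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_subtypes(self) -> int:
        return len(self.subtype_order)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise CohortError(f"gene {gene!r} not in cohort") from None


@dataclass
class GeneSetResult:
    """A selected gene set: per-gene direction plus selection bookkeeping.

    ``directions`` maps gene id -> +1 (high expression adverse) or -1 (low
    expression adverse).  ``selection_frequency`` counts, per (gene,
    direction), how many aggregated runs selected it; single-run results use
    frequency 1.  ``provenance`` records seeds and a config digest.
    """

    directions: dict[str, int]
    selection_frequency: dict[str, int] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g: d for g, d in self.directions.items() if d not in (+1, -1)}
        if bad:
            raise CohortError(f"gene directions must be +1/-1, got {bad}")
        if not self.selection_frequency:
            self.selection_frequency = {g: 1 for g in self.directions}

    def __len__(self) -> int:
        return len(self.directions)


def _check_unique(items: Sequence[str], name: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for x in items:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise CohortError(f"duplicate {name}: {sorted(set(dups))}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression(path, orientation: str = "genes-as-rows") -> pd.DataFrame:
    """Read an expression TSV and return a samples x genes DataFrame.

    ``orientation`` states how the file is laid out; the returned frame is
    always samples-as-rows.  Orientation is never guessed: a silently
    transposed matrix is a classic data bug.
    """
    if orientation not in ("genes-as-rows", "samples-as-rows"):
        raise CohortError(
            f"orientation must be 'genes-as-rows' or 'samples-as-rows', got {orientation!r}"
        )
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise CohortError(f"duplicate row identifiers in {path}: {dups}")
    if df.columns.has_duplicates:
        dups = sorted(df.columns[df.columns.duplicated()].unique())
        raise CohortError(f"duplicate column identifiers in {path}: {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().values)
    if bad.size:
        r, c = bad[0]
        raise CohortError(
            f"non-numeric expression value {df.iat[r, c]!r} at row "
            f"{df.index[r]!r}, column {df.columns[c]!r} in {path}"
        )
    neg = np.argwhere((numeric.values < 0))
    if neg.size:
        r, c = neg[0]
        raise CohortError(
            f"negative expression value at row {df.index[r]!r}, "
            f"column {df.columns[c]!r} in {path}"
        )
    if orientation == "genes-as-rows":
        numeric = numeric.T
    numeric.index.name = "sample_id"
    numeric.columns.name = "gene_id"
    return numeric


def read_clinical(path, subtype_order: Sequence[str] | None = None) -> pd.DataFrame:
    """Read the clinical TSV (sample_id, subtype, os_time, os_event).

    When ``subtype_order`` is given, subtype labels are validated against it.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subtype": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"clinical table {path} missing column(s): {missing}")
    if len(df) == 0:
        raise CohortError(f"clinical table {path} contains no samples")
    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"].unique())
        raise CohortError(f"duplicate sample ids in {path}: {dups}")
    df["os_time"] = pd.to_numeric(df["os_time"], errors="raise")
    df["os_event"] = pd.to_numeric(df["os_event"], errors="raise")
    if not df["os_event"].isin([0, 1]).all():
        bad = sorted(df.loc[~df["os_event"].isin([0, 1]), "os_event"].unique())
        raise CohortError(f"os_event values outside {{0,1}} in {path}: {bad}")
    if (df["os_time"] < 0).any():
        raise CohortError(f"negative os_time in {path}")
    if subtype_order is not None:
        unknown = sorted(set(df["subtype"]) - set(subtype_order))
        if unknown:
            raise CohortError(
                f"unknown subtype labels {unknown} in {path}; "
                f"allowed: {list(subtype_order)}"
            )
    return df[list(CLINICAL_COLUMNS)]


def align_cohort(
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    subtype_order: Sequence[str],
) -> Cohort:
    """Intersect expression and clinical samples and build a Cohort.

    Sample order of record is the clinical table's order.  Idempotent:
    aligning an already-aligned pair changes nothing.
    """
    expr_ids = set(expression.index)
    kept = [s for s in clinical["sample_id"] if s in expr_ids]
    if not kept:
        raise CohortError("no overlapping samples between expression and clinical tables")
    dropped_clin = len(clinical) - len(kept)
    dropped_expr = len(expr_ids) - len(kept)
    logger.info(
        "aligned cohort: %d samples kept, %d dropped from clinical, %d dropped from expression",
        len(kept), dropped_clin, dropped_expr,
    )
    clin = clinical.set_index("sample_id").loc[kept]
    expr = expression.loc[kept]
    return Cohort(
        sample_ids=kept,
        expression=expr.values.astype(float),
        gene_ids=list(expr.columns),
        subtype=clin["subtype"].values,
        os_time=clin["os_time"].values,
        os_event=clin["os_event"].values,
        subtype_order=list(subtype_order),
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_expression(df: pd.DataFrame, path, orientation: str = "genes-as-rows",
                     log2: bool = False) -> None:
    """Write a samples x genes DataFrame as TSV in the requested orientation.

    ``log2`` applies log2(x+1) for export/visualisation only; the core method
    is rank-based, so the transform never feeds back into the algorithm.
    """
    out = np.log2(df + 1.0) if log2 else df
    if orientation == "genes-as-rows":
        out = out.T
    out.to_csv(path, sep="\t", float_format="%.10g")


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_gene_set(result: GeneSetResult, path) -> None:
    """Write a gene set as TSV with columns gene, direction, frequency."""
    rows = sorted(
        result.directions.items(),
        key=lambda kv: (-result.selection_frequency.get(kv[0], 1), kv[0]),
    )
    df = pd.DataFrame(
        {
            "gene": [g for g, _ in rows],
            "direction": ["%+d" % d for _, d in rows],
            "frequency": [result.selection_frequency.get(g, 1) for g, _ in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_set(path) -> GeneSetResult:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    for col in ("gene", "direction"):
        if col not in df.columns:
            raise CohortError(f"gene-set table {path} missing column {col!r}")
    directions = {g: int(d) for g, d in zip(df["gene"], df["direction"])}
    freq = (
        {g: int(f) for g, f in zip(df["gene"], df["frequency"])}
        if "frequency" in df.columns
        else {}
    )
    return GeneSetResult(directions=directions, selection_frequency=freq)


def write_risk_table(profile, grouping, cohort: Cohort, path) -> None:
    """Write the per-sample risk table, sorted ascending by risk score.

    Columns: sample_id, subtype, risk_score, rank, risk_group.
    """
    order = profile.order
    groups = grouping.groups if grouping is not None else ["NA"] * cohort.n_samples
    df = pd.DataFrame(
        {
            "sample_id": [cohort.sample_ids[i] for i in order],
            "subtype": [cohort.subtype[i] for i in order],
            "risk_score": profile.risk_score[order],
            "rank": np.arange(1, cohort.n_samples + 1),
            "risk_group": [groups[i] for i in order],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
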