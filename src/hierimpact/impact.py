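"""Micro/macro-averaged recall and precision impact of hierarchy defects.

A *missing* is-a relation c1 -> c2 makes every cohort query for c2 or an
ancestor p of c2 under-retrieve: patients reachable only through c1 are lost.
The query for p then has recall

    |N_p| / |N_c1 ∪ N_p|

where N_c is the patient set retrieved by the atomic query for c (c plus its
descendants).  An *inaccurate* is-a relation c1 -> c2 makes those queries
over-retrieve, giving precision

    |N_p − N_c1| / |N_p|.

The overall impact of one defect aggregates these per-ancestor ratios over
c2^ (c2 and all its ancestors) in two ways:

* micro average — ratio of summed numerators to summed denominators,
  patient-weighted;
* macro average — unweighted mean of the per-ancestor ratios, query-weighted.

A per-ancestor ratio is NA when its denominator is zero (no patients
retrieved); NA terms are excluded from both aggregates, and the aggregates
themselves are NA exactly when every term is NA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .cohort import CohortIndex, cohort_query
from .errors import PreconditionError
from .terminology import TerminologyGraph

DefectType = Literal["missing", "inaccurate"]

#: Sentinel for undefined (0/0) metrics; serialized as the literal string "NA".
NA = float("nan")


def is_na(x: float | None) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class DefectRelation:
    """An asserted hierarchy defect between subconcept c1 and superconcept c2."""

    subconcept: str
    superconcept: str
    defect_type: DefectType
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.subconcept == self.superconcept:
            raise PreconditionError(
                f"defect relates concept {self.subconcept!r} to itself"
            )
        if self.defect_type not in ("missing", "inaccurate"):
            raise PreconditionError(f"unknown defect type {self.defect_type!r}")


@dataclass(frozen=True)
class AncestorImpactRow:
    """Per-ancestor metric row: one impacted cohort query.

    ``n_reference`` is |N_c1 ∪ N_p| for missing defects and |N_p − N_c1| for
    inaccurate ones; ``metric`` is the recall or precision of the query for
    ``ancestor``, or NA when the denominator is zero.
    """

    ancestor: str
    n_p: int
    n_reference: int
    metric: float  # NaN when undefined


@dataclass
class ImpactResult:
    """Impact of one defect on all queries in c2^."""

    defect: DefectRelation
    rows: list[AncestorImpactRow] = field(default_factory=list)
    micro: float = NA
    macro: float = NA
    n_ancestors: int = 0
    n_c1: int = 0
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


def per_query_recall(n_retrieved: int, n_expected: int) -> float:
    """Recall of one cohort query: |N_p| / |N_c1 ∪ N_p|; NA when nothing expected."""
    return n_retrieved / n_expected if n_expected > 0 else NA


def per_query_precision(n_correct: int, n_retrieved: int) -> float:
    """Precision of one cohort query: |N_p − N_c1| / |N_p|; NA when nothing retrieved."""
    return n_correct / n_retrieved if n_retrieved > 0 else NA


def _aggregate(rows: list[AncestorImpactRow], kind: DefectType) -> tuple[float, float]:
    """Micro and macro averages over rows with a defined (non-NA) metric."""
    defined = [r for r in rows if not is_na(r.metric)]
    if not defined:
        return NA, NA
    if kind == "missing":
        num = sum(r.n_p for r in defined)
        den = sum(r.n_reference for r in defined)
    else:
        num = sum(r.n_reference for r in defined)
        den = sum(r.n_p for r in defined)
    micro = num / den
    macro = sum(r.metric for r in defined) / len(defined)
    return micro, macro


def recall_impact(
    idx: CohortIndex,
    g: TerminologyGraph,
    d: DefectRelation,
    check_preconditions: bool = True,
) -> ImpactResult:
    """Assess a missing is-a relation on the graph where it is absent.

    The assessment graph ``g`` must not link c1 to c2 (directly or
    transitively) — that is what makes the relation missing.  Set
    ``check_preconditions=False`` for simulated removals where an alternate
    path may legitimately survive (those defects then show no impact:
    metrics of exactly 1).
    """
    if d.defect_type != "missing":
        raise PreconditionError(f"recall_impact needs a missing defect, got {d.defect_type!r}")
    if check_preconditions and g.has_path(d.subconcept, d.superconcept):
        raise PreconditionError(
            f"has_path({d.subconcept!r}, {d.superconcept!r}) holds in the assessment "
            "graph; the relation is not missing there"
        )
    n_c1_set = cohort_query(idx, g, d.subconcept).patients
    rows: list[AncestorImpactRow] = []
    for p in sorted(g.ancestors_inclusive(d.superconcept)):
        n_p_set = cohort_query(idx, g, p).patients
        n_p = len(n_p_set)
        n_union = len(n_c1_set | n_p_set)
        rows.append(AncestorImpactRow(p, n_p, n_union, per_query_recall(n_p, n_union)))
    micro, macro = _aggregate(rows, "missing")
    return ImpactResult(
        defect=d, rows=rows, micro=micro, macro=macro,
        n_ancestors=len(rows), n_c1=len(n_c1_set),
    )


def precision_impact(
    idx: CohortIndex, g: TerminologyGraph, d: DefectRelation
) -> ImpactResult:
    """Assess an inaccurate is-a relation on the graph where the edge is present."""
    if d.defect_type != "inaccurate":
        raise PreconditionError(
            f"precision_impact needs an inaccurate defect, got {d.defect_type!r}"
        )
    if not g.has_edge(d.subconcept, d.superconcept):
        raise PreconditionError(
            f"direct edge ({d.subconcept!r} -> {d.superconcept!r}) absent from the "
            "assessment graph; an inaccurate relation must be present to assess"
        )
    n_c1_set = cohort_query(idx, g, d.subconcept).patients
    rows: list[AncestorImpactRow] = []
    for p in sorted(g.ancestors_inclusive(d.superconcept)):
        n_p_set = cohort_query(idx, g, p).patients
        n_p = len(n_p_set)
        n_diff = len(n_p_set - n_c1_set)
        rows.append(AncestorImpactRow(p, n_p, n_diff, per_query_precision(n_diff, n_p)))
    micro, macro = _aggregate(rows, "inaccurate")
    return ImpactResult(
        defect=d, rows=rows, micro=micro, macro=macro,
        n_ancestors=len(rows), n_c1=len(n_c1_set),
    )


def batch_assess(
    idx: CohortIndex, g: TerminologyGraph, defects: Iterable[DefectRelation]
) -> list[ImpactResult]:
    """Assess many defects; per-defect failures are captured, not raised."""
    results: list[ImpactResult] = []
    for d in defects:
        try:
            if d.defect_type == "missing":
                results.append(recall_impact(idx, g, d))
            else:
                results.append(precision_impact(idx, g, d))
        except PreconditionError as exc:
            results.append(ImpactResult(defect=d, error=str(exc)))
    return results


# -- serialization ---------------------------------------------------------


def results_to_frame(
    results: Iterable[ImpactResult], g: TerminologyGraph | None = None
) -> pd.DataFrame:
    """Summarize impact results, one row per defect.

    Per-query columns (``n_super``, ``n_reference``, ``query_metric``) refer to
    the superconcept c2's own query; metrics are rounded to 4 decimals and NA
    is written literally in CSV output.
    """
    rows = []
    for r in results:
        c1, c2 = r.defect.subconcept, r.defect.superconcept
        c2_row = next((row for row in r.rows if row.ancestor == c2), None)
        rows.append({
            "subconcept_id": c1,
            "subconcept_name": g.name(c1) if g is not None and c1 in g else c1,
            "superconcept_id": c2,
            "superconcept_name": g.name(c2) if g is not None and c2 in g else c2,
            "defect_type": r.defect.defect_type,
            "n_super": c2_row.n_p if c2_row else NA,
            "n_reference": c2_row.n_reference if c2_row else NA,
            "query_metric": round(c2_row.metric, 4) if c2_row and not is_na(c2_row.metric) else NA,
            "micro": round(r.micro, 4) if not is_na(r.micro) else NA,
            "macro": round(r.macro, 4) if not is_na(r.macro) else NA,
            "n_ancestors": r.n_ancestors,
            "error": r.error or "",
        })
    return pd.DataFrame(rows)


def write_metrics_csv(
    results: Iterable[ImpactResult], path: str | Path, g: TerminologyGraph | None = None
) -> pd.DataFrame:
    df = results_to_frame(results, g)
    df.to_csv(path, index=False, na_rep="NA")
    return df
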