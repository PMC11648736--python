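"""Curation of aggregated defect lists against a reference terminology release.

Defect lists collected from multiple quality-assurance studies are filtered in
two ways before impact assessment:

* rectification — a defect already fixed in a newer release is dropped: a
  missing relation whose concepts are both active and now linked (directly or
  transitively), or an inaccurate edge that has been retired;
* subhierarchy restriction — keep only defects whose concepts both lie under
  chosen top-level concepts (e.g. Clinical finding, Procedure).

Removal requires positive evidence: a concept entirely absent from the
reference release is treated as inactive, so its defects are conservatively
kept (with a warning).  Provenance labels travel through untouched.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import LookupError_
from .impact import DefectRelation
from .terminology import TerminologyGraph

logger = logging.getLogger(__name__)


def _activity(g_ref: TerminologyGraph, concept_id: str) -> str:
    """Classify a concept in the reference release: active / inactive / absent."""
    if concept_id in g_ref:
        return "active"
    if concept_id in g_ref.inactive_ids:
        return "inactive"
    return "absent"


def filter_rectified_missing(
    defects: Sequence[DefectRelation], g_ref: TerminologyGraph
) -> tuple[list[DefectRelation], list[DefectRelation]]:
    """Partition missing defects into (kept, removed) against a reference release.

    A defect is removed iff both concepts are active in ``g_ref`` and the
    subconcept reaches the superconcept there — the relation has been
    rectified.  Concepts absent from the reference are treated as inactive
    (defect kept, warning logged).
    """
    kept: list[DefectRelation] = []
    removed: list[DefectRelation] = []
    for d in defects:
        if d.defect_type != "missing":
            raise LookupError_(f"expected missing defects, got {d.defect_type!r}")
        acts = (_activity(g_ref, d.subconcept), _activity(g_ref, d.superconcept))
        if "absent" in acts:
            logger.warning(
                "defect (%s -> %s): concept absent from reference %s; kept",
                d.subconcept, d.superconcept, g_ref.version_label or "release",
            )
        if acts == ("active", "active") and g_ref.has_path(d.subconcept, d.superconcept):
            removed.append(d)
        else:
            kept.append(d)
    logger.info("rectification filter (missing): kept %d, removed %d", len(kept), len(removed))
    return kept, removed


def filter_rectified_inaccurate(
    defects: Sequence[DefectRelation], g_ref: TerminologyGraph
) -> tuple[list[DefectRelation], list[DefectRelation]]:
    """Partition inaccurate defects into (kept, removed) against a reference release.

    A defect is removed iff the bad edge is positively gone: either concept is
    explicitly inactive in ``g_ref``, or both are active and the direct edge
    is absent.  Concepts absent from the reference are treated as unknown
    (defect kept, warning logged).
    """
    kept: list[DefectRelation] = []
    removed: list[DefectRelation] = []
    for d in defects:
        if d.defect_type != "inaccurate":
            raise LookupError_(f"expected inaccurate defects, got {d.defect_type!r}")
        acts = (_activity(g_ref, d.subconcept), _activity(g_ref, d.superconcept))
        if "absent" in acts:
            logger.warning(
                "defect (%s -> %s): concept absent from reference %s; kept",
                d.subconcept, d.superconcept, g_ref.version_label or "release",
            )
            kept.append(d)
        elif "inactive" in acts or not g_ref.has_edge(d.subconcept, d.superconcept):
            removed.append(d)
        else:
            kept.append(d)
    logger.info("rectification filter (inaccurate): kept %d, removed %d", len(kept), len(removed))
    return kept, removed


def restrict_to_subhierarchies(
    defects: Sequence[DefectRelation],
    g: TerminologyGraph,
    tops: Iterable[str],
) -> list[DefectRelation]:
    """Keep defects whose concepts both lie under at least one top concept."""
    scope: set[str] = set()
    for top in tops:
        if top not in g:
            raise LookupError_(f"unknown subhierarchy top {top!r}")
        scope |= g.descendants_inclusive(top)
    kept = [d for d in defects if d.subconcept in scope and d.superconcept in scope]
    logger.info("subhierarchy restriction: kept %d of %d defects", len(kept), len(defects))
    return kept


# -- CSV interface ---------------------------------------------------------

_COLUMNS = ["subconcept_id", "superconcept_id", "defect_type", "provenance"]


def read_defect_csv(path: str | Path) -> list[DefectRelation]:
    df = pd.read_csv(path, dtype=str).fillna("")
    return [
        DefectRelation(r.subconcept_id, r.superconcept_id, r.defect_type, r.provenance)
        for r in df.itertuples()
    ]


def write_defect_csv(defects: Iterable[DefectRelation], path: str | Path) -> None:
    pd.DataFrame(
        [(d.subconcept, d.superconcept, d.defect_type, d.provenance) for d in defects],
        columns=_COLUMNS,
    ).to_csv(path, index=False)
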