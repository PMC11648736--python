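"""Subtype (is-a) hierarchy as a directed acyclic graph.

The taxonomic backbone of a clinical terminology such as SNOMED CT is the set
of is-a relations: directed edges from a more specific concept (child) to a
more general one (parent).  Cohort queries and defect-impact metrics are all
defined in terms of two transitive closures over this DAG:

* ``ancestors_inclusive(c)`` — ``c`` together with every concept reachable by
  following child->parent edges (written ``c^`` in the metric definitions);
* ``descendants_inclusive(c)`` — the mirror closure over reversed edges, which
  determines which patients an atomic cohort query for ``c`` retrieves.

Graphs are immutable values: :meth:`TerminologyGraph.remove_edge` and
:meth:`TerminologyGraph.add_edge` return new graphs, so each instance can
safely cache its closures lazily per concept.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .errors import LookupError_, ValidationError

#: Relationship typeId identifying is-a rows in SNOMED CT RF2 releases.
SNOMED_IS_A = "116680003"

_RF2_CONCEPT_COLUMNS = ["id", "effectiveTime", "active", "moduleId", "definitionStatusId"]
_RF2_RELATIONSHIP_COLUMNS = [
    "id",
    "effectiveTime",
    "active",
    "moduleId",
    "sourceId",
    "destinationId",
    "relationshipGroup",
    "typeId",
    "characteristicTypeId",
    "modifierId",
]


@dataclass(frozen=True)
class Concept:
    """A terminology concept.

    Parameters
    ----------
    concept_id:
        Opaque identifier, unique within a graph.
    name:
        Human-readable label; defaults to the identifier when no label is known
        (RF2 snapshot concept files carry no terms).
    active:
        Inactive concepts are dropped at load time and carry no is-a edges.
    subhierarchy:
        Optional subhierarchy tag (e.g. ``"Clinical finding"``), usually set
        only on top-level concepts.
    """

    concept_id: str
    name: str = ""
    active: bool = True
    subhierarchy: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            object.__setattr__(self, "name", self.concept_id)


@dataclass(frozen=True)
class IsAEdge:
    """A directed subtype link: ``child`` is-a ``parent``."""

    child: str
    parent: str

    def __post_init__(self) -> None:
        if self.child == self.parent:
            raise ValidationError(f"self-loop is-a edge on concept {self.child!r}")


class TerminologyGraph:
    """An is-a DAG over active concepts.

    Parameters
    ----------
    concepts:
        Active concepts of the graph.  May be omitted when concepts should be
        inferred from edge endpoints.
    edges:
        Child->parent is-a edges; endpoints must be among ``concepts``.
    version_label:
        Free-text release label (e.g. ``"2023-09-01 US"``).
    inactive_ids:
        Concept ids known to be inactive in this release.  They are *not*
        nodes of the graph; curation uses them to distinguish an explicitly
        retired concept from one that is simply absent.
    """

    def __init__(
        self,
        concepts: Iterable[Concept],
        edges: Iterable[IsAEdge],
        version_label: str = "",
        inactive_ids: Iterable[str] = (),
    ) -> None:
        self.version_label = version_label
        self.inactive_ids = frozenset(inactive_ids)
        self._concepts: dict[str, Concept] = {}
        for c in concepts:
            if c.concept_id in self._concepts:
                raise ValidationError(f"duplicate concept id {c.concept_id!r}")
            self._concepts[c.concept_id] = c

        g = nx.DiGraph()
        g.add_nodes_from(self._concepts)
        dangling: list[IsAEdge] = []
        for e in edges:
            if e.child not in self._concepts or e.parent not in self._concepts:
                dangling.append(e)
            else:
                g.add_edge(e.child, e.parent)
        if dangling:
            shown = ", ".join(f"({e.child}->{e.parent})" for e in dangling[:10])
            raise ValidationError(
                f"{len(dangling)} edge(s) reference unknown concepts: {shown}"
            )
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[0][0]}"
            raise ValidationError(f"is-a graph contains a cycle: {path}")
        self._g = g
        self._anc_cache: dict[str, frozenset[str]] = {}
        self._desc_cache: dict[str, frozenset[str]] = {}

    # -- basic accessors ---------------------------------------------------

    @property
    def concept_ids(self) -> frozenset[str]:
        return frozenset(self._concepts)

    @property
    def n_concepts(self) -> int:
        return len(self._concepts)

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def concept(self, concept_id: str) -> Concept:
        self._require(concept_id)
        return self._concepts[concept_id]

    def name(self, concept_id: str) -> str:
        return self.concept(concept_id).name

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._concepts

    def edges(self) -> list[IsAEdge]:
        """All edges, sorted by (child, parent) for reproducible iteration."""
        return [IsAEdge(c, p) for c, p in sorted(self._g.edges())]

    def has_edge(self, child: str, parent: str) -> bool:
        return self._g.has_edge(child, parent)

    def parents(self, concept_id: str) -> frozenset[str]:
        self._require(concept_id)
        return frozenset(self._g.successors(concept_id))

    def children(self, concept_id: str) -> frozenset[str]:
        self._require(concept_id)
        return frozenset(self._g.predecessors(concept_id))

    def roots(self) -> frozenset[str]:
        """Concepts with no parents (subhierarchy tops and the global root)."""
        return frozenset(n for n in self._g if self._g.out_degree(n) == 0)

    def _require(self, concept_id: str) -> None:
        if concept_id not in self._concepts:
            raise LookupError_(f"unknown concept {concept_id!r}")

    # -- closures ----------------------------------------------------------

    def ancestors_inclusive(self, concept_id: str) -> frozenset[str]:
        """``c^`` — the concept plus everything reachable via child->parent edges."""
        self._require(concept_id)
        cached = self._anc_cache.get(concept_id)
        if cached is None:
            cached = frozenset(nx.descendants(self._g, concept_id)) | {concept_id}
            self._anc_cache[concept_id] = cached
        return cached

    def descendants_inclusive(self, concept_id: str) -> frozenset[str]:
        """The concept plus everything that reaches it via child->parent edges."""
        self._require(concept_id)
        cached = self._desc_cache.get(concept_id)
        if cached is None:
            cached = frozenset(nx.ancestors(self._g, concept_id)) | {concept_id}
            self._desc_cache[concept_id] = cached
        return cached

    def has_path(self, c1: str, c2: str) -> bool:
        """True iff ``c1`` reaches ``c2`` via one or more is-a edges (``c1 != c2``)."""
        self._require(c1)
        self._require(c2)
        return c1 != c2 and c2 in self.ancestors_inclusive(c1)

    # -- mutation (value semantics) ---------------------------------------

    def _replace_edges(self, edges: Iterable[IsAEdge]) -> "TerminologyGraph":
        return TerminologyGraph(
            self._concepts.values(), edges, self.version_label, self.inactive_ids
        )

    def remove_edge(self, child: str, parent: str) -> "TerminologyGraph":
        """Return a new graph without the edge ``child -> parent``."""
        if not self._g.has_edge(child, parent):
            raise LookupError_(f"edge ({child!r} -> {parent!r}) not in graph")
        return self._replace_edges(
            IsAEdge(c, p) for c, p in self._g.edges() if (c, p) != (child, parent)
        )

    def add_edge(self, child: str, parent: str) -> "TerminologyGraph":
        """Return a new graph with the edge added; rejects cycles and duplicates."""
        self._require(child)
        self._require(parent)
        if self._g.has_edge(child, parent):
            raise ValidationError(f"edge ({child!r} -> {parent!r}) already present")
        edges = [IsAEdge(c, p) for c, p in self._g.edges()]
        edges.append(IsAEdge(child, parent))
        return self._replace_edges(edges)

    def __repr__(self) -> str:
        return (
            f"TerminologyGraph({self.n_concepts} concepts, {self.n_edges} edges"
            + (f", version={self.version_label!r})" if self.version_label else ")")
        )


# -- module-level functional surface --------------------------------------


def ancestors_inclusive(g: TerminologyGraph, c: str) -> frozenset[str]:
    return g.ancestors_inclusive(c)


def descendants_inclusive(g: TerminologyGraph, c: str) -> frozenset[str]:
    return g.descendants_inclusive(c)


def remove_edge(g: TerminologyGraph, e: IsAEdge) -> TerminologyGraph:
    return g.remove_edge(e.child, e.parent)


def has_path(g: TerminologyGraph, c1: str, c2: str) -> bool:
    return g.has_path(c1, c2)


# -- readers / writers -----------------------------------------------------


def load_rf2(
    concept_file: str | Path,
    relationship_file: str | Path,
    is_a_type_id: str = SNOMED_IS_A,
    version_label: str = "",
) -> TerminologyGraph:
    """Load an RF2-lite snapshot (concept + relationship TSV files).

    Only active concepts are retained; only active relationship rows whose
    ``typeId`` equals ``is_a_type_id`` become edges.  Edges whose endpoint is
    an explicitly inactive concept are dropped (inactive concepts carry no
    is-a edges); an endpoint absent from the concept file is a validation
    error.
    """
    con = pd.read_csv(concept_file, sep="\t", dtype=str)
    rel = pd.read_csv(relationship_file, sep="\t", dtype=str)
    for col in ("id", "active"):
        if col not in con.columns:
            raise ValidationError(f"concept file lacks required column {col!r}")
    for col in ("sourceId", "destinationId", "typeId", "active"):
        if col not in rel.columns:
            raise ValidationError(f"relationship file lacks required column {col!r}")

    active_mask = con["active"] == "1"
    active_ids = set(con.loc[active_mask, "id"])
    inactive_ids = set(con.loc[~active_mask, "id"])
    known = active_ids | inactive_ids

    rel = rel[(rel["active"] == "1") & (rel["typeId"] == is_a_type_id)]
    unknown = rel[~rel["sourceId"].isin(known) | ~rel["destinationId"].isin(known)]
    if len(unknown):
        offenders = [
            f"({r.sourceId}->{r.destinationId})" for r in unknown.head(10).itertuples()
        ]
        raise ValidationError(
            f"{len(unknown)} relationship row(s) reference concepts absent from the "
            f"concept file: {', '.join(offenders)}"
        )
    rel = rel[rel["sourceId"].isin(active_ids) & rel["destinationId"].isin(active_ids)]

    concepts = [Concept(cid) for cid in sorted(active_ids)]
    edges = [IsAEdge(r.sourceId, r.destinationId) for r in rel.itertuples()]
    return TerminologyGraph(concepts, edges, version_label, inactive_ids)


def write_rf2(
    g: TerminologyGraph, concept_file: str | Path, relationship_file: str | Path
) -> None:
    """Write an RF2-lite snapshot round-trippable through :func:`load_rf2`."""
    rows = [
        {"id": cid, "effectiveTime": "20230901", "active": "1",
         "moduleId": "0", "definitionStatusId": "0"}
        for cid in sorted(g.concept_ids)
    ] + [
        {"id": cid, "effectiveTime": "20230901", "active": "0",
         "moduleId": "0", "definitionStatusId": "0"}
        for cid in sorted(g.inactive_ids)
    ]
    pd.DataFrame(rows, columns=_RF2_CONCEPT_COLUMNS).to_csv(
        concept_file, sep="\t", index=False
    )
    rel_rows = [
        {"id": str(i + 1), "effectiveTime": "20230901", "active": "1", "moduleId": "0",
         "sourceId": e.child, "destinationId": e.parent, "relationshipGroup": "0",
         "typeId": SNOMED_IS_A, "characteristicTypeId": "0", "modifierId": "0"}
        for i, e in enumerate(g.edges())
    ]
    pd.DataFrame(rel_rows, columns=_RF2_RELATIONSHIP_COLUMNS).to_csv(
        relationship_file, sep="\t", index=False
    )


def load_edge_list(edge_file: str | Path, version_label: str = "") -> TerminologyGraph:
    """Load a generic two-column (child_id, parent_id) edge list.

    Optional columns ``child_name``, ``parent_name`` and ``subhierarchy``
    supply labels; concepts are inferred from edge endpoints.
    """
    df = pd.read_csv(edge_file, dtype=str)
    for col in ("child_id", "parent_id"):
        if col not in df.columns:
            raise ValidationError(f"edge list lacks required column {col!r}")
    names: dict[str, str] = {}
    tags: dict[str, str] = {}
    for r in df.itertuples():
        if r.child_id == r.parent_id:
            raise ValidationError(f"self-loop row on concept {r.child_id!r}")
        if "child_name" in df.columns and isinstance(r.child_name, str):
            names[r.child_id] = r.child_name
        if "parent_name" in df.columns and isinstance(r.parent_name, str):
            names[r.parent_id] = r.parent_name
        if "subhierarchy" in df.columns and isinstance(r.subhierarchy, str):
            tags[r.parent_id] = r.subhierarchy
    ids = sorted(set(df["child_id"]) | set(df["parent_id"]))
    concepts = [
        Concept(cid, names.get(cid, cid), subhierarchy=tags.get(cid)) for cid in ids
    ]
    edges = [IsAEdge(r.child_id, r.parent_id) for r in df.itertuples()]
    return TerminologyGraph(concepts, edges, version_label)
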