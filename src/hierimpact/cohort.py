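"""Diagnosis records, code mappings, and the concept->patient inverted index.

An atomic cohort query "identify patients diagnosed with concept c" returns
every patient carrying a diagnosis code that resolves to c or any descendant
of c.  Records may be coded directly in the standard vocabulary (SNOMED) or in
source vocabularies (ICD-9-CM, ICD-10-CM) that are resolved through
OHDSI-style "maps to" rows; one source code may map to several standard
concepts, and unmappable records are dropped and counted.

All cardinalities are patient-level: a patient diagnosed with several
descendants of c counts once in |N_c|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import ConfigurationError, LookupError_
from .terminology import TerminologyGraph

logger = logging.getLogger(__name__)

#: Default label of the standard (terminology-native) vocabulary.
STANDARD_VOCABULARY = "SNOMED"


@dataclass(frozen=True)
class DiagnosisRecord:
    patient_id: str
    code: str
    vocabulary: str

    def __post_init__(self) -> None:
        if not self.patient_id or not self.code:
            raise ConfigurationError("diagnosis record needs non-empty patient_id and code")


@dataclass(frozen=True)
class MappingEntry:
    """One "maps to" row: (source_code, source_vocabulary) -> target_concept."""

    source_code: str
    source_vocabulary: str
    target_concept: str


@dataclass
class MappedRecords:
    """Outcome of mapping resolution: kept (patient, concept) pairs + drop count."""

    pairs: list[tuple[str, str]]
    n_dropped: int
    n_input: int


@dataclass
class CohortIndex:
    """Inverted index from concept to the set of patients directly diagnosed with it."""

    postings: dict[str, frozenset[str]]
    n_patients: int
    n_dropped_records: int = 0

    def direct_patients(self, concept_id: str) -> frozenset[str]:
        return self.postings.get(concept_id, frozenset())


@dataclass(frozen=True)
class CohortResult:
    concept: str
    patients: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.patients)


def apply_mappings(
    records: Iterable[DiagnosisRecord],
    mappings: Iterable[MappingEntry],
    graph: TerminologyGraph | None = None,
    standard_vocabulary: str = STANDARD_VOCABULARY,
) -> MappedRecords:
    """Resolve diagnosis records to (patient_id, concept_id) pairs.

    Standard-vocabulary records pass through when their code is a concept of
    ``graph`` (always, if no graph is given).  Source-vocabulary records emit
    one pair per matching mapping row — one-to-many mappings fan out.  Records
    with no resolution are dropped and counted.  A record whose vocabulary is
    neither the standard label nor any mapping's source vocabulary raises
    :class:`ConfigurationError`.
    """
    by_source: dict[tuple[str, str], list[str]] = {}
    known_vocabs = {standard_vocabulary}
    for m in mappings:
        known_vocabs.add(m.source_vocabulary)
        by_source.setdefault((m.source_code, m.source_vocabulary), []).append(
            m.target_concept
        )

    pairs: list[tuple[str, str]] = []
    n_dropped = 0
    n_input = 0
    for rec in records:
        n_input += 1
        if rec.vocabulary not in known_vocabs:
            raise ConfigurationError(
                f"unknown vocabulary {rec.vocabulary!r} (known: {sorted(known_vocabs)})"
            )
        if rec.vocabulary == standard_vocabulary:
            targets = [rec.code]
        else:
            targets = by_source.get((rec.code, rec.vocabulary), [])
        if graph is not None:
            targets = [t for t in targets if t in graph]
        if targets:
            pairs.extend((rec.patient_id, t) for t in targets)
        else:
            n_dropped += 1
    logger.info(
        "mapped %d/%d records (%d dropped as unmappable)",
        n_input - n_dropped, n_input, n_dropped,
    )
    return MappedRecords(pairs=pairs, n_dropped=n_dropped, n_input=n_input)


def build_index(
    pairs: Iterable[tuple[str, str]], n_dropped_records: int = 0
) -> CohortIndex:
    """Build the concept->patient-set index; duplicate pairs collapse."""
    acc: dict[str, set[str]] = {}
    patients: set[str] = set()
    for patient_id, concept_id in pairs:
        acc.setdefault(concept_id, set()).add(patient_id)
        patients.add(patient_id)
    return CohortIndex(
        postings={c: frozenset(s) for c, s in acc.items()},
        n_patients=len(patients),
        n_dropped_records=n_dropped_records,
    )


def cohort_query(idx: CohortIndex, g: TerminologyGraph, c: str) -> CohortResult:
    """Answer the atomic query for ``c``: union of postings over its inclusive descendants."""
    if c not in g:
        raise LookupError_(f"unknown concept {c!r}")
    patients: set[str] = set()
    for d in g.descendants_inclusive(c):
        patients |= idx.postings.get(d, frozenset())
    return CohortResult(concept=c, patients=frozenset(patients))


# -- CSV interfaces --------------------------------------------------------


def read_diagnosis_csv(path: str | Path) -> list[DiagnosisRecord]:
    """Read a diagnosis table with columns patient_id, code, vocabulary."""
    df = pd.read_csv(path, dtype=str)
    return [
        DiagnosisRecord(r.patient_id, r.code, r.vocabulary) for r in df.itertuples()
    ]


def read_mapping_csv(path: str | Path) -> list[MappingEntry]:
    """Read a mapping table with columns source_code, source_vocabulary, target_concept_id."""
    df = pd.read_csv(path, dtype=str)
    return [
        MappingEntry(r.source_code, r.source_vocabulary, r.target_concept_id)
        for r in df.itertuples()
    ]


def write_diagnosis_csv(records: Iterable[DiagnosisRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.patient_id, r.code, r.vocabulary) for r in records],
        columns=["patient_id", "code", "vocabulary"],
    ).to_csv(path, index=False)


def write_mapping_csv(mappings: Iterable[MappingEntry], path: str | Path) -> None:
    pd.DataFrame(
        [(m.source_code, m.source_vocabulary, m.target_concept) for m in mappings],
        columns=["source_code", "source_vocabulary", "target_concept_id"],
    ).to_csv(path, index=False)
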