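"""Synthetic terminologies, diagnosis populations, mappings, and planted defects.

Every other module is testable offline against fixtures generated here with
known ground truth.  The generator emulates the structural features the impact
analyses assume:

* a polyhierarchy — a layered DAG in which each non-root concept has one or
  more parents drawn from strictly shallower layers (acyclic by construction),
  with at least two root concepts acting as subhierarchy tops;
* heavy-tailed per-concept diagnosis prevalence (Zipf-like), so a few concepts
  dominate the records while most are rare, as in real EHR data;
* a mix of standard-vocabulary and source-vocabulary records, the latter
  resolved through a generated mapping table, plus a small unmappable fraction
  to exercise the drop path;
* planted defects with recorded ground truth: missing relations realized by
  deleting edges (no surviving alternate path), inaccurate relations by
  inserting acyclic non-edges.

All output is fully determined by the configuration, including its seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np

from .cohort import DiagnosisRecord, MappingEntry, write_diagnosis_csv, write_mapping_csv
from .curation import write_defect_csv
from .errors import GenerationError
from .impact import DefectRelation
from .terminology import Concept, IsAEdge, TerminologyGraph, write_rf2


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic study universe.

    Defaults give a desk-scale polyhierarchy (a few hundred concepts, a few
    thousand patients) with the heavy-tailed prevalence and mapped-code mix
    the assessment pipeline expects.
    """

    n_concepts: int = 300
    n_layers: int = 6
    max_parents: int = 3
    n_patients: int = 2000
    mean_dx_per_patient: float = 4.0
    prevalence_skew: float = 1.2  # Zipf-like exponent over prevalence ranks
    frac_source_coded: float = 0.3  # fraction of records re-coded in a source vocabulary
    frac_unmappable: float = 0.02  # fraction of records given codes with no mapping
    n_missing_defects: int = 20
    n_inaccurate_defects: int = 20
    seed: int = 20230901
    source_vocabulary: str = "SRC"
    standard_vocabulary: str = "SNOMED"

    def __post_init__(self) -> None:
        if min(self.n_concepts, self.n_layers, self.max_parents, self.n_patients) < 1:
            raise GenerationError("all structural counts must be positive")
        for frac in (self.frac_source_coded, self.frac_unmappable):
            if not 0.0 <= frac <= 1.0:
                raise GenerationError("fractions must lie in [0, 1]")


def _concept_id(i: int) -> str:
    return str(1000000 + i)


def generate_terminology(cfg: SynthConfig) -> TerminologyGraph:
    """Generate a layered is-a DAG with >= 2 subhierarchy tops (when possible)."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_concepts
    n_roots = min(2, n)
    n_layers = min(cfg.n_layers, n)
    # layer 0 holds the roots; remaining concepts spread over deeper layers
    layers: list[list[int]] = [list(range(n_roots))]
    rest = list(range(n_roots, n))
    if rest:
        cuts = np.array_split(np.array(rest), max(1, n_layers - 1))
        layers.extend(list(chunk) for chunk in cuts if len(chunk))

    concepts = []
    for layer_idx, layer in enumerate(layers):
        for j, i in enumerate(layer):
            tag = f"Subhierarchy {chr(ord('A') + j)}" if layer_idx == 0 else None
            concepts.append(
                Concept(_concept_id(i), f"Concept {_concept_id(i)}", subhierarchy=tag)
            )

    edges: list[IsAEdge] = []
    shallower: list[int] = list(layers[0])
    for layer in layers[1:]:
        pool = np.array(shallower)
        for i in layer:
            k = int(rng.integers(1, cfg.max_parents + 1))
            k = min(k, pool.size)
            parents = rng.choice(pool, size=k, replace=False)
            edges.extend(IsAEdge(_concept_id(i), _concept_id(int(p))) for p in parents)
        shallower.extend(layer)

    return TerminologyGraph(concepts, edges, version_label=f"synthetic-{cfg.seed}")


def generate_population(
    cfg: SynthConfig, g: TerminologyGraph
) -> tuple[list[DiagnosisRecord], list[MappingEntry]]:
    """Generate patient diagnosis records plus a mapping table.

    Per-concept prevalence follows a Zipf-like law over a random rank
    permutation of the concepts; each patient receives a Poisson number of
    diagnoses drawn from that distribution.  A ``frac_source_coded`` share of
    records is re-expressed in a synthetic source vocabulary (with a complete
    mapping back), and a ``frac_unmappable`` share gets codes with no mapping.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    ids = sorted(g.concept_ids)
    ranks = rng.permutation(len(ids)) + 1
    weights = 1.0 / np.power(ranks, cfg.prevalence_skew)
    weights /= weights.sum()

    mappings = [
        MappingEntry(f"S-{cid}", cfg.source_vocabulary, cid) for cid in ids
    ]
    records: list[DiagnosisRecord] = []
    counts = rng.poisson(cfg.mean_dx_per_patient, size=cfg.n_patients)
    for pi, k in enumerate(counts):
        patient = f"P{pi:05d}"
        if k == 0:
            continue
        drawn = rng.choice(len(ids), size=int(k), replace=True, p=weights)
        for ci in drawn:
            cid = ids[int(ci)]
            u = rng.random()
            if u < cfg.frac_unmappable:
                records.append(
                    DiagnosisRecord(patient, f"X-{cid}", cfg.source_vocabulary)
                )
            elif u < cfg.frac_unmappable + cfg.frac_source_coded:
                records.append(
                    DiagnosisRecord(patient, f"S-{cid}", cfg.source_vocabulary)
                )
            else:
                records.append(DiagnosisRecord(patient, cid, cfg.standard_vocabulary))
    return records, mappings


@dataclass
class PlantedTruth:
    """Ground truth for one planted defect: the closures brute-force checks need."""

    defect: DefectRelation
    ancestors_of_super: list[str]  # c2^ in the defective graph
    descendants_of_sub: list[str]  # c1's inclusive descendants in the defective graph


def plant_defects(
    cfg: SynthConfig, g: TerminologyGraph, max_retries: int = 200
) -> tuple[TerminologyGraph, list[DefectRelation], list[PlantedTruth]]:
    """Plant missing and inaccurate defects into ``g``.

    Missing defects delete edges whose removal leaves no alternate path from
    child to parent (so the missing-relation precondition holds in the
    defective graph); inaccurate defects insert acyclic non-edges.  Returns
    the defective graph, the defect list, and per-defect truth closures.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    g_def = g
    defects: list[DefectRelation] = []

    # -- missing: delete edges, rejecting removals with a surviving path
    candidates = g_def.edges()
    rng.shuffle(candidates)  # type: ignore[arg-type]
    planted = 0
    tried = 0
    for e in candidates:
        if planted >= cfg.n_missing_defects:
            break
        if not g_def.has_edge(e.child, e.parent):
            continue
        g_try = g_def.remove_edge(e.child, e.parent)
        tried += 1
        if g_try.has_path(e.child, e.parent):
            continue
        # keep the hierarchy connected enough to stay interesting: allow
        # orphaned children (they become extra roots), which mirrors what a
        # genuinely missing relation looks like
        g_def = g_try
        defects.append(DefectRelation(e.child, e.parent, "missing", provenance="planted"))
        planted += 1
    if planted < cfg.n_missing_defects:
        raise GenerationError(
            f"could only plant {planted}/{cfg.n_missing_defects} missing defects "
            f"after {tried} candidate removals"
        )

    # -- inaccurate: insert acyclic non-edges that do not reconnect a planted
    # missing pair (which would invalidate its no-path precondition)
    missing_pairs = [(d.subconcept, d.superconcept) for d in defects]
    ids = sorted(g.concept_ids)
    planted = 0
    for _ in range(max_retries * max(1, cfg.n_inaccurate_defects)):
        if planted >= cfg.n_inaccurate_defects:
            break
        c1, c2 = (ids[int(i)] for i in rng.integers(0, len(ids), size=2))
        if c1 == c2 or g_def.has_edge(c1, c2):
            continue
        if g_def.has_path(c2, c1):  # adding c1->c2 would close a cycle
            continue
        g_try = g_def.add_edge(c1, c2)
        if any(g_try.has_path(m1, m2) for m1, m2 in missing_pairs):
            continue
        g_def = g_try
        defects.append(DefectRelation(c1, c2, "inaccurate", provenance="planted"))
        planted += 1
    if planted < cfg.n_inaccurate_defects:
        raise GenerationError(
            f"could only plant {planted}/{cfg.n_inaccurate_defects} inaccurate defects"
        )

    truth = [
        PlantedTruth(
            defect=d,
            ancestors_of_super=sorted(g_def.ancestors_inclusive(d.superconcept)),
            descendants_of_sub=sorted(g_def.descendants_inclusive(d.subconcept)),
        )
        for d in defects
    ]
    return g_def, defects, truth


def write_fixture_set(cfg: SynthConfig, out_dir: str | Path) -> dict[str, str]:
    """Generate and write the full fixture set into ``out_dir``.

    Writes RF2-lite concept/relationship files for the defective terminology,
    diagnosis and mapping CSVs, the defect CSV, truth JSON, and the resolved
    configuration; returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g = generate_terminology(cfg)
    records, mappings = generate_population(cfg, g)
    g_def, defects, truth = plant_defects(cfg, g)

    paths = {
        "concepts": str(out / "sct2_Concept_Snapshot.txt"),
        "relationships": str(out / "sct2_Relationship_Snapshot.txt"),
        "diagnoses": str(out / "diagnoses.csv"),
        "mappings": str(out / "mappings.csv"),
        "defects": str(out / "defects.csv"),
        "truth": str(out / "truth.json"),
        "config": str(out / "synth_config.json"),
        "reference_concepts": str(out / "reference" / "sct2_Concept_Snapshot.txt"),
        "reference_relationships": str(out / "reference" / "sct2_Relationship_Snapshot.txt"),
    }
    write_rf2(g_def, paths["concepts"], paths["relationships"])
    (out / "reference").mkdir(exist_ok=True)
    write_rf2(g, paths["reference_concepts"], paths["reference_relationships"])
    write_diagnosis_csv(records, paths["diagnoses"])
    write_mapping_csv(mappings, paths["mappings"])
    write_defect_csv(defects, paths["defects"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            [
                {
                    "subconcept": t.defect.subconcept,
                    "superconcept": t.defect.superconcept,
                    "defect_type": t.defect.defect_type,
                    "ancestors_of_super": t.ancestors_of_super,
                    "descendants_of_sub": t.descendants_of_sub,
                }
                for t in truth
            ],
            fh,
            indent=1,
        )
    with open(paths["config"], "w") as fh:
        json.dump(asdict(cfg), fh, indent=1)
    return paths
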