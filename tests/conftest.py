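import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))

from hierimpact import (
    SynthConfig,
    apply_mappings,
    build_index,
    generate_population,
    generate_terminology,
    plant_defects,
)
from hierimpact.terminology import Concept, IsAEdge, TerminologyGraph


def make_graph(edges, extra_concepts=(), inactive=()):
    """Build a graph straight from (child, parent) string pairs."""
    ids = sorted({c for e in edges for c in e} | set(extra_concepts))
    return TerminologyGraph(
        [Concept(i) for i in ids],
        [IsAEdge(c, p) for c, p in edges],
        inactive_ids=inactive,
    )


@pytest.fixture(scope="session")
def chain():
    return make_graph([("a", "b"), ("b", "c")])


@pytest.fixture(scope="session")
def diamond():
    return make_graph([("a", "b"), ("a", "c"), ("b", "d"), ("c", "d")])


@pytest.fixture(scope="session")
def synth_world():
    """A full seeded synthetic study universe shared across tests.

    Returns (cfg, clean graph, defective graph, defects, truth, index,
    resolved pairs); the pairs feed the brute-force oracles.
    """
    cfg = SynthConfig(
        n_concepts=150,
        n_patients=500,
        n_missing_defects=20,
        n_inaccurate_defects=20,
        seed=20230901,
    )
    g = generate_terminology(cfg)
    records, mappings = generate_population(cfg, g)
    g_def, defects, truth = plant_defects(cfg, g)
    mapped = apply_mappings(records, mappings, g_def)
    idx = build_index(mapped.pairs, n_dropped_records=mapped.n_dropped)
    return cfg, g, g_def, defects, truth, idx, mapped.pairs
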