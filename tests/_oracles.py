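"""Independent brute-force oracles used to cross-check the implementation.

Everything here works from raw edge lists and raw (patient, concept) pairs —
no TerminologyGraph, no CohortIndex — so agreement with the package is a
genuine dual-route check.
"""

from __future__ import annotations

import itertools
from statistics import mean

import numpy as np
from scipy.stats import rankdata


def fixpoint_ancestors(edges: list[tuple[str, str]], c: str) -> set[str]:
    """Inclusive ancestor closure by repeated single-step parent expansion."""
    out = {c}
    changed = True
    while changed:
        changed = False
        for child, parent in edges:
            if child in out and parent not in out:
                out.add(parent)
                changed = True
    return out


def fixpoint_descendants(edges: list[tuple[str, str]], c: str) -> set[str]:
    return fixpoint_ancestors([(p, ch) for ch, p in edges], c)


def naive_cohorts(
    edges: list[tuple[str, str]],
    concepts: set[str],
    pairs: list[tuple[str, str]],
) -> dict[str, set[str]]:
    """Patient set of every atomic query, by scanning each patient's diagnoses.

    A patient belongs to the cohort of c iff some diagnosed concept has c in
    its inclusive ancestor closure.
    """
    anc_cache: dict[str, set[str]] = {}
    cohorts: dict[str, set[str]] = {c: set() for c in concepts}
    for patient, diagnosed in pairs:
        if diagnosed not in anc_cache:
            anc_cache[diagnosed] = fixpoint_ancestors(edges, diagnosed)
        for c in anc_cache[diagnosed]:
            cohorts[c].add(patient)
    return cohorts


def brute_impact(
    edges: list[tuple[str, str]],
    concepts: set[str],
    pairs: list[tuple[str, str]],
    c1: str,
    c2: str,
    kind: str,
) -> tuple[float, float]:
    """(micro, macro) by explicit set arithmetic; NaN when every term is 0/0."""
    cohorts = naive_cohorts(edges, concepts, pairs)
    n_c1 = cohorts[c1]
    terms: list[tuple[int, int, float]] = []  # (numerator, denominator, ratio)
    for p in fixpoint_ancestors(edges, c2):
        n_p = cohorts[p]
        if kind == "missing":
            num, den = len(n_p), len(n_c1 | n_p)
        else:
            num, den = len(n_p - n_c1), len(n_p)
        if den > 0:
            terms.append((num, den, num / den))
    if not terms:
        return float("nan"), float("nan")
    micro = sum(t[0] for t in terms) / sum(t[1] for t in terms)
    macro = mean(t[2] for t in terms)
    return micro, macro


def enumerate_wilcoxon_less(values: list[float]) -> float:
    """Exact one-sided p-value for 'median < 1' by full 2^n sign enumeration.

    Requires tie-free |differences| with no value equal to 1.
    """
    d = np.asarray(values, dtype=float) - 1.0
    assert np.all(d != 0)
    ranks = rankdata(np.abs(d))
    t_obs = ranks[d > 0].sum()
    n = d.size
    count = 0
    for signs in itertools.product((False, True), repeat=n):
        t = sum(r for r, pos in zip(ranks, signs) if pos)
        if t <= t_obs:
            count += 1
    return count / 2**n
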