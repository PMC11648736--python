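"""Statistical testing of impact metrics and simulated-defect sampling.

The no-impact null is that the median micro- (or macro-) averaged metric over
a defect set equals 1; the one-sided alternative is that it is below 1.  The
test is the Wilcoxon signed-rank test on differences d = metric − 1: NA
metrics are excluded, zero differences dropped, and the p-value is exact for
small tie-free samples and a tie- and continuity-corrected normal
approximation otherwise.

Simulated defects are existing is-a edges sampled uniformly without
replacement: a sampled edge assessed on the graph with that edge removed plays
a missing relation; assessed in place it plays an inaccurate one.  Cochran's
formula with finite-population correction gives the sample size such a
simulation needs for a chosen confidence level and margin of error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .cohort import CohortIndex
from .errors import ConfigurationError, DegenerateInputError, PreconditionError
from .impact import DefectRelation, ImpactResult, is_na, precision_impact, recall_impact
from .terminology import TerminologyGraph

#: Largest tie-free effective sample size for which the exact null distribution
#: of the signed-rank statistic is used; beyond it the corrected normal
#: approximation applies (the study-scale sets of hundreds of defects all do).
EXACT_THRESHOLD = 25


@dataclass(frozen=True)
class WilcoxonResult:
    """One-sided signed-rank test of 'median metric < 1'."""

    statistic: float
    p_value: float
    n_input: int
    n_effective: int
    method: Literal["exact", "normal"]
    alternative: str = "less than 1"


def wilcoxon_vs_one(
    values: Iterable[float],
    zero_method: Literal["wilcox", "pratt"] = "wilcox",
    exact_threshold: int = EXACT_THRESHOLD,
) -> WilcoxonResult:
    """Test whether the median of ``values`` is below 1.

    Parameters
    ----------
    values:
        Micro- or macro-averaged metrics; NA entries (NaN/None) are excluded.
    zero_method:
        Treatment of values exactly equal to 1: ``"wilcox"`` (default) drops
        them before ranking, ``"pratt"`` keeps them in the ranking.
    exact_threshold:
        Use the exact null distribution when the effective sample size is at
        most this and |d| has no ties; otherwise the normal approximation
        with tie and continuity corrections.

    Raises
    ------
    DegenerateInputError
        If every value is NA, or every value equals 1 (no information about
        the median's direction).
    """
    clean = np.asarray([v for v in values if not is_na(v)], dtype=float)
    n_input = clean.size
    if n_input == 0:
        raise DegenerateInputError("all metric values are NA; test undefined")
    d = clean - 1.0
    nonzero = d[d != 0.0]
    n_effective = int(nonzero.size)
    if n_effective == 0:
        raise DegenerateInputError("all metric values equal 1; test undefined")

    has_ties = np.unique(np.abs(nonzero)).size < n_effective
    has_zeros = n_effective < n_input
    # Pratt's method keeps zeros in the ranking; scipy's exact distribution
    # does not cover that case, so fall back to the approximation there.
    use_exact = (
        n_effective <= exact_threshold
        and not has_ties
        and (zero_method == "wilcox" or not has_zeros)
    )
    res = stats.wilcoxon(
        d if zero_method == "pratt" else nonzero,
        zero_method=zero_method,
        alternative="less",
        correction=not use_exact,
        method="exact" if use_exact else "approx",
    )
    return WilcoxonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_input=n_input,
        n_effective=n_effective,
        method="exact" if use_exact else "normal",
    )


def sample_simulated_defects(
    g: TerminologyGraph,
    n: int,
    defect_type: Literal["missing", "inaccurate"],
    seed: int,
) -> list[DefectRelation]:
    """Sample ``n`` distinct existing edges uniformly without replacement.

    Each sampled edge (c1, c2) is recorded as a defect of the requested type:
    a simulated missing relation is later assessed on the graph with the edge
    removed; a simulated inaccurate one is assessed with the edge in place.
    """
    edges = g.edges()
    if n > len(edges):
        raise ConfigurationError(f"cannot sample {n} edges from a graph with {len(edges)}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(edges), size=n, replace=False)
    return [
        DefectRelation(edges[i].child, edges[i].parent, defect_type, provenance="simulated")
        for i in chosen
    ]


def assess_simulated(
    idx: CohortIndex,
    g: TerminologyGraph,
    defects: Sequence[DefectRelation],
) -> list[ImpactResult]:
    """Assess simulated defects with the edge-removal semantics for missing ones.

    For a simulated missing relation the sampled edge is removed before
    assessment, so N_p reflects its absence; an alternate surviving path is
    allowed and simply yields metrics of 1 (no impact).  Simulated inaccurate
    relations are assessed on the graph as-is.
    """
    results: list[ImpactResult] = []
    for d in defects:
        if d.defect_type == "missing":
            if not g.has_edge(d.subconcept, d.superconcept):
                raise PreconditionError(
                    f"simulated missing defect ({d.subconcept!r} -> {d.superconcept!r}) "
                    "must correspond to an existing edge"
                )
            g2 = g.remove_edge(d.subconcept, d.superconcept)
            results.append(recall_impact(idx, g2, d, check_preconditions=False))
        else:
            results.append(precision_impact(idx, g, d))
    return results


def cochran_sample_size(confidence: float, margin: float, population: int) -> int:
    """Cochran's sample size with finite-population correction.

    ``n0 = z^2 p(1-p) / margin^2`` with maximal variance ``p = 0.5`` and ``z``
    the two-sided normal quantile for the confidence level, then
    ``n = n0 / (1 + (n0 - 1)/population)``, rounded up.
    """
    if not 0 < confidence < 1:
        raise ConfigurationError(f"confidence must be in (0, 1), got {confidence}")
    if not 0 < margin < 1:
        raise ConfigurationError(f"margin must be in (0, 1), got {margin}")
    if population < 1:
        raise ConfigurationError(f"population must be >= 1, got {population}")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    n0 = z * z * 0.25 / (margin * margin)
    n = n0 / (1.0 + (n0 - 1.0) / population)
    return math.ceil(n)


def stats_report(
    metrics_by_name: dict[str, Sequence[float]],
    seed: int | None = None,
) -> dict:
    """Run the median-vs-1 test per metric series and return a JSON-ready report."""
    report: dict = {}
    for name, values in metrics_by_name.items():
        try:
            r = wilcoxon_vs_one(values)
            entry = {
                "statistic": r.statistic,
                "p_value": r.p_value,
                "n_input": r.n_input,
                "n_effective": r.n_effective,
                "method": r.method,
                "alternative": r.alternative,
            }
        except DegenerateInputError as exc:
            entry = {"error": str(exc)}
        report[name] = entry
    if seed is not None:
        report["seed"] = seed
    return report
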