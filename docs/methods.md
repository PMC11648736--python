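# Methods

## Model of the problem

A terminology's subtype backbone is modelled as a directed acyclic graph over
active concepts with child → parent is-a edges. The two closures that drive
everything are inclusive: `ancestors_inclusive(c)` contains `c` itself plus
everything reachable via parent edges (the set of queries a defect at `c`
impacts, written `c↑`), and `descendants_inclusive(c)` is its mirror (the set
of codes an atomic cohort query for `c` retrieves). The atomic query is purely
diagnostic membership: a patient is in `N_c` iff any of their diagnosis codes
resolves to a concept in `descendants_inclusive(c)`. There are no dates,
visits, or Boolean compositions; composite queries are out of scope.

All cardinalities are distinct-patient counts, not record counts. Source
vocabulary codes (ICD-9-CM / ICD-10-CM style) resolve through "maps to" rows;
one-to-many mappings fan out to every target, because collapsing them would
silently remove patients from cohorts. Records that resolve to nothing — no
mapping row, or a standard-vocabulary code that is not an active concept in
the loaded graph — are dropped and counted, never silently discarded. The
inverted index is a plain in-memory dict of concept → frozen patient set;
query cost is a union over the descendant closure. That is deliberately the
simplest structure satisfying the query contract — production event-level
indexes solve a scale problem this package does not have.

## Impact metrics

For a missing relation c1 is-a c2, assessed on a graph in which no path
c1 ⇒ c2 exists, the query for each p ∈ c2↑ has recall |N_p| / |N_c1 ∪ N_p|;
for an inaccurate relation, assessed with the edge present, precision
|N_p − N_c1| / |N_p|. Micro averaging sums numerators and denominators over
c2↑ before dividing (patient-weighted); macro averaging takes the unweighted
mean of per-query ratios (query-weighted).

Numerical conventions:

* a per-query term with denominator 0 is NA; NA terms are excluded from both
  the micro sums and the macro mean, and the aggregate is NA exactly when
  every term is NA. Whether undefined terms should instead be imputed is
  genuinely open; exclusion is this package's declared convention and is
  consistent with publishing NA for defects whose concepts retrieve no
  patients at all;
* precision subtracts the whole of N_c1 even when some of its patients reach
  p through legitimate alternate paths — the formula is applied literally,
  with no path-aware correction;
* c2↑ is computed on the assessment graph as given. This is unambiguous:
  adding or removing the edge c1 → c2 changes c1's ancestors, never c2's
  (a change would require a path c2 ⇒ c1, i.e. a cycle). A regression test
  pins this down;
* metrics are kept at full float precision internally and rounded to 4
  decimals only in serialized CSV output, where NA is written literally.

Preconditions are enforced: assessing a "missing" relation whose path in fact
exists, or an "inaccurate" relation whose edge is absent, raises; in batch
mode such failures are captured per defect without aborting the batch.

## Curation

Rectification filtering removes a defect only on positive evidence from the
reference release: a missing relation is rectified when both concepts are
active there and a path exists; an inaccurate relation when either concept is
explicitly retired or both are active and the direct edge is gone. A concept
entirely absent from the reference is treated as unknown → the defect is kept
and a warning logged. Loaders therefore retain the set of explicitly inactive
concept ids alongside the active graph. Subhierarchy restriction keeps a
defect when both its concepts lie in the union of the inclusive descendant
closures of the chosen top concepts (the union reading is a declared choice;
in practice defect lists live inside single subhierarchies, where the two
readings coincide). Provenance labels are opaque and pass through untouched.

## Statistical testing

The no-impact null is that the median micro- (or macro-) averaged metric
equals 1; the alternative is one-sided, median < 1. The signed-rank test
forms d = metric − 1, excludes NA values, drops zero differences (classic
Wilcoxon treatment; Pratt's zero-rank method is available by flag, the choice
left open by the underlying analyses), and midranks tied |d|. The p-value is
exact when the effective n is ≤ 25 with tie-free |d|, otherwise a normal
approximation with tie and continuity corrections; all study-scale inputs
(hundreds of defects) fall in the approximation regime, and a guard test
checks the two regimes agree within 0.02 for n ≤ 12. The exact path is
verified against full 2ⁿ sign enumeration in the tests.

Simulated defects sample existing edges uniformly without replacement under a
recorded seed. A simulated missing relation is assessed on the graph with the
sampled edge removed; when the child still reaches the parent through an
alternate path the defect correctly shows no impact (all metrics exactly 1),
so the strict no-path precondition is relaxed for this mode only. Cochran's
sample size uses maximal variance p = 0.5 and the two-sided normal quantile
(1.96 at 95%), then the finite-population correction, rounded up — giving 384
for 5% margin over a population of 370 014.

## Synthetic data

The generator emulates what the assessment pipeline assumes about real data:

* **terminology**: a layered DAG — concepts are assigned to layers, each
  non-root draws 1..`max_parents` parents from strictly shallower layers,
  which guarantees acyclicity by construction and gives controllable depth
  (closure sizes drive micro-vs-macro divergence). Layered construction was
  chosen over rejection-sampled random DAGs for exactly those two properties.
  At least two roots act as subhierarchy tops;
* **population**: per-concept prevalence is Zipf-like (default exponent 1.2
  over a random rank permutation), each patient receives a Poisson number of
  diagnoses (default mean 4), so a few concepts dominate while most are rare,
  as in real EHR diagnosis tables. A configurable fraction of records
  (default 0.3) is re-expressed in a synthetic source vocabulary with a
  complete mapping table, plus a small unmappable fraction (default 0.02) so
  the drop path is always exercised;
* **defects**: missing relations are planted by deleting edges whose removal
  leaves no alternate path (so the no-path precondition holds in the
  defective graph); inaccurate relations by inserting acyclic non-edges that
  do not reconnect a planted missing pair. Ground truth records the closures
  needed for brute-force verification.

Everything is a pure function of the configuration, including its seed.

What the generator does **not** emulate: visit/temporal structure, comorbidity
correlations between concepts, realistic code-assignment noise, or any
disease-specific epidemiology. Passing tests therefore demonstrate the
correctness of the metric machinery and pipeline plumbing on structurally
realistic inputs, not empirical conclusions about any particular EHR dataset.

## Problem sizes and verification

The test suite and acceptance script run at desk scale as a deliberate design
point: oracle-equivalence checks use 150 concepts / 500 patients / 40 planted
defects against a brute-force implementation that materializes every patient
set (agreement to 1e-12); end-to-end recovery uses a 120-concept fixture
round-tripped through RF2-lite files; the simulated analysis samples 400
relations from a 400-concept / 4000-patient universe, mirroring the published
sample-size calculation, and both micro and macro medians reject the
no-impact null far below α = 0.001. Full-scale terminology releases and
licensed EHR datasets are inputs the package accepts but does not ship.

## Known limitations

* Only the is-a backbone is modelled: no attribute relationships, role
  groups, or description-logic classification, and no full RF2 (descriptions,
  refsets, languages).
* Ancestor traversal runs to the roots by default; stopping at a subhierarchy
  top is possible by restricting the graph, not by a traversal flag.
* Handling of records coded in non-standard or inactive standard-vocabulary
  codes (drop + count) is a documented default, not an inferred intent of any
  upstream dataset.
* Mutating operations copy the graph; this is a value-semantics convenience
  appropriate for desk-scale simulation, not an at-scale design.
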