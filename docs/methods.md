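# Methods

## Model

`hfacsbn` couples the four-level HFACS incident-causation taxonomy with a
discrete Bayesian network.  The structure is fixed by the taxonomy, not
learned: every factor at level L+1 is a direct parent of every factor at
level L ("layered completeness"), factors within a level share no edges, and
nothing skips a level.  This encodes two modelling assumptions: (i) causal
influence flows strictly downward through adjacent organizational layers,
and (ii) factors at the same layer are conditionally independent given the
layer above.  Both are simplifications — in reality supervision failures can
feed back into organizational climate, and same-level factors co-occur for
reasons other than shared upstream causes — but they keep every CPT small
enough to estimate from double-digit case counts and make the model's
claims auditable.

The default network has twelve nodes.  Ten are binary (yes/no) presence
indicators: resource management (RM), organizational climate (OC),
organizational process (OP) at level 4; inadequate supervision (IS),
planned inappropriate operations (PIO), failure to correct known problems
(FCP), supervisory violations (SV) at level 3; condition of operators (CO),
personnel factors (PF), environmental factors (EF) at level 2.  The unsafe
acts at level 1 are two multi-state nodes rather than five binary ones: the
error type ERR ∈ {skill, decision, perception, none} and the violation type
VIO ∈ {routine, exceptional, none}.  Modelling subtypes as mutually
exclusive states asserts that one incident carries at most one error type
and one violation type; the named subtypes (SBE, DE, PE, RV, EV) appear
downstream as *rows* of the sensitivity matrix, not as nodes.  Alternative
layered taxonomies (different node sets per level) are accepted by the
validator so other facilities can adapt the structure; free-form DAGs are
not.

Level numbering runs bottom-up (1 = unsafe acts, 4 = organizational
influences), matching how sensitivity tables are conventionally laid out in
this literature.

## Estimation

CPTs are learned from complete codings only.  For node state s and parent
configuration c with counts n_{s|c}:

    P(s | c) = (n_{s|c} + α) / (Σ_{s'} n_{s'|c} + α·|states|)

* **α (pseudo-count), default 1.**  Dirichlet add-one smoothing.  With a
  few dozen cases and 16-row CPTs, many parent configurations are observed
  a handful of times; α = 1 keeps those rows away from degenerate 0/1
  estimates that would propagate as false certainty.  α = 0 gives the pure
  MLE; parent configurations never observed then get a uniform row, flagged
  in the results' provenance so downstream users can see which parts of the
  model are prior-only.
* **Missing cells.**  The default policy rejects a database containing an
  empty node cell ("strict"); an opt-in "drop-record" policy skips the row
  with a logged warning.  There is no EM-style missing-data learning —
  incident coding is a deliberate human step that yields complete
  assignments, and silently imputing factor presence would change the
  meaning of the learned tables.

## Inference

Inference is exact.  Queries run variable elimination over dense factors
with a min-degree elimination heuristic, ties broken lexicographically by
node code; the answer is provably independent of elimination order, and the
test suite verifies agreement (to 1e-9 absolute) with brute-force
enumeration of the full joint, which at 12,288 states is cheap enough to
serve as an oracle.  Conditioning is observational evidence propagation —
asserting a node's state and reading posteriors elsewhere — not a
do-intervention; with a layered DAG and a single asserted upper factor the
distinction only matters through the upper factor's own co-parents, and the
observational reading matches how such networks are interrogated in
practice.  Evidence with probability zero under the model raises a
dedicated error naming the assertion.  All probability arithmetic is
ordinary double precision; comparisons in tests use absolute tolerance
1e-9 unless a test states otherwise.

## Sensitivity statistic

For an upper binary factor x_i and a lower factor occurrence state x_j:

    S_ij = (p1 − p0) / p0   if p1 ≥ p0, else 0,
    p1 = P(x_j | x_i = yes),  p0 = P(x_j | x_i = no)

— a truncated relative risk change.  "Occurrence" means state "yes" for
binary factors and one named subtype state for ERR/VIO.  Negative changes
are truncated to zero rather than reported, so the statistic ranks
*promoting* influences only.  If p0 = 0 while p1 > 0 the ratio is
undefined: the scalar call raises, and bulk outputs record NA with a
warning (a fitted model with α > 0 never produces this).  The matrix
computes every pair with the upper factor's level strictly above the
lower's, including non-adjacent levels, through full network propagation.
The overall score per upper factor is the mean over the three error states
and, separately, the two violation states; values are non-negative by
construction so this equals the absolute mean.  Full precision is kept
internally; half-up rounding to 2 decimals (configurable) applies only to
rendered tables.

## Synthetic data generator

The generator exists because coded incident databases behind published
analyses are typically not deposited.  It emulates the *statistical* shape
of such data: 12 factor columns drawn by ancestral sampling from a known
layered network, plus phase/error-type labels drawn from the packaged
81-incident phase-by-error-type count table (16 categories).  It does not
emulate reporter behaviour — under-reporting, severity mixes, correlated
coding errors, free-text narratives — so tests passing on synthetic data
demonstrate correctness of the estimation/inference machinery, not validity
of any substantive conclusion about real incidents.

The packaged ground truth is hand-authored.  Each CPT row has an additive
parent-effect form: P(occurs | parents) = base + Σ increments over parents
present.  Because the form is linear in parent indicators, each node's
exact marginal is computable in closed form by linearity of expectation,
and the coefficients were chosen analytically — before any sampling — so
that the five marginals with published values land inside ±0.05 of them:
skill-based errors 37.5%, condition of operators 49.6%, personnel factors
59.8%, inadequate supervision 57.6%, organizational climate 25.3%
(the packaged truth gives 0.370, 0.496, 0.602, 0.576, 0.253).  Marginals
without published values are set to plausible mid-range rates respecting
the published orderings (e.g. routine violations above exceptional).

Randomness: a single master integer seed; each node samples from its own
substream whose seed material mixes the master seed with a CRC-32 of the
node code, so adding a node to the network never perturbs the sampled
columns of existing nodes.  Identical spec + seed reproduces a
byte-identical CSV.

## Parameter recovery

`recovery_experiment` samples n incidents from a ground truth, refits with
`fit_cpts`, and reports the total-variation distance (half the L1
difference) between every true and refitted CPT row together with the
row's observation count.  The headline number is the max TV over rows
observed at least 50 times.

Two statistical facts shape how the tests use this harness, established by
binomial concentration before the tests were frozen:

* A row observed ~50 times has standard error up to 0.5/√50 ≈ 0.071, so
  the *max* TV over the ~95 qualifying rows at n = 5000 is dominated by the
  least-observed rows and concentrates around 0.10–0.15 — a max-TV
  criterion of 0.05 at this threshold is unattainable for any
  non-degenerate truth (the chance that all rows land within 0.05 is
  ~10⁻⁶).  The unit tests therefore bound the headline by the 3σ
  concentration value 0.25 at the ≥50-observation threshold, and check
  0.05 recovery only for rows observed ≥400 times.  One acceptance-level
  test retains the stricter 0.05/≥50 form and is expected to fail; it is
  kept as an honest record rather than weakened.
* The headline max is not monotone in n: growing n pushes ever-rarer,
  noisier rows over the 50-observation threshold, so the max over the
  qualifying set typically *rises* even as every individual row improves.
  The monotonicity test therefore uses the mean TV over all rows, which
  decreases robustly (checked over 5 seed pairs).

Problem sizes used throughout the suite — 12,288-state enumeration oracles,
20 random-model seeds, recovery at n = 200/5000, marginal-concentration
checks at n = 10,000 — were chosen as the smallest sizes at which the
statistical assertions have comfortable margins.

## Known limitations

* Structure is fixed; no structure learning, no cross-level or within-level
  edges, no continuous or temporal nodes.
* Complete-case learning only.
* Observational conditioning only; interventional ("do") semantics are out
  of scope.
* The sensitivity statistic is a relative measure: a rare lower factor with
  a tiny baseline can show a large S_ij from a small absolute change.
  Ranking by S alone inherits that property from the definition.
* Exact inference only — appropriate at this scale, but the implementation
  makes no attempt at approximate inference for substantially larger
  layered taxonomies.
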