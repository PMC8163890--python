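# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `lbpdesign`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Function profiling

A therapeutic function is encoded as one or more *marker groups* of annotation
terms. Within a group any term may match (alternative enzymes for the same
step); by default **all** groups must match (`min_groups_required = None`),
reflecting that a multi-step pathway needs every step. A term matches an
annotation feature by case-insensitive substring on the product text or by
exact match against controlled-vocabulary term ids. This is deliberately a
term-list approach, not HMM-based protein family search: it operates on
consistently annotated genomes where product strings are comparable across
strains, and it fails conservatively (absent annotation ⇒ absent function).
Every positive call records its evidence (group, term, feature id) so presence
is re-derivable from the inputs.

Exclusion screening uses the same matcher against two fixed categories,
`transferable_AMR` and `virulence_factor`, with small default term lists
shipped as YAML (`src/lbpdesign/data/exclusion_terms.yaml`). The lists are a
starting point, not a safety review; mobile-element context, for example, is
out of scope.

### GUT-103 / GUT-108 fixtures

The two packaged fixtures encode only what the published consortium overview
tables print. Each printed mark expands to a representative product phrase
(e.g. a butyrate "+" becomes "butyrate kinase", the code `CGH` becomes
"choloylglycine hydrolase"), and the expanded tables flow through the same
profiling machinery as any annotation table. Because the underlying marker
genes live in unpublished supplementary data, the expansion phrases are
stand-ins for the printed codes, chosen to match the shipped catalog exactly
and nothing else. Fixture candidates have no metabolic models; community and
complementarity checks must stay disabled when verifying them, and the
verification report records which checks ran.

## Average nucleotide identity

`compute_ani` follows the fragment-based (ANIb-style) convention:

* the query genome is cut into consecutive non-overlapping fragments of
  **1020 bp** (trailing remainder dropped; multi-record genomes are fragmented
  per record and never concatenated);
* each fragment is anchored in the subject by exact 16-mer seeding on both
  strands; seed hits vote for diagonals, and the top 3 diagonal clusters are
  evaluated;
* the fragment is aligned glocally (full query against a subject window
  extended by the **60 bp** band) with edlib; identity is
  `1 − edit_distance / fragment_length`;
* fragments pass when identity ≥ **0.30** and coverage ≥ **0.70**. Because the
  glocal alignment consumes the whole fragment once anchored, the coverage
  filter operationally rejects *unanchored* fragments — sequences with no
  seedable homology (e.g. shuffled controls) produce zero passing fragments
  and a flagged, undefined ANI rather than a spurious low value;
* directional ANI is the mean identity of passing fragments, the symmetric ANI
  is the mean of the two directions, and `aligned_fraction` is the passing
  fraction of fragments.

Two genomes are called distinct species when `1 − ANI > 0.10` (the 10%
whole-genome difference rule). On substitution-only synthetic pairs the
positional mismatch count of the un-fragmented pair is an exact oracle; the
tests require mean recovered divergence within ±0.01 of the planted rate over
seeds and near-symmetry (|ANI(a,b) − ANI(b,a)| ≤ 0.005). Edit-distance
alignment can explain a few substitutions as cheaper indel pairs, giving a
small (≪0.01) downward bias in recovered divergence at high divergence; this
is inherent to alignment-based ANI. The genome generator is i.i.d. uniform
DNA — no gene structure, repeats, or GC skew — so the ANI tests demonstrate
calibration of the estimator, not performance on repeat-rich real genomes.

## Constraint-based modeling

Models follow COBRA conventions: exchange reactions touch exactly one
extracellular metabolite with coefficient −1, uptake is a negative exchange
lower bound set from the medium, secretion bounds default to +1000
(unconstrained within numerics). FBA maximizes biomass flux subject to
steady state `S·v = 0` and bounds, solved with HiGHS via
`scipy.optimize.linprog`. Growth is declared at biomass flux ≥ **1e-6**
(`GROWTH_THRESHOLD`); reported optima must satisfy the steady state within
1e-6 and bounds within 1e-8. Alternate optimal flux distributions are not
disambiguated: only the objective value and status are contract-bound.

**Gapfilling** returns a minimum-total-penalty subset of a universal reaction
database (default penalty 1.0 per reaction, ids disjoint from the model)
whose addition lifts growth above threshold. For databases of ≤ 12 reactions
the search enumerates subsets in increasing (penalty, lexicographic id) order
— exact, with a deterministic tie-break, and directly checkable against the
full-enumeration oracle in the tests. Larger databases fall back to a big-M
indicator MILP (`scipy.optimize.milp`), which is penalty-optimal but does not
guarantee the lexicographic tie-break. Infeasible gapfills return the best
biomass objective attained as a certificate.

**Auxotrophy detection** probes each compound c (named by its extracellular
id, as media name compounds): the strain is auxotrophic for c when it grows on
the complete medium, fails on the complete medium minus c, and grows again
with c restored. Producibility attaches a temporary demand (sink) reaction —
preferring the cytosolic counterpart (`x_e → x_c`) so intracellular synthesis
counts without an exporter — and asks for demand flux > 1e-6 on the c-free
medium. Auxotrophy therefore implies not-produced on the same medium context.
Probes absent from the model namespace are recorded as `not_probed`.

## Community modeling

`merge_models` namespaces every member metabolite/reaction with
`<strain_id>__`, converts each member exchange into a member↔pool transfer
reaction (bounds ±1000, positive flux = secretion), and gives the shared pool
the only environment exchanges, bounded by the medium. Members are weighted
equally; there is no biomass-ratio coupling, because no abundances exist at
design time.

Two objectives are provided and labeled. `max_total` maximizes summed member
biomass; `max_min` maximizes an auxiliary variable t subject to every member
biomass ≥ t. **`max_min` is the default** because the design claim is that
*all* members grow as a consortium — a max-total optimum happily reports a
community where one member carries everything. A singleton community reduces
to individual FBA under both schemes (tested to 1e-6).

The strain-interaction table reports net member↔pool transfer fluxes at the
reported optimum (secretion > 1e-6, uptake < −1e-6) and dependency edges by
pairwise removal: edge (i, j, m) is recorded when member i can reach the
growth threshold (maximizing its own biomass) with j present but not with j's
reactions clamped to zero, *and* m is secreted by j and consumed by i at the
optimum. The metabolite condition keeps edges direct: in a feeding chain
A→B→C, C fails without A but shares no compound with A, so no (C, A, ·) edge
is recorded. Removal-based detection was chosen over flux-coupling analysis
because it is directly testable against constructed toys. Dropout analysis
re-runs max-min community FBA after removing each member, flags collapse
(any remaining member below threshold), and joins a function profile to list
required functions no longer covered.

## Consortium selection

The published design states its constraints (functional redundancy,
complementary auxotrophies, exclusion of unsafe strains, community viability)
but not a selection algorithm; the selector here is the package's own
declared procedure, built to be reproducible and oracle-checkable:

1. **Filter** exclusion-flagged strains (optional, on by default).
2. **Greedy set-multicover**: repeatedly add the strain with the largest
   marginal coverage of unmet (function, redundancy-target) demand; ties break
   by fewer own auxotrophies, then lexicographic strain id. Unsatisfiable
   redundancy fails fast, naming the limiting function.
3. **Repair**: while any member's auxotrophic compound is secretable by fewer
   than k co-members, add the outside strain covering the most unmet
   (member, compound) needs (same tie-break).
4. **Prune** in reverse addition order, removing any strain whose removal
   preserves all constraints (including viability when enabled) — so every
   remaining member is load-bearing and pruning twice changes nothing.
5. **Viability** (optional): community max-min growth ≥ 1e-6 on the working
   medium.

`default_selection_constraints()` packages the recommended defaults —
redundancy target 2 per required function (one dropout never uncovers a
function) and complementarity degree k = 1 (every auxotrophy covered by at
least one co-member); the `SelectionConstraints` dataclass itself stays
neutral (k = 0) so profile-only candidate sets, which carry no models or
secretion data, verify without vacuously failing complementarity.

"Complemented" means the co-member's model can *secrete* the compound on the
working medium (max exchange flux > 1e-6), not merely produce it
intracellularly — cross-feeding requires export. Candidates are sorted by
strain id before selection, and the full procedure is deterministic given
inputs and seed (the seed is recorded in the trace; no stage currently draws
randomness). Greedy multicover is not optimal in general; `exhaustive_select`
(pools ≤ 15) provides the minimum-cardinality oracle, and the tests require
greedy feasibility whenever the oracle is feasible. `verify_consortium`
recomputes every constraint from scratch, plus a dropout-robustness check
(after any single removal, every required function still covered ≥ 1) when
all redundancy targets are ≥ 2.

## qPCR quantification

Template abundance scales as `efficiency^(−Ct)` with efficiency fixed at 2
(the doubling assumption of the printed comparative-Ct formulas; configurable
for sensitivity analyses). Composition normalizes the weights within a
sample, so it is invariant to adding a constant to every Ct. Targets below
the detection limit map to abundance 0 — no floor or imputation — and an
all-missing sample is an all-zero row flagged `no_detection`. Expression fold
change is `2^(−((Ct_t,case − Ct_ref,case) − (Ct_t,ctrl − Ct_ref,ctrl)))`.
Normalization is within-sample only; per-strain input-DNA normalization is
out of scope.

## Synthetic universes

The generator emulates the structural assumptions of the design analysis: all
strains share a core metabolism (one common substrate → a biomass precursor);
each community compound has a two-reaction biosynthesis chain; biomass
consumes the precursor plus every compound. Planting an auxotrophy deletes
that strain's chain and downgrades its transporter to uptake-only; producers
keep a reversible exporter. Under the **cyclic** plan strain i is auxotrophic
for compound `i mod m` (strain i+1 retains that chain), so every singleton
fails on the minimal medium (substrate only, uptake 10 mmol·gDW⁻¹·h⁻¹ by
default) while the full cycle grows — the obligate-interdependence topology
the community tests exercise. The **random-with-guarantee** plan draws
auxotrophies i.i.d. at the configured rate (default 0.3 per strain×compound)
and then guarantees every compound at least one producing strain, so the full
pool is always a feasible consortium. Planted functions are i.i.d. (p = 0.5)
with a ≥ 2-carriers guarantee per function, matching the redundancy the
dropout tests assume. Annotation tables carry one marker phrase per planted
function plus noise rows; genomes are i.i.d. uniform DNA.

All randomness flows from the spec seed through a single numpy Generator, and
every emitted universe is verified against its own truth labels (growth on
the complete medium, detected = planted auxotrophies, and cyclic synergy)
before being returned — a spec that cannot satisfy its guarantee raises at
generation time rather than emitting silently. `mutate_genome` is
substitution-only by default so the positional mismatch count is an exact
divergence oracle; indel-containing evaluation is deliberately excluded from
the oracle tests.

What the synthetic universes do **not** emulate: genome-scale network size
and redundancy (real reconstructions have thousands of reactions and
alternate pathways), annotation noise and mis-annotation, partial pathway
loss, realistic media chemistry, or abundance dynamics. Passing the planted
recovery tests therefore demonstrates the correctness of the inference
machinery on its stated assumptions, not its accuracy on real genomes.

## Problem sizes and numerical choices

Test and acceptance runs use 20-kb genomes for ANI, universes of up to 20
strains × 6 compounds, universal databases ≤ 12 reactions (where gapfill is
brute-force verifiable), and selection pools ≤ 12 candidates (where the
exhaustive oracle is cheap) — sizes chosen so every claim is checkable
against full enumeration while the whole suite runs in minutes on one CPU.
LP tolerances: steady-state residual ≤ 1e-6 at reported optima, bounds within
1e-8, growth threshold 1e-6, secretion/uptake call threshold 1e-6. Fixture
presence/absence is exact (no tolerances). The max-min LP's auxiliary
variable equals the reported minimum member growth within 1e-6 at any
optimum.
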