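# lbpdesign

Rational, bottom-up design of live biotherapeutic products (LBPs): defined
consortia of commensal gut bacteria assembled to restore therapeutic functions
(short-chain fatty acids, indole derivatives, secondary bile acids,
siderophore-mediated iron competition, bacteriocins) that are under-represented
in the dysbiotic microbiome of IBD patients. The package implements the
computational side of that design process for microbiome researchers and
consortium engineers:

* **Function profiling** — match strain annotation tables (TSV/GFF3) against a
  marker-term catalog of therapeutic functions; screen candidates against
  transferable-AMR and virulence term lists.
* **Species delimitation** — fragment-based average nucleotide identity (ANI):
  1020-bp fragments, k-mer-seeded banded glocal alignment, identity/coverage
  filters; two genomes are distinct species when `1 − ANI > 0.10`.
* **Constraint-based modeling** — flux balance analysis
  (maximize biomass `c·v` s.t. `S·v = 0`, `lb ≤ v ≤ ub`, HiGHS LP), exact
  minimum-penalty gapfilling against a universal reaction database, and
  auxotrophy detection by single-omission growth tests plus demand-reaction
  producibility.
* **Community simulation** — compartmentalized merge of strain models around a
  shared extracellular pool; community FBA under `max_total` (summed biomass)
  or `max_min` (maximize t with every member's growth ≥ t); strain-interaction
  tables (secretion/uptake and pairwise-removal dependency edges) and
  single-dropout robustness.
* **Consortium selection** — greedy set-multicover with repair and pruning
  under function-redundancy targets r_f, auxotrophy-complementarity degree k,
  exclusion screening, and community-viability constraints, with an exhaustive
  minimum-cardinality oracle for small pools.
* **qPCR quantification** — community composition by the comparative Ct method
  (weights `2^−Ct`, normalized within sample) and expression fold change by
  `2^−ΔΔCt`.
* **Synthetic universes** — generators for annotation tables, toy metabolic
  models with planted auxotrophies and secretion capabilities, mutated genome
  pairs at known divergence, and Ct tables from known compositions, so every
  stage is testable against planted ground truth without downloads.

The packaged `gut103` (17 strains) and `gut108` (11 strains) fixtures encode
the printed function/enzyme assignments of the two published consortium
overview tables (bile-acid enzyme codes CGH, 3α/7α/7β-HSD, 7α/β-DH, 3α-DH,
3-oxo-5α, LCD, SBS; SCFA/GABA/indole marks; siderophore and bacteriocin
notes). The fixtures carry no metabolic models, so model-dependent checks are
disabled when verifying them.

## Worked example

```python
from lbpdesign.fixtures import load_fixture, HEADLINE_FUNCTIONS
from lbpdesign.catalog import redundancy_counts
from lbpdesign.designer import SelectionConstraints, verify_consortium

gut108 = load_fixture("gut108")
print(len(gut108))                                   # 11
print(redundancy_counts(gut108.profile, {"dh_7ab"})) # {'dh_7ab': 2}
required = {f: 1 for f in HEADLINE_FUNCTIONS["gut108"]}
report = verify_consortium(
    gut108.strain_ids, gut108,
    SelectionConstraints(required_functions=required, forbid_flagged=False),
)
print(report.passes)                                 # True
```

The optimized 11-strain table carries two 7α/β-dehydratase-capable strains —
the redundancy added for secondary bile-acid (DCA/LCA) synthesis — and covers
every headline therapeutic function at least once.

The community-synergy prediction on a synthetic universe:

```python
from lbpdesign.synthetic import UniverseSpec, generate_universe
from lbpdesign.fba import fba
from lbpdesign.community import merge_models, community_fba

u = generate_universe(UniverseSpec(n_strains=3, n_compounds=3, plan="cyclic", seed=1))
print([fba(u.models[s], u.minimal_medium).objective_value for s in u.strains])
# [0.0, 0.0, 0.0]  — every strain fails alone
com = merge_models([u.models[s] for s in u.strains], u.minimal_medium)
print(community_fba(com, "max_min").objective_value)
# 0.8333333333333334  — the consortium grows by cross-feeding
```

## Analysis scripts

Numbered drivers under `analysis/` re-run each stage end to end and write
tables under `results/`:

1. `01_profile_consortium_tables.py` — fixture function matrices, redundancy,
   headline-coverage verification
2. `02_delimit_species_by_ani.py` — ANI divergence sweep and species calls
3. `03_infer_auxotrophies.py` — planted-auxotrophy recovery
4. `04_simulate_community_interdependence.py` — singleton vs community growth,
   interaction table, dropout robustness
5. `05_design_consortia.py` — selector benchmark vs the exhaustive oracle and
   a full profile→auxotrophy→selection pipeline
6. `06_quantify_composition_qpcr.py` — comparative-Ct composition recovery and
   ΔΔCt worked examples

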