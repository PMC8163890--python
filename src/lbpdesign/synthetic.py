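"""Synthetic strain universes, genomes, and qPCR tables with planted truth.

The universe generator emulates the structural property the consortium-design
analysis relies on: a pool of strains sharing a core metabolism (one common
substrate feeding a biomass precursor) with one biosynthesis chain per
community compound.  Auxotrophies are planted by deleting a strain's chain for
a compound; producers export their products, so the planted configuration
creates a network of metabolically interdependent strains.  Under the cyclic
plan strain i is auxotrophic for compound i mod m while strain i+1 retains that
chain, so every singleton fails on the minimal medium and the full cycle grows
as a community.

All randomness flows from the spec seed through a single numpy Generator, and
every emitted universe is verified against its own truth labels (single-strain
FBA, auxotrophy detection, and — for the cyclic plan — community synergy)
before being returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .catalog import (
    AnnotationRow,
    AnnotationTable,
    FunctionCatalog,
    FunctionDef,
)
from .community import MAX_MIN, community_fba, merge_models
from .fba import GROWTH_THRESHOLD, detect_auxotrophies, fba
from .model import (
    CYTOSOL,
    EXTRACELLULAR,
    Medium,
    Metabolite,
    Reaction,
    StrainModel,
    UniversalReactionDB,
)
from .quant import CompositionTable, CtTable

CYCLIC = "cyclic"
RANDOM_GUARANTEED = "random-with-guarantee"

_BASES = "ACGT"


class GenerationError(RuntimeError):
    """A spec admitting no feasible consortium (never silently emitted)."""


@dataclass
class UniverseSpec:
    n_strains: int = 10
    n_compounds: int = 6
    n_functions: int = 6
    auxotrophy_rate: float = 0.3
    plan: str = CYCLIC
    marker_vocab_size: int = 40
    genome_length: int = 20000
    substrate_uptake: float = 10.0
    compound_uptake: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_strains, self.n_compounds, self.n_functions) < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.auxotrophy_rate <= 1.0:
            raise ValueError("auxotrophy_rate must be in [0, 1]")
        if self.plan not in (CYCLIC, RANDOM_GUARANTEED):
            raise ValueError(f"unknown complementarity plan {self.plan!r}")
        if self.plan == CYCLIC and (self.n_strains < 2 or self.n_compounds < 2):
            raise ValueError("cyclic plan needs >= 2 strains and >= 2 compounds")


@dataclass
class SyntheticUniverse:
    spec: UniverseSpec
    strains: list[str]
    models: dict[str, StrainModel]
    annotations: dict[str, AnnotationTable]
    genomes: dict[str, str]
    catalog: FunctionCatalog
    universal_db: UniversalReactionDB
    complete_medium: Medium
    minimal_medium: Medium
    probe_compounds: set[str]
    planted_auxotrophies: dict[str, set[str]]
    planted_functions: dict[str, set[str]]
    guaranteed_consortium: list[str] = field(default_factory=list)


def _compound_ids(n: int) -> list[str]:
    return [f"cmp{j:02d}" for j in range(n)]


def build_strain_model(
    strain_id: str,
    compounds: list[str],
    auxotrophic_for: set[str],
    substrate: str = "substrate",
) -> StrainModel:
    """One toy strain: shared substrate -> precursor -> biomass + compound chains.

    Producers carry a two-reaction biosynthesis chain and a reversible
    exporter per compound; auxotrophs lose the chain and keep an uptake-only
    transporter, so growth requires external supply.
    """
    mets = [
        Metabolite(f"{substrate}_e", "shared substrate", EXTRACELLULAR),
        Metabolite("prec_c", "biomass precursor", CYTOSOL),
    ]
    rxns = [
        Reaction(f"EX_{substrate}_e", {f"{substrate}_e": -1.0}, 0.0, 1000.0, is_exchange=True),
        Reaction("CORE", {f"{substrate}_e": -1.0, "prec_c": 1.0}, 0.0, 1000.0),
    ]
    biomass_stoich = {"prec_c": -1.0}
    for c in compounds:
        ce, cc = f"{c}_e", f"{c}_c"
        mets.append(Metabolite(ce, f"{c} (extracellular)", EXTRACELLULAR))
        mets.append(Metabolite(cc, f"{c} (cytosol)", CYTOSOL))
        rxns.append(Reaction(f"EX_{ce}", {ce: -1.0}, 0.0, 1000.0, is_exchange=True))
        if c in auxotrophic_for:
            # uptake-only transporter; biosynthesis chain deleted
            rxns.append(Reaction(f"T_{c}", {ce: -1.0, cc: 1.0}, 0.0, 1000.0))
        else:
            mets.append(Metabolite(f"{c}_i", f"{c} intermediate", CYTOSOL))
            rxns.append(Reaction(f"SYN1_{c}", {"prec_c": -1.0, f"{c}_i": 1.0}, 0.0, 1000.0))
            rxns.append(Reaction(f"SYN2_{c}", {f"{c}_i": -1.0, cc: 1.0}, 0.0, 1000.0))
            # reversible exporter: retained products can be secreted
            rxns.append(Reaction(f"T_{c}", {cc: -1.0, ce: 1.0}, -1000.0, 1000.0))
        biomass_stoich[cc] = -1.0
    rxns.append(Reaction("BIOMASS", biomass_stoich, 0.0, 1000.0, is_biomass=True))
    return StrainModel(
        strain_id=strain_id,
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id="BIOMASS",
    )


def _universal_db(compounds: list[str]) -> UniversalReactionDB:
    """Every biosynthesis chain, under db-namespaced reaction ids."""
    mets = []
    rxns = []
    for c in compounds:
        mets.append(Metabolite(f"{c}_i", f"{c} intermediate", CYTOSOL))
        rxns.append(Reaction(f"U_SYN1_{c}", {"prec_c": -1.0, f"{c}_i": 1.0}, 0.0, 1000.0))
        rxns.append(Reaction(f"U_SYN2_{c}", {f"{c}_i": -1.0, f"{c}_c": 1.0}, 0.0, 1000.0))
    return UniversalReactionDB(reactions=rxns, metabolites=mets)


def _plant_auxotrophies(spec: UniverseSpec, rng: np.random.Generator) -> list[set[str]]:
    compounds = _compound_ids(spec.n_compounds)
    if spec.plan == CYCLIC:
        return [{compounds[i % spec.n_compounds]} for i in range(spec.n_strains)]
    aux = [
        {c for c in compounds if rng.random() < spec.auxotrophy_rate}
        for _ in range(spec.n_strains)
    ]
    # guarantee: every compound keeps at least one producing (and hence
    # secreting) strain, so the full pool is a feasible consortium
    if spec.n_strains == 1 and any(aux[0]):
        raise GenerationError("single-strain universe cannot complement auxotrophies")
    for j, c in enumerate(compounds):
        producers = [i for i in range(spec.n_strains) if c not in aux[i]]
        if not producers:
            i = int(rng.integers(spec.n_strains))
            aux[i].discard(c)
    return aux


def _plant_functions(spec: UniverseSpec, rng: np.random.Generator) -> list[set[str]]:
    fids = [f"fn{k:02d}" for k in range(spec.n_functions)]
    planted = [
        {f for f in fids if rng.random() < 0.5} for _ in range(spec.n_strains)
    ]
    if spec.n_strains >= 2:
        # every function keeps >= 2 carriers so single-strain dropout never
        # uncovers a required function
        for f in fids:
            carriers = [i for i in range(spec.n_strains) if f in planted[i]]
            while len(carriers) < 2:
                i = int(rng.integers(spec.n_strains))
                if i not in carriers:
                    planted[i].add(f)
                    carriers.append(i)
    return planted


def _marker_catalog(spec: UniverseSpec) -> FunctionCatalog:
    defs = []
    for k in range(spec.n_functions):
        fid = f"fn{k:02d}"
        defs.append(
            FunctionDef(
                function_id=fid,
                display_name=f"synthetic function {k}",
                marker_groups=((f"{fid} synthase", f"{fid} ligase"),),
            )
        )
    return FunctionCatalog(defs)


def random_genome(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def mutate_genome(seq: str, divergence: float, seed: int) -> str:
    """Substitute each position independently with the given probability.

    Substitutions go to a uniformly chosen *different* base; no indels, so the
    positional mismatch count is an exact divergence oracle.
    """
    if not 0.0 <= divergence < 0.75:
        raise ValueError(f"divergence must be in [0, 0.75), got {divergence}")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < divergence
    for i in np.nonzero(hit)[0]:
        base = arr[i].decode()
        choices = [b for b in _BASES if b != base]
        arr[i] = rng.choice(choices).encode()
    return arr.tobytes().decode()


def _annotation_table(
    strain_id: str,
    functions: set[str],
    catalog: FunctionCatalog,
    rng: np.random.Generator,
    n_noise: int = 5,
) -> AnnotationTable:
    rows = []
    i = 0
    for fid in sorted(functions):
        group = catalog.get(fid).marker_groups[0]
        term = group[int(rng.integers(len(group)))]
        i += 1
        rows.append(AnnotationRow(f"{strain_id}_f{i:03d}", f"putative {term}"))
    for _ in range(n_noise):
        i += 1
        rows.append(AnnotationRow(f"{strain_id}_f{i:03d}", "hypothetical protein"))
    return AnnotationTable(strain_id=strain_id, rows=rows)


def generate_universe(spec: UniverseSpec, verify: bool = True) -> SyntheticUniverse:
    """Build a universe and verify its truth labels before returning it."""
    rng = np.random.default_rng(spec.seed)
    compounds = _compound_ids(spec.n_compounds)
    strains = [f"S{i:02d}" for i in range(spec.n_strains)]
    aux_plan = _plant_auxotrophies(spec, rng)
    fn_plan = _plant_functions(spec, rng)
    catalog = _marker_catalog(spec)

    models = {
        sid: build_strain_model(sid, compounds, aux_plan[i])
        for i, sid in enumerate(strains)
    }
    annotations = {
        sid: _annotation_table(sid, fn_plan[i], catalog, rng)
        for i, sid in enumerate(strains)
    }
    genomes = {sid: random_genome(spec.genome_length, rng) for sid in strains}

    probe = {f"{c}_e" for c in compounds}
    complete = Medium(
        {"substrate_e": spec.substrate_uptake, **{f"{c}_e": spec.compound_uptake for c in compounds}},
        name="complete",
    )
    minimal = Medium({"substrate_e": spec.substrate_uptake}, name="minimal")

    universe = SyntheticUniverse(
        spec=spec,
        strains=strains,
        models=models,
        annotations=annotations,
        genomes=genomes,
        catalog=catalog,
        universal_db=_universal_db(compounds),
        complete_medium=complete,
        minimal_medium=minimal,
        probe_compounds=probe,
        planted_auxotrophies={
            sid: {f"{c}_e" for c in aux_plan[i]} for i, sid in enumerate(strains)
        },
        planted_functions={sid: set(fn_plan[i]) for i, sid in enumerate(strains)},
        guaranteed_consortium=list(strains),
    )
    if verify:
        _verify_universe(universe)
    return universe


def _verify_universe(u: SyntheticUniverse) -> None:
    for sid in u.strains:
        sol = fba(u.models[sid], u.complete_medium)
        if not sol.grows:
            raise GenerationError(f"{sid} fails to grow on the complete medium")
        profile = detect_auxotrophies(u.models[sid], u.complete_medium, u.probe_compounds)
        if profile.auxotrophic_for != u.planted_auxotrophies[sid]:
            raise GenerationError(
                f"{sid}: detected auxotrophies {sorted(profile.auxotrophic_for)} "
                f"!= planted {sorted(u.planted_auxotrophies[sid])}"
            )
    if u.spec.plan == CYCLIC:
        for sid in u.strains:
            if fba(u.models[sid], u.minimal_medium).objective_value >= GROWTH_THRESHOLD:
                raise GenerationError(f"{sid} grows alone under the cyclic plan")
        com = merge_models([u.models[s] for s in u.strains], u.minimal_medium)
        sol = community_fba(com, MAX_MIN)
        if not (sol.status == "optimal" and sol.objective_value > GROWTH_THRESHOLD):
            raise GenerationError("cyclic community fails to grow as a consortium")


def serialize_universe(universe: SyntheticUniverse, directory) -> None:
    """Write models (JSON), annotations (TSV), genomes (FASTA), truth (JSON)."""
    import json
    import os

    from .model import write_model

    os.makedirs(directory, exist_ok=True)
    for sid in universe.strains:
        write_model(universe.models[sid], os.path.join(directory, f"{sid}.model.json"))
        with open(os.path.join(directory, f"{sid}.annotations.tsv"), "w") as fh:
            fh.write("feature_id\tproduct\tterms\n")
            for row in universe.annotations[sid].rows:
                fh.write(f"{row.feature_id}\t{row.product}\t{','.join(row.term_ids)}\n")
        with open(os.path.join(directory, f"{sid}.fasta"), "w") as fh:
            fh.write(f">{sid}\n")
            g = universe.genomes[sid]
            for i in range(0, len(g), 80):
                fh.write(g[i : i + 80] + "\n")
    truth = {
        "planted_auxotrophies": {
            s: sorted(v) for s, v in universe.planted_auxotrophies.items()
        },
        "planted_functions": {
            s: sorted(v) for s, v in universe.planted_functions.items()
        },
        "guaranteed_consortium": universe.guaranteed_consortium,
    }
    with open(os.path.join(directory, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Forward qPCR model


def simulate_ct(
    composition: CompositionTable,
    scale: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CtTable:
    """Ct_i = -log2(w_i) + scale + Normal(0, noise_sd); w_i = 0 => missing."""
    rng = np.random.default_rng(seed)
    ct: dict[str, float | None] = {}
    for target, w in composition.fractions.items():
        if w == 0.0:
            ct[target] = None
        else:
            ct[target] = -math.log2(w) + scale + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
    return CtTable(sample_id=composition.sample_id, ct=ct)


# ---------------------------------------------------------------------------
# Planted selection pools (designer test driver)


def generate_selection_pool(
    n_candidates: int,
    planted_size: int,
    seed: int,
    n_decoy_functions: int = 3,
):
    """A candidate pool whose unique minimum feasible set is planted.

    Each planted strain carries one anchor function no other strain has, so any
    feasible selection must contain the whole planted set; decoy functions are
    scattered over the pool.  Returns (CandidateSet, SelectionConstraints,
    planted ids).
    """
    from .designer import Candidate, CandidateSet, SelectionConstraints

    if planted_size > n_candidates:
        raise ValueError("planted_size exceeds the pool size")
    rng = np.random.default_rng(seed)
    ids = [f"C{i:02d}" for i in range(n_candidates)]
    planted = sorted(rng.choice(ids, size=planted_size, replace=False).tolist())
    anchors = {sid: f"anchor_{sid}" for sid in planted}
    decoys = [f"decoy{d}" for d in range(n_decoy_functions)]
    compounds = [f"cmp{j}" for j in range(4)]
    candidates = {}
    for sid in ids:
        functions = {anchors[sid]} if sid in anchors else set()
        functions |= {d for d in decoys if rng.random() < 0.5}
        aux = {c for c in compounds if rng.random() < 0.3}
        secretes = {c for c in compounds if c not in aux and rng.random() < 0.7}
        candidates[sid] = Candidate(
            strain_id=sid,
            functions=functions,
            auxotrophic_for=aux,
            secretes=secretes,
        )
    constraints = SelectionConstraints(
        required_functions={a: 1 for a in anchors.values()},
        complementarity_degree=0,
        forbid_flagged=False,
    )
    return CandidateSet(candidates=candidates), constraints, planted
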