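import numpy as np
import pytest

from lbpdesign.fba import (
    GROWTH_THRESHOLD,
    NOT_PRODUCED,
    PRODUCED,
    detect_auxotrophies,
    fba,
    gapfill,
    secretable_compounds,
    stoichiometric_matrix,
)
from lbpdesign.model import (
    Medium,
    Metabolite,
    ModelValidationError,
    Reaction,
    UniversalReactionDB,
)
from lbpdesign.synthetic import UniverseSpec, build_strain_model, generate_universe
from tests.conftest import make_chain_model
from tests.oracles import fba_oracle, gapfill_oracle


def test_chain_objective_equals_uptake_bound(chain_model, medium_a5):
    sol = fba(chain_model, medium_a5)
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(5.0, abs=1e-9)


def test_no_substrate_no_growth(chain_model):
    sol = fba(chain_model, Medium({}, name="empty"))
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(0.0, abs=1e-9)


def test_biomass_bound_is_the_bottleneck(medium_a5):
    sol = fba(make_chain_model(biomass_ub=2.0), medium_a5)
    assert sol.objective_value == pytest.approx(2.0, abs=1e-9)


def test_steady_state_and_bounds_hold_at_optimum(chain_model, medium_a5):
    from lbpdesign.model import apply_medium

    applied = apply_medium(chain_model, medium_a5)
    sol = fba(chain_model, medium_a5)
    v = np.array([sol.fluxes[r.id] for r in applied.reactions])
    S = stoichiometric_matrix(applied.reactions, sorted(applied.metabolite_ids))
    assert np.max(np.abs(S @ v)) <= 1e-6
    for r in applied.reactions:
        assert r.lower_bound - 1e-8 <= sol.fluxes[r.id] <= r.upper_bound + 1e-8


@pytest.mark.parametrize("seed", range(6))
def test_objective_matches_vertex_enumeration_oracle(seed):
    """FBA optimum equals exhaustive vertex enumeration on small networks."""
    rng = np.random.default_rng(seed)
    compounds = [f"cmp{j:02d}" for j in range(2)]
    aux = {c for c in compounds if rng.random() < 0.5}
    model = build_strain_model("toy", compounds, aux)
    medium = Medium(
        {
            "substrate_e": float(rng.integers(1, 10)),
            **{f"{c}_e": float(rng.integers(0, 5)) for c in compounds},
        }
    )
    got = fba(model, medium).objective_value
    expect = fba_oracle(model, medium)
    assert expect is not None
    assert got == pytest.approx(expect, abs=1e-6)


def test_objective_matches_cobra_on_chain_toy(medium_a5):
    """Independent cross-check of the LP path against cobrapy."""
    cobra = pytest.importorskip("cobra")
    m = cobra.Model("chain")
    mets = {
        "A_e": cobra.Metabolite("A_e", compartment="e"),
        "A_c": cobra.Metabolite("A_c", compartment="c"),
        "B_c": cobra.Metabolite("B_c", compartment="c"),
    }
    def rxn(rid, stoich, lb, ub):
        r = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
        r.add_metabolites({mets[k]: v for k, v in stoich.items()})
        return r
    m.add_reactions([
        rxn("EX_A_e", {"A_e": -1}, -5.0, 1000.0),
        rxn("T_A", {"A_e": -1, "A_c": 1}, 0.0, 1000.0),
        rxn("R_AB", {"A_c": -1, "B_c": 1}, 0.0, 1000.0),
        rxn("BIOMASS", {"B_c": -1}, 0.0, 1000.0),
    ])
    m.objective = "BIOMASS"
    ours = fba(make_chain_model(), medium_a5).objective_value
    assert ours == pytest.approx(m.optimize().objective_value, abs=1e-6)


@pytest.mark.parametrize("seed", range(15))
def test_raising_uptake_never_decreases_growth(seed):
    """Relaxing a medium constraint cannot hurt the optimum."""
    rng = np.random.default_rng(100 + seed)
    compounds = [f"cmp{j:02d}" for j in range(3)]
    aux = {c for c in compounds if rng.random() < 0.4}
    model = build_strain_model("toy", compounds, aux)
    uptake = {
        "substrate_e": float(rng.uniform(0, 10)),
        **{f"{c}_e": float(rng.uniform(0, 5)) for c in compounds},
    }
    base = fba(model, Medium(uptake)).objective_value
    for _ in range(3):
        key = rng.choice(sorted(uptake))
        bumped = dict(uptake)
        bumped[key] = uptake[key] + float(rng.uniform(0.5, 5))
        relaxed = fba(model, Medium(bumped)).objective_value
        assert relaxed >= base - 1e-8


# ---------------------------------------------------------------------------
# gapfilling


@pytest.fixture
def broken_strain():
    """A strain missing one biosynthesis chain, plus the universal db."""
    u = generate_universe(UniverseSpec(n_strains=2, n_compounds=2, seed=11))
    sid = u.strains[0]
    return u.models[sid], u.minimal_medium, u.universal_db


def test_gapfill_restores_growth_minimally(broken_strain):
    model, medium, db = broken_strain
    res = gapfill(model, medium, db)
    assert res.status == "optimal"
    assert fba(res.model, medium).objective_value >= GROWTH_THRESHOLD
    best_penalty, best_sets = gapfill_oracle(model, medium, db)
    assert res.penalty == pytest.approx(best_penalty)
    assert tuple(res.added_reactions) == min(best_sets)  # lexicographic tie-break


def test_gapfill_single_missing_reaction():
    mets = [
        Metabolite("A_e", compartment="extracellular"),
        Metabolite("A_c", compartment="cytosol"),
        Metabolite("B_c", compartment="cytosol"),
    ]
    rxns = [
        Reaction("EX_A_e", {"A_e": -1.0}, 0.0, 1000.0, is_exchange=True),
        Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}),
        Reaction("BIOMASS", {"B_c": -1.0}, is_biomass=True),
    ]
    from lbpdesign.model import StrainModel

    model = StrainModel("gap", mets, rxns, "BIOMASS")
    db = UniversalReactionDB(
        reactions=[
            Reaction("U_AB", {"A_c": -1.0, "B_c": 1.0}),
            Reaction("U_noise", {"A_c": -1.0}, 0.0, 0.0),
        ]
    )
    res = gapfill(model, Medium({"A_e": 5.0}), db)
    assert res.added_reactions == ["U_AB"]
    assert res.penalty == 1.0


def test_gapfill_already_growing_returns_empty(chain_model, medium_a5):
    db = UniversalReactionDB(reactions=[Reaction("U_x", {"A_c": -1.0, "B_c": 1.0})])
    res = gapfill(chain_model, medium_a5, db)
    assert res.status == "optimal" and res.added_reactions == []


def test_gapfill_infeasible_when_db_cannot_reach_biomass(broken_strain):
    model, medium, _ = broken_strain
    useless = UniversalReactionDB(
        reactions=[Reaction("U_loop", {"prec_c": -1.0, "prec_c2__x": 1.0})],
        metabolites=[Metabolite("prec_c2__x", compartment="cytosol")],
    )
    res = gapfill(model, medium, useless)
    assert res.status == "infeasible"
    assert res.best_objective < GROWTH_THRESHOLD


def test_gapfill_minimality_every_returned_reaction_is_needed(broken_strain):
    model, medium, db = broken_strain
    res = gapfill(model, medium, db)
    from lbpdesign.fba import _augment

    for rid in res.added_reactions:
        reduced = _augment(model, db, set(res.added_reactions) - {rid})
        assert fba(reduced, medium).objective_value < GROWTH_THRESHOLD


def test_gapfill_rejects_colliding_reaction_ids(chain_model, medium_a5):
    db = UniversalReactionDB(reactions=[Reaction("R_AB", {"A_c": -1.0, "B_c": 1.0})])
    with pytest.raises(ModelValidationError, match="collide"):
        gapfill(make_chain_model(biomass_ub=0.0), medium_a5, db)


# ---------------------------------------------------------------------------
# auxotrophy detection


def test_planted_auxotrophies_are_recovered_exactly():
    u = generate_universe(UniverseSpec(n_strains=4, n_compounds=3, seed=5), verify=False)
    for sid in u.strains:
        prof = detect_auxotrophies(u.models[sid], u.complete_medium, u.probe_compounds)
        assert prof.auxotrophic_for == u.planted_auxotrophies[sid]
        for c in u.probe_compounds:
            expected = NOT_PRODUCED if c in u.planted_auxotrophies[sid] else PRODUCED
            assert prof.producible[c] == expected


def test_prototroph_has_no_auxotrophies():
    model = build_strain_model("proto", ["cmp00", "cmp01"], set())
    medium = Medium({"substrate_e": 10.0, "cmp00_e": 10.0, "cmp01_e": 10.0})
    prof = detect_auxotrophies(model, medium, {"cmp00_e", "cmp01_e"})
    assert prof.auxotrophic_for == set()
    assert set(prof.producible.values()) == {PRODUCED}


def test_auxotrophy_never_coexists_with_producibility():
    u = generate_universe(
        UniverseSpec(n_strains=6, n_compounds=4, plan="random-with-guarantee", seed=2),
        verify=False,
    )
    for sid in u.strains:
        prof = detect_auxotrophies(u.models[sid], u.complete_medium, u.probe_compounds)
        for c in prof.auxotrophic_for:
            assert prof.producible[c] == NOT_PRODUCED


def test_unknown_probe_compound_recorded_not_probed(chain_model, medium_a5):
    prof = detect_auxotrophies(chain_model, medium_a5, {"ghost_e"})
    assert prof.not_probed == {"ghost_e"}
    assert "ghost_e" not in prof.producible


def test_secretable_compounds_reflect_model_capabilities():
    model = build_strain_model("s", ["cmp00", "cmp01"], {"cmp01"})
    medium = Medium({"substrate_e": 10.0})
    out = secretable_compounds(model, medium)
    assert "cmp00_e" in out  # synthesized and exported
    assert "cmp01_e" not in out  # chain deleted, uptake-only transporter
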