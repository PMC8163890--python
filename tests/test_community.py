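import numpy as np
import pytest

from lbpdesign.community import (
    MAX_MIN,
    MAX_TOTAL,
    community_fba,
    dropout_analysis,
    member_growth_capacity,
    merge_models,
    strain_interaction_table,
)
from lbpdesign.fba import GROWTH_THRESHOLD, fba, stoichiometric_matrix
from lbpdesign.model import ModelValidationError
from lbpdesign.synthetic import UniverseSpec, generate_universe
from tests.conftest import make_chain_model


@pytest.mark.parametrize("scheme", [MAX_MIN, MAX_TOTAL])
def test_singleton_community_equals_individual_fba(medium_a5, scheme):
    model = make_chain_model()
    single = fba(model, medium_a5).objective_value
    com = merge_models([model], medium_a5)
    sol = community_fba(com, scheme)
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(single, abs=1e-6)
    assert sol.growth["chain"] == pytest.approx(single, abs=1e-6)


def test_pool_is_union_of_member_extracellular_metabolites(cross_feeding_pair, shared_a10):
    com = merge_models(cross_feeding_pair, shared_a10)
    assert set(com.pool_exchanges) == {"A_e", "x_e", "y_e"}
    # member internals are disjoint namespaces
    internal = [m.id for m in com.metabolites if "__" in m.id]
    assert all(m.startswith(("P1__", "P2__")) for m in internal)


def test_duplicate_strain_ids_rejected(shared_a10):
    m = make_chain_model()
    with pytest.raises(ModelValidationError, match="duplicate"):
        merge_models([m, m], shared_a10)


def test_obligate_cross_feeders_fail_alone_but_grow_together(
    cross_feeding_pair, shared_a10
):
    """The central in-silico claim: interdependent strains grow only as a community.

    Hand LP for the pair: biomass needs 1 A + 1 partner compound, each partner
    compound costs 1 A, pool supplies 10 A => 2 g1 + 2 g2 <= 10, so the
    max-min optimum is 2.5 per member.
    """
    for m in cross_feeding_pair:
        assert fba(m, shared_a10).objective_value < GROWTH_THRESHOLD
    com = merge_models(cross_feeding_pair, shared_a10)
    sol = community_fba(com, MAX_MIN)
    assert sol.status == "optimal"
    assert sol.growth["P1"] == pytest.approx(2.5, abs=1e-6)
    assert sol.growth["P2"] == pytest.approx(2.5, abs=1e-6)


def test_max_min_objective_equals_reported_min_growth(cross_feeding_pair, shared_a10):
    com = merge_models(cross_feeding_pair, shared_a10)
    sol = community_fba(com, MAX_MIN)
    assert sol.objective_value == pytest.approx(sol.min_growth, abs=1e-6)


def test_max_total_at_least_best_individual(shared_a10):
    u = generate_universe(UniverseSpec(n_strains=3, n_compounds=3, seed=9), verify=False)
    models = [u.models[s] for s in u.strains]
    best_alone = max(fba(m, u.complete_medium).objective_value for m in models)
    sol = community_fba(merge_models(models, u.complete_medium), MAX_TOTAL)
    assert sol.objective_value >= best_alone - 1e-8


def test_pool_metabolites_are_conserved_at_optimum(cross_feeding_pair, shared_a10):
    com = merge_models(cross_feeding_pair, shared_a10)
    sol = community_fba(com, MAX_MIN)
    v = np.array([sol.fluxes[r.id] for r in com.reactions])
    S = stoichiometric_matrix(com.reactions, com.metabolite_ids)
    assert np.max(np.abs(S @ v)) <= 1e-6


def test_interaction_table_finds_mutual_cross_feeding_edges(
    cross_feeding_pair, shared_a10
):
    com = merge_models(cross_feeding_pair, shared_a10)
    sol = community_fba(com, MAX_MIN)
    table = strain_interaction_table(com, sol)
    assert ("P1", "P2", "y_e") in table.dependencies
    assert ("P2", "P1", "x_e") in table.dependencies
    assert table.secreted_by("P1") >= {"x_e"}
    assert "y_e" in table.consumed_by("P1")


def test_prototroph_community_has_no_dependency_edges():
    u = generate_universe(
        UniverseSpec(n_strains=2, n_compounds=2, plan="random-with-guarantee",
                     auxotrophy_rate=0.0, seed=3),
        verify=False,
    )
    com = merge_models([u.models[s] for s in u.strains], u.minimal_medium)
    sol = community_fba(com, MAX_MIN)
    table = strain_interaction_table(com, sol)
    assert table.dependencies == []


def test_three_member_chain_has_no_transitive_edge(shared_a10):
    """A feeds B feeds C: dependency edges carry the directly exchanged compound,
    so the C->A pair (no shared metabolite) yields no edge."""
    from lbpdesign.model import Metabolite, Reaction, StrainModel

    def producer(sid, makes, needs=None):
        mets = [
            Metabolite("A_e", compartment="extracellular"),
            Metabolite("A_c", compartment="cytosol"),
            Metabolite(f"{makes}_c", compartment="cytosol"),
            Metabolite(f"{makes}_e", compartment="extracellular"),
        ]
        rxns = [
            Reaction("EX_A_e", {"A_e": -1.0}, 0.0, 1000.0, is_exchange=True),
            Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}),
            Reaction(f"SYN_{makes}", {"A_c": -1.0, f"{makes}_c": 1.0}),
            Reaction(f"T_{makes}", {f"{makes}_c": -1.0, f"{makes}_e": 1.0}, -1000.0, 1000.0),
            Reaction(f"EX_{makes}_e", {f"{makes}_e": -1.0}, 0.0, 1000.0, is_exchange=True),
        ]
        biomass = {"A_c": -1.0}
        if needs:
            mets += [
                Metabolite(f"{needs}_c", compartment="cytosol"),
                Metabolite(f"{needs}_e", compartment="extracellular"),
            ]
            rxns += [
                Reaction(f"T_{needs}", {f"{needs}_e": -1.0, f"{needs}_c": 1.0}),
                Reaction(f"EX_{needs}_e", {f"{needs}_e": -1.0}, 0.0, 1000.0, is_exchange=True),
            ]
            biomass[f"{needs}_c"] = -1.0
        rxns.append(Reaction("BIOMASS", biomass, 0.0, 1000.0, is_biomass=True))
        return StrainModel(sid, mets, rxns, "BIOMASS")

    chain = [
        producer("A", makes="x"),
        producer("B", makes="y", needs="x"),
        producer("C", makes="z", needs="y"),
    ]
    com = merge_models(chain, shared_a10)
    sol = community_fba(com, MAX_MIN)
    table = strain_interaction_table(com, sol)
    pairs = {(i, j) for i, j, _ in table.dependencies}
    assert ("B", "A") in pairs
    assert ("C", "B") in pairs
    assert ("C", "A") not in pairs  # fails without A, but no directly shared compound


def test_dropout_collapse_when_sole_producer_removed(cross_feeding_pair, shared_a10):
    com = merge_models(cross_feeding_pair, shared_a10)
    report = dropout_analysis(com)
    assert all(e.collapsed for e in report.entries)


def test_dropout_robust_with_redundant_producers():
    u = generate_universe(UniverseSpec(n_strains=4, n_compounds=2, seed=13), verify=False)
    com = merge_models([u.models[s] for s in u.strains], u.minimal_medium)
    report = dropout_analysis(com)
    # every compound has >= 2 producers (4 strains, 2 compounds, cyclic plan)
    assert not any(e.collapsed for e in report.entries)


def test_dropout_reports_lost_functions():
    from lbpdesign.catalog import profile_functions
    from lbpdesign.synthetic import CYCLIC

    u = generate_universe(UniverseSpec(n_strains=3, n_compounds=3, plan=CYCLIC, seed=21), verify=False)
    profile = profile_functions([u.annotations[s] for s in u.strains], u.catalog)
    com = merge_models([u.models[s] for s in u.strains], u.minimal_medium)
    required = set(u.catalog.function_ids)
    report = dropout_analysis(com, profile, required)
    for entry in report.entries:
        remaining = [s for s in u.strains if s != entry.removed]
        for f in required:
            covered = any(f in u.planted_functions[s] for s in remaining)
            assert (f in entry.functions_lost) == (not covered)


def test_singleton_dropout_is_vacuous(medium_a5):
    com = merge_models([make_chain_model()], medium_a5)
    report = dropout_analysis(com)
    assert len(report.entries) == 1
    assert report.entries[0].growth == {}
    assert not report.entries[0].collapsed


def test_member_growth_capacity_matches_singleton(medium_a5):
    model = make_chain_model()
    com = merge_models([model], medium_a5)
    assert member_growth_capacity(com, "chain") == pytest.approx(
        fba(model, medium_a5).objective_value, abs=1e-6
    )
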