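import pytest

from lbpdesign.designer import (
    Candidate,
    CandidateSet,
    SelectionConstraints,
    exhaustive_select,
    select_consortium,
    verify_consortium,
)
from lbpdesign.synthetic import generate_selection_pool


def pool_from(specs):
    """specs: strain_id -> (functions, auxotrophies, secretes, flagged)."""
    from lbpdesign.catalog import ExclusionFlag, ExclusionReport

    candidates = {}
    for sid, (fns, aux, sec, flagged) in specs.items():
        report = ExclusionReport(
            sid,
            [ExclusionFlag("transferable_AMR", "vanA", "f1")] if flagged else [],
        )
        candidates[sid] = Candidate(sid, set(fns), set(aux), set(sec), report)
    return CandidateSet(candidates=candidates)


def test_empty_requirements_give_empty_feasible_consortium():
    cs = pool_from({"a": (["fn"], [], [], False)})
    design = select_consortium(cs, SelectionConstraints(required_functions={}))
    assert design.status == "feasible"
    assert design.selected == []


def test_redundancy_shortfall_is_infeasible_and_names_the_function():
    cs = pool_from({
        "a": (["prop"], [], [], False),
        "b": (["prop"], [], [], False),
        "c": (["but"], [], [], False),
    })
    design = select_consortium(
        cs, SelectionConstraints(required_functions={"prop": 3, "but": 1})
    )
    assert design.status == "infeasible"
    assert "prop" in design.diagnostic


def test_flagged_strains_are_dropped_before_selection():
    cs = pool_from({
        "a": (["fn"], [], [], True),
        "b": (["fn"], [], [], False),
    })
    design = select_consortium(cs, SelectionConstraints(required_functions={"fn": 1}))
    assert design.selected == ["b"]
    permissive = SelectionConstraints(required_functions={"fn": 2}, forbid_flagged=False)
    assert select_consortium(cs, permissive).status == "feasible"


def test_complementarity_repair_adds_a_provider():
    cs = pool_from({
        "a": (["fn"], ["cmp0"], [], False),      # carrier, auxotrophic for cmp0
        "b": ([], [], ["cmp0"], False),           # silent provider
    })
    constraints = SelectionConstraints(
        required_functions={"fn": 1}, complementarity_degree=1
    )
    design = select_consortium(cs, constraints)
    assert design.status == "feasible"
    assert design.selected == ["a", "b"]
    assert design.verification.complementation[("a", "cmp0")] == 1


def test_uncomplementable_auxotrophy_is_infeasible():
    cs = pool_from({"a": (["fn"], ["cmp0"], [], False)})
    constraints = SelectionConstraints(
        required_functions={"fn": 1}, complementarity_degree=1
    )
    design = select_consortium(cs, constraints)
    assert design.status == "infeasible"
    assert "cmp0" in design.diagnostic


def test_prune_removes_redundant_greedy_additions():
    # 'big' covers two functions; greedy grabs it first, then singles are
    # needed anyway for redundancy 2, making 'big' potentially redundant
    cs = pool_from({
        "big": (["f1", "f2"], [], [], False),
        "a1": (["f1"], [], [], False),
        "a2": (["f1"], [], [], False),
        "b1": (["f2"], [], [], False),
        "b2": (["f2"], [], [], False),
    })
    constraints = SelectionConstraints(required_functions={"f1": 2, "f2": 2})
    design = select_consortium(cs, constraints)
    assert design.status == "feasible"
    report = verify_consortium(design.selected, cs, constraints)
    assert report.passes
    # pruning is idempotent: every remaining member is load-bearing
    for s in design.selected:
        rest = [t for t in design.selected if t != s]
        assert not verify_consortium(rest, cs, constraints).passes


def test_determinism_identical_inputs_identical_trace():
    cs, constraints, _ = generate_selection_pool(10, 4, seed=5)
    d1 = select_consortium(cs, constraints, seed=42)
    d2 = select_consortium(cs, constraints, seed=42)
    assert d1.selected == d2.selected
    assert d1.trace == d2.trace


@pytest.mark.parametrize("seed", range(3))
def test_exhaustive_recovers_planted_minimum(seed):
    cs, constraints, planted = generate_selection_pool(8, 3, seed=seed)
    design = exhaustive_select(cs, constraints)
    assert design.status == "feasible"
    assert design.selected == planted


@pytest.mark.parametrize("seed", range(3))
def test_greedy_is_feasible_and_no_smaller_than_the_optimum(seed):
    cs, constraints, planted = generate_selection_pool(12, 4, seed=100 + seed)
    ex = exhaustive_select(cs, constraints)
    gr = select_consortium(cs, constraints)
    assert ex.status == "feasible"
    assert gr.status == "feasible"
    assert len(gr.selected) >= len(ex.selected)
    assert verify_consortium(gr.selected, cs, constraints).passes


def test_all_prototroph_singleton_tie_break_is_lexicographic():
    cs = pool_from({
        "z": (["fn"], [], [], False),
        "a": (["fn"], [], [], False),
    })
    constraints = SelectionConstraints(required_functions={"fn": 1})
    assert exhaustive_select(cs, constraints).selected == ["a"]
    assert select_consortium(cs, constraints).selected == ["a"]


def test_greedy_tie_break_prefers_fewer_auxotrophies():
    cs = pool_from({
        "a": (["fn"], ["c1", "c2"], [], False),
        "b": (["fn"], ["c1"], [], False),
    })
    design = select_consortium(cs, SelectionConstraints(required_functions={"fn": 1}))
    assert design.selected == ["b"]


def test_tightening_an_infeasible_instance_stays_infeasible():
    cs = pool_from({
        "a": (["f"], [], [], False),
        "b": (["f"], [], [], False),
    })
    base = SelectionConstraints(required_functions={"f": 3})
    assert select_consortium(cs, base).status == "infeasible"
    tighter = SelectionConstraints(required_functions={"f": 4}, complementarity_degree=1)
    assert select_consortium(cs, tighter).status == "infeasible"


def test_verify_reports_uncomplemented_pairs():
    cs = pool_from({
        "a": (["fn"], ["cmp0"], [], False),
        "b": (["fn"], [], [], False),
    })
    constraints = SelectionConstraints(
        required_functions={"fn": 1}, complementarity_degree=1
    )
    report = verify_consortium(["a", "b"], cs, constraints)
    assert not report.passes
    assert report.uncomplemented == [("a", "cmp0")]


def test_verify_unknown_strain_errors():
    cs = pool_from({"a": (["fn"], [], [], False)})
    with pytest.raises(KeyError, match="ghost"):
        verify_consortium(["ghost"], cs, SelectionConstraints(required_functions={}))


def test_feasible_design_passes_full_reverification():
    for seed in range(3):
        cs, constraints, _ = generate_selection_pool(9, 3, seed=200 + seed)
        design = select_consortium(cs, constraints)
        assert design.status == "feasible"
        assert verify_consortium(design.selected, cs, constraints).passes


def test_viability_stage_on_cross_feeding_models(cross_feeding_pair, shared_a10):
    from lbpdesign.fba import secretable_compounds

    candidates = {}
    for m in cross_feeding_pair:
        # inside the pair each strain's required compound is made by the partner
        needs = "y_e" if m.strain_id == "P1" else "x_e"
        candidates[m.strain_id] = Candidate(
            m.strain_id,
            functions={"fn"},
            auxotrophic_for={needs},
            secretes=secretable_compounds(m, shared_a10),
            model=m,
        )
    cs = CandidateSet(candidates=candidates)
    constraints = SelectionConstraints(
        required_functions={"fn": 2},
        complementarity_degree=1,
        medium=shared_a10,
        require_community_growth=True,
    )
    design = select_consortium(cs, constraints)
    assert design.status == "feasible"
    assert sorted(design.selected) == ["P1", "P2"]
    assert design.verification.community_growth == pytest.approx(2.5, abs=1e-6)
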