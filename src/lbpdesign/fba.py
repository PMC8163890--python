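"""Flux balance analysis, exact gapfilling, and auxotrophy detection.

All linear programs are solved with HiGHS through :func:`scipy.optimize.linprog`
(steady state ``S v = 0``, flux bounds, linear objective).  Growth is declared
when the biomass flux reaches :data:`GROWTH_THRESHOLD`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import (
    Medium,
    Metabolite,
    ModelValidationError,
    Reaction,
    StrainModel,
    UniversalReactionDB,
    apply_medium,
)

GROWTH_THRESHOLD = 1e-6
#: absolute steady-state residual tolerance accepted on reported optima
STEADY_STATE_TOL = 1e-6

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

_LINPROG_STATUS = {0: OPTIMAL, 2: INFEASIBLE, 3: UNBOUNDED}


@dataclass
class FluxSolution:
    status: str
    objective_value: float
    fluxes: dict[str, float]

    @property
    def grows(self) -> bool:
        return self.status == OPTIMAL and self.objective_value >= GROWTH_THRESHOLD


def stoichiometric_matrix(reactions: list[Reaction], metabolite_ids: list[str]):
    """Dense S (metabolites x reactions) for the given ordering."""
    idx = {m: i for i, m in enumerate(metabolite_ids)}
    S = np.zeros((len(metabolite_ids), len(reactions)))
    for j, r in enumerate(reactions):
        for m, coeff in r.stoichiometry.items():
            S[idx[m], j] = coeff
    return S


def solve_lp(
    reactions: list[Reaction],
    metabolite_ids: list[str],
    objective: dict[str, float],
    sense: str = "max",
) -> FluxSolution:
    """Optimize a linear flux objective subject to S v = 0 and bounds."""
    S = stoichiometric_matrix(reactions, metabolite_ids)
    c = np.zeros(len(reactions))
    for j, r in enumerate(reactions):
        c[j] = objective.get(r.id, 0.0)
    sign = -1.0 if sense == "max" else 1.0
    bounds = [(r.lower_bound, r.upper_bound) for r in reactions]
    res = linprog(
        sign * c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
    )
    status = _LINPROG_STATUS.get(res.status, INFEASIBLE)
    if status != OPTIMAL:
        return FluxSolution(status=status, objective_value=float("nan"), fluxes={})
    fluxes = {r.id: float(v) for r, v in zip(reactions, res.x)}
    return FluxSolution(
        status=OPTIMAL,
        objective_value=float(c @ res.x),
        fluxes=fluxes,
    )


def fba(model: StrainModel, medium: Medium | None = None) -> FluxSolution:
    """Maximize biomass flux; growth is declared iff the optimum >= 1e-6."""
    if medium is not None:
        model = apply_medium(model, medium)
    return solve_lp(
        model.reactions,
        sorted(model.metabolite_ids),
        {model.biomass_reaction_id: 1.0},
    )


def optimize_reaction(
    model: StrainModel, reaction_id: str, medium: Medium | None = None, sense: str = "max"
) -> FluxSolution:
    """Maximize (or minimize) the flux through one reaction."""
    if medium is not None:
        model = apply_medium(model, medium)
    return solve_lp(model.reactions, sorted(model.metabolite_ids), {reaction_id: 1.0}, sense)


# ---------------------------------------------------------------------------
# Gapfilling


@dataclass
class GapfillResult:
    status: str  # optimal | infeasible
    added_reactions: list[str]
    model: StrainModel | None
    penalty: float
    #: best biomass objective attained (the certificate when infeasible)
    best_objective: float


def _augment(model: StrainModel, db: UniversalReactionDB, rxn_ids: set[str]) -> StrainModel:
    add = [r for r in db.reactions if r.id in rxn_ids]
    need = set()
    for r in add:
        need |= set(r.stoichiometry)
    need -= model.metabolite_ids
    extra_mets = [m for m in db.metabolites if m.id in need]
    still = need - {m.id for m in extra_mets}
    if still:
        raise ModelValidationError(
            f"universal database reactions reference undeclared metabolites: {sorted(still)}"
        )
    return StrainModel(
        strain_id=model.strain_id,
        metabolites=list(model.metabolites) + extra_mets,
        reactions=list(model.reactions) + add,
        biomass_reaction_id=model.biomass_reaction_id,
    )


def gapfill(
    model: StrainModel,
    medium: Medium,
    db: UniversalReactionDB,
    growth_threshold: float = GROWTH_THRESHOLD,
) -> GapfillResult:
    """Minimum-total-penalty reaction additions restoring growth.

    Exact: for |db| <= 12 the search enumerates candidate subsets in increasing
    (penalty, lexicographic id) order, so the returned set is the optimum and
    penalty ties break lexicographically; larger databases fall back to a
    big-M MILP (HiGHS), which is penalty-optimal but does not guarantee the
    lexicographic tie-break.
    """
    if not db.reactions:
        raise ModelValidationError("empty universal reaction database")
    clash = model.metabolite_ids  # reaction-id disjointness per the db contract
    dup = sorted({r.id for r in db.reactions} & {r.id for r in model.reactions})
    if dup:
        raise ModelValidationError(f"db reaction ids collide with model: {dup}")
    del clash
    base = fba(model, medium)
    if base.status == OPTIMAL and base.objective_value >= growth_threshold:
        return GapfillResult(OPTIMAL, [], model.copy(), 0.0, base.objective_value)
    if len(db.reactions) <= 12:
        return _gapfill_exhaustive(model, medium, db, growth_threshold)
    return _gapfill_milp(model, medium, db, growth_threshold)


def _gapfill_exhaustive(model, medium, db, growth_threshold) -> GapfillResult:
    ids = sorted(r.id for r in db.reactions)
    subsets = []
    for k in range(1, len(ids) + 1):
        for combo in itertools.combinations(ids, k):
            subsets.append((sum(db.penalties[i] for i in combo), combo))
    subsets.sort(key=lambda t: (t[0], t[1]))
    best_obj = 0.0
    for penalty, combo in subsets:
        aug = _augment(model, db, set(combo))
        sol = fba(aug, medium)
        if sol.status == OPTIMAL:
            best_obj = max(best_obj, sol.objective_value)
            if sol.objective_value >= growth_threshold:
                return GapfillResult(OPTIMAL, list(combo), aug, penalty, sol.objective_value)
    return GapfillResult(INFEASIBLE, [], None, float("inf"), best_obj)


def _gapfill_milp(model, medium, db, growth_threshold) -> GapfillResult:
    from scipy.optimize import Bounds, LinearConstraint, milp
    from scipy.sparse import lil_matrix

    full = _augment(model, db, {r.id for r in db.reactions})
    full = apply_medium(full, medium)
    reactions = full.reactions
    mets = sorted(full.metabolite_ids)
    S = stoichiometric_matrix(reactions, mets)
    n = len(reactions)
    db_ids = sorted(r.id for r in db.reactions)
    db_pos = {rid: n + k for k, rid in enumerate(db_ids)}
    nvar = n + len(db_ids)

    A = lil_matrix((S.shape[0], nvar))
    A[:, :n] = S
    constraints = [LinearConstraint(A.tocsc(), 0.0, 0.0)]

    lb = np.array([r.lower_bound for r in reactions] + [0.0] * len(db_ids))
    ub = np.array([r.upper_bound for r in reactions] + [1.0] * len(db_ids))
    # indicator coupling: lb_j*y_j <= v_j <= ub_j*y_j for db reactions
    rows_up = lil_matrix((len(db_ids), nvar))
    rows_lo = lil_matrix((len(db_ids), nvar))
    for k, rid in enumerate(db_ids):
        j = next(i for i, r in enumerate(reactions) if r.id == rid)
        rows_up[k, j] = 1.0
        rows_up[k, db_pos[rid]] = -reactions[j].upper_bound
        rows_lo[k, j] = 1.0
        rows_lo[k, db_pos[rid]] = -reactions[j].lower_bound
    constraints.append(LinearConstraint(rows_up.tocsc(), -np.inf, 0.0))
    constraints.append(LinearConstraint(rows_lo.tocsc(), 0.0, np.inf))
    # growth requirement
    grow = lil_matrix((1, nvar))
    j_bio = next(i for i, r in enumerate(reactions) if r.id == full.biomass_reaction_id)
    grow[0, j_bio] = 1.0
    constraints.append(LinearConstraint(grow.tocsc(), growth_threshold, np.inf))

    c = np.zeros(nvar)
    for rid in db_ids:
        c[db_pos[rid]] = db.penalties[rid]
    integrality = np.zeros(nvar)
    integrality[n:] = 1
    res = milp(
        c,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(lb, ub),
    )
    if not res.success:
        relax = solve_lp(full.reactions, mets, {full.biomass_reaction_id: 1.0})
        best = relax.objective_value if relax.status == OPTIMAL else 0.0
        return GapfillResult(INFEASIBLE, [], None, float("inf"), best)
    chosen = [rid for rid in db_ids if res.x[db_pos[rid]] > 0.5]
    aug = _augment(model, db, set(chosen))
    sol = fba(aug, medium)
    penalty = sum(db.penalties[r] for r in chosen)
    return GapfillResult(OPTIMAL, chosen, aug, penalty, sol.objective_value)


# ---------------------------------------------------------------------------
# Auxotrophy detection

PRODUCED = "produced"
NOT_PRODUCED = "not_produced"


@dataclass
class AuxotrophyProfile:
    strain_id: str
    auxotrophic_for: set[str]
    producible: dict[str, str]
    not_probed: set[str] = field(default_factory=set)


def _demand_target(model: StrainModel, compound: str) -> str:
    """Metabolite the producibility demand attaches to.

    Probe compounds are named by their extracellular id (they appear in media);
    the demand prefers the cytosolic counterpart (``_e`` -> ``_c``) so that
    intracellular synthesis counts even without an exporter.
    """
    if compound.endswith("_e"):
        cyt = compound[:-2] + "_c"
        if cyt in model.metabolite_ids:
            return cyt
    return compound


def detect_auxotrophies(
    model: StrainModel,
    complete_medium: Medium,
    probe_compounds: set[str],
    growth_threshold: float = GROWTH_THRESHOLD,
) -> AuxotrophyProfile:
    """Single-omission growth tests plus demand-reaction producibility.

    A probe compound c is an auxotrophy when the strain fails to grow on the
    complete medium lacking c but grows with c restored.  Producibility asks
    whether a temporary demand (sink) for c can carry flux > 1e-6 on the same
    c-free medium.
    """
    base = fba(model, complete_medium)
    if not (base.status == OPTIMAL and base.objective_value >= growth_threshold):
        raise ModelValidationError(
            f"{model.strain_id!r} does not grow on the complete medium "
            f"{complete_medium.name!r} (objective {base.objective_value!r})"
        )
    auxotrophic: set[str] = set()
    producible: dict[str, str] = {}
    not_probed: set[str] = set()
    for c in sorted(probe_compounds):
        if c not in model.metabolite_ids:
            not_probed.add(c)
            continue
        minus = complete_medium.without(c)
        g_without = fba(model, minus)
        fails_without = not (
            g_without.status == OPTIMAL and g_without.objective_value >= growth_threshold
        )
        if fails_without:
            restored = fba(model, minus.with_compound(c, complete_medium.uptake.get(c, 10.0)))
            if restored.status == OPTIMAL and restored.objective_value >= growth_threshold:
                auxotrophic.add(c)
        target = _demand_target(model, c)
        demand = Reaction(id="DM__probe", stoichiometry={target: -1.0}, lower_bound=0.0)
        probe_model = StrainModel(
            strain_id=model.strain_id,
            metabolites=list(model.metabolites),
            reactions=list(model.reactions) + [demand],
            biomass_reaction_id=model.biomass_reaction_id,
        )
        dem = optimize_reaction(probe_model, "DM__probe", minus)
        made = dem.status == OPTIMAL and dem.objective_value > 1e-6
        producible[c] = PRODUCED if made else NOT_PRODUCED
    return AuxotrophyProfile(
        strain_id=model.strain_id,
        auxotrophic_for=auxotrophic,
        producible=producible,
        not_probed=not_probed,
    )


def secretable_compounds(
    model: StrainModel, medium: Medium, threshold: float = 1e-6
) -> set[str]:
    """Extracellular compounds the strain can export on the medium.

    A compound is secretable when the maximal (positive) flux through its
    exchange reaction exceeds the threshold.
    """
    applied = apply_medium(model, medium)
    out = set()
    for r in applied.exchanges:
        met = next(iter(r.stoichiometry))
        sol = optimize_reaction(applied, r.id)
        if sol.status == OPTIMAL and sol.objective_value > threshold:
            out.add(met)
    return out
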