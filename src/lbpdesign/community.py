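"""Compartmentalized community models with a shared extracellular pool.

Each member keeps a private namespace (``<strain_id>__`` prefix on every
metabolite and reaction); its former exchange reactions become member<->pool
transfer reactions (bounds +/-1000, positive flux = secretion into the pool);
the pool alone exchanges with the environment, bounded by the medium.

Two community objectives are provided:

* ``max_total`` — maximize the summed member biomass fluxes;
* ``max_min``  — maximize an auxiliary lower bound t with every member's
  biomass >= t (the fairness objective: the consortium grows only if every
  member grows).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linprog

from .fba import (
    GROWTH_THRESHOLD,
    OPTIMAL,
    FluxSolution,
    _LINPROG_STATUS,
    stoichiometric_matrix,
)
from .model import (
    DEFAULT_BOUND,
    EXTRACELLULAR,
    Medium,
    Metabolite,
    ModelValidationError,
    Reaction,
    StrainModel,
)

MAX_MIN = "max_min"
MAX_TOTAL = "max_total"


@dataclass
class CommunityModel:
    members: list[str]
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_ids: dict[str, str]  # strain_id -> namespaced biomass reaction id
    #: (strain_id, pool metabolite) -> transfer reaction id
    transfers: dict[tuple[str, str], str]
    #: pool metabolite -> environment exchange reaction id
    pool_exchanges: dict[str, str]
    medium: Medium

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def without_member(self, strain_id: str) -> "CommunityModel":
        """A copy with one member inactivated (all its reactions clamped to 0)."""
        if strain_id not in self.members:
            raise KeyError(strain_id)
        prefix = strain_id + "__"
        reactions = [
            replace(r, lower_bound=0.0, upper_bound=0.0)
            if r.id.startswith(prefix)
            else r
            for r in self.reactions
        ]
        return CommunityModel(
            members=[m for m in self.members if m != strain_id],
            metabolites=list(self.metabolites),
            reactions=reactions,
            biomass_ids={k: v for k, v in self.biomass_ids.items() if k != strain_id},
            transfers={k: v for k, v in self.transfers.items() if k[0] != strain_id},
            pool_exchanges=dict(self.pool_exchanges),
            medium=self.medium,
        )


def merge_models(models: list[StrainModel], medium: Medium) -> CommunityModel:
    """Merge strain models around a shared extracellular pool."""
    if not models:
        raise ModelValidationError("need at least one model to merge")
    ids = [m.strain_id for m in models]
    if len(ids) != len(set(ids)):
        dup = sorted({s for s in ids if ids.count(s) > 1})
        raise ModelValidationError(f"duplicate strain_ids: {dup}")

    pool_mets: dict[str, Metabolite] = {}
    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    biomass_ids: dict[str, str] = {}
    transfers: dict[tuple[str, str], str] = {}

    for m in models:
        prefix = m.strain_id + "__"
        for met in m.metabolites:
            metabolites.append(replace(met, id=prefix + met.id))
            if met.compartment == EXTRACELLULAR and met.id not in pool_mets:
                pool_mets[met.id] = replace(met, id=met.id)
        for r in m.reactions:
            stoich = {prefix + k: v for k, v in r.stoichiometry.items()}
            if r.is_exchange:
                pool_met = next(iter(r.stoichiometry))
                # member exchange -> member<->pool transfer (+ = secretion)
                coeff = r.stoichiometry[pool_met]
                tid = prefix + r.id
                reactions.append(
                    Reaction(
                        id=tid,
                        stoichiometry={prefix + pool_met: coeff, pool_met: -coeff},
                        lower_bound=-DEFAULT_BOUND,
                        upper_bound=DEFAULT_BOUND,
                        is_exchange=False,
                    )
                )
                transfers[(m.strain_id, pool_met)] = tid
            else:
                reactions.append(
                    Reaction(
                        id=prefix + r.id,
                        stoichiometry=stoich,
                        lower_bound=r.lower_bound,
                        upper_bound=r.upper_bound,
                        is_biomass=r.is_biomass,
                    )
                )
                if r.id == m.biomass_reaction_id:
                    biomass_ids[m.strain_id] = prefix + r.id

    pool_exchanges: dict[str, str] = {}
    for met_id, met in sorted(pool_mets.items()):
        metabolites.append(met)
        rid = f"POOLEX_{met_id}"
        uptake = medium.uptake.get(met_id, 0.0)
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry={met_id: -1.0},
                lower_bound=-uptake,
                upper_bound=DEFAULT_BOUND,
                is_exchange=True,
            )
        )
        pool_exchanges[met_id] = rid

    return CommunityModel(
        members=list(ids),
        metabolites=metabolites,
        reactions=reactions,
        biomass_ids=biomass_ids,
        transfers=transfers,
        pool_exchanges=pool_exchanges,
        medium=medium,
    )


@dataclass
class CommunitySolution:
    status: str
    scheme: str
    objective_value: float
    growth: dict[str, float]
    pool_exchange_fluxes: dict[str, float]
    transfer_fluxes: dict[tuple[str, str], float]
    fluxes: dict[str, float] = field(default_factory=dict)
    diagnostic: str = ""

    @property
    def min_growth(self) -> float:
        return min(self.growth.values()) if self.growth else 0.0


def community_fba(community: CommunityModel, scheme: str = MAX_MIN) -> CommunitySolution:
    """Solve community FBA under the max_min or max_total scheme."""
    if scheme not in (MAX_MIN, MAX_TOTAL):
        raise ValueError(f"unknown scheme {scheme!r}")
    reactions = community.reactions
    mets = community.metabolite_ids
    S = stoichiometric_matrix(reactions, mets)
    n = len(reactions)
    bio_cols = {
        sid: next(j for j, r in enumerate(reactions) if r.id == rid)
        for sid, rid in community.biomass_ids.items()
    }
    lb = np.array([r.lower_bound for r in reactions])
    ub = np.array([r.upper_bound for r in reactions])

    if scheme == MAX_TOTAL:
        c = np.zeros(n)
        for j in bio_cols.values():
            c[j] = 1.0
        res = linprog(
            -c, A_eq=S, b_eq=np.zeros(S.shape[0]),
            bounds=list(zip(lb, ub)), method="highs",
        )
        x = res.x if res.status == 0 else None
    else:
        # variables: fluxes + auxiliary t; constraints t - biomass_i <= 0
        c = np.zeros(n + 1)
        c[n] = 1.0
        A_eq = np.hstack([S, np.zeros((S.shape[0], 1))])
        A_ub = np.zeros((len(bio_cols), n + 1))
        for i, j in enumerate(bio_cols.values()):
            A_ub[i, j] = -1.0
            A_ub[i, n] = 1.0
        res = linprog(
            -c,
            A_eq=A_eq,
            b_eq=np.zeros(S.shape[0]),
            A_ub=A_ub,
            b_ub=np.zeros(len(bio_cols)),
            bounds=list(zip(lb, ub)) + [(0.0, None)],
            method="highs",
        )
        x = res.x[:n] if res.status == 0 else None

    status = _LINPROG_STATUS.get(res.status, "infeasible")
    if x is None:
        diag = _diagnose_infeasible(community)
        return CommunitySolution(
            status=status, scheme=scheme, objective_value=float("nan"),
            growth={}, pool_exchange_fluxes={}, transfer_fluxes={}, diagnostic=diag,
        )
    fluxes = {r.id: float(v) for r, v in zip(reactions, x)}
    growth = {sid: fluxes[rid] for sid, rid in community.biomass_ids.items()}
    objective = (
        sum(growth.values()) if scheme == MAX_TOTAL else float(res.x[n])
    )
    return CommunitySolution(
        status=OPTIMAL,
        scheme=scheme,
        objective_value=objective,
        growth=growth,
        pool_exchange_fluxes={m: fluxes[rid] for m, rid in community.pool_exchanges.items()},
        transfer_fluxes={k: fluxes[rid] for k, rid in community.transfers.items()},
        fluxes=fluxes,
    )


def _diagnose_infeasible(community: CommunityModel) -> str:
    weak = []
    for sid in community.members:
        g = member_growth_capacity(community, sid)
        if g < GROWTH_THRESHOLD:
            weak.append(sid)
    if weak:
        return "members unable to reach the growth threshold: " + ", ".join(weak)
    return "community LP infeasible"


def member_growth_capacity(community: CommunityModel, strain_id: str) -> float:
    """Maximum biomass flux a single member can reach inside the community."""
    rid = community.biomass_ids[strain_id]
    reactions = community.reactions
    S = stoichiometric_matrix(reactions, community.metabolite_ids)
    c = np.zeros(len(reactions))
    c[next(j for j, r in enumerate(reactions) if r.id == rid)] = 1.0
    res = linprog(
        -c, A_eq=S, b_eq=np.zeros(S.shape[0]),
        bounds=[(r.lower_bound, r.upper_bound) for r in reactions], method="highs",
    )
    return float(c @ res.x) if res.status == 0 else 0.0


# ---------------------------------------------------------------------------
# Strain interactions and dropout robustness

SECRETION_TOL = 1e-6


@dataclass
class InteractionTable:
    #: (strain_id, pool metabolite) -> net transfer flux at the optimum
    net_flux: dict[tuple[str, str], float]
    #: (consumer, producer, metabolite) dependency edges
    dependencies: list[tuple[str, str, str]]

    def secreted_by(self, strain_id: str) -> set[str]:
        return {m for (s, m), v in self.net_flux.items() if s == strain_id and v > SECRETION_TOL}

    def consumed_by(self, strain_id: str) -> set[str]:
        return {m for (s, m), v in self.net_flux.items() if s == strain_id and v < -SECRETION_TOL}


def strain_interaction_table(
    community: CommunityModel, solution: CommunitySolution
) -> InteractionTable:
    """Secretion/uptake matrix and pairwise-removal dependency edges.

    Edge (i, j, m): member i reaches the growth threshold with j present but
    not with j removed, and m is secreted by j and consumed by i at the
    reported optimum.
    """
    if solution.status != OPTIMAL:
        raise ValueError("interaction table requires an optimal community solution")
    net = dict(solution.transfer_fluxes)
    secreted = {
        s: {m for (s2, m), v in net.items() if s2 == s and v > SECRETION_TOL}
        for s in community.members
    }
    consumed = {
        s: {m for (s2, m), v in net.items() if s2 == s and v < -SECRETION_TOL}
        for s in community.members
    }
    capacity = {s: member_growth_capacity(community, s) for s in community.members}
    edges = []
    for j in community.members:
        reduced = community.without_member(j)
        for i in community.members:
            if i == j or capacity[i] < GROWTH_THRESHOLD:
                continue
            if member_growth_capacity(reduced, i) < GROWTH_THRESHOLD:
                for m in sorted(secreted[j] & consumed[i]):
                    edges.append((i, j, m))
    return InteractionTable(net_flux=net, dependencies=edges)


@dataclass
class DropoutEntry:
    removed: str
    growth: dict[str, float]
    functions_lost: set[str]
    collapsed: bool


@dataclass
class DropoutReport:
    entries: list[DropoutEntry]

    @property
    def robust(self) -> bool:
        return not any(e.collapsed or e.functions_lost for e in self.entries)


def dropout_analysis(
    community: CommunityModel,
    profile=None,
    required: set[str] | None = None,
    growth_threshold: float = GROWTH_THRESHOLD,
) -> DropoutReport:
    """Remove each member in turn; record growth, collapse, and lost functions.

    ``profile`` is a FunctionProfile sharing the community's strain ids; a
    required function is lost when no remaining member carries it.
    """
    entries = []
    for sid in community.members:
        remaining = [s for s in community.members if s != sid]
        lost: set[str] = set()
        if profile is not None and required:
            for f in sorted(required):
                if not any(profile.has_function(s, f) for s in remaining):
                    lost.add(f)
        if not remaining:  # singleton community: vacuous entry
            entries.append(DropoutEntry(sid, {}, lost, collapsed=False))
            continue
        sol = community_fba(community.without_member(sid), MAX_MIN)
        growth = sol.growth
        collapsed = sol.status != OPTIMAL or any(
            g < growth_threshold for g in growth.values()
        )
        entries.append(DropoutEntry(sid, growth, lost, collapsed))
    return DropoutReport(entries)
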