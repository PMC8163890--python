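"""Consortium selection under redundancy, complementarity, and viability constraints.

The selection procedure is a deterministic greedy set-multicover with repair
and reverse-order pruning:

1. drop exclusion-flagged strains (optional);
2. greedily add the strain with the largest marginal coverage of unmet
   (function, redundancy) demand — ties go to the strain with fewer own
   auxotrophies, then lexicographic id;
3. repair: while some member's auxotrophic compound is secreted by fewer than
   k co-members, add the non-member covering the most unmet needs;
4. prune members in reverse addition order when removal preserves all
   constraints;
5. optionally require community max-min growth on the working medium.

An exhaustive minimum-cardinality search over pools of <= 15 candidates serves
as the optimality oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .catalog import ExclusionReport, FunctionProfile
from .community import MAX_MIN, community_fba, merge_models
from .fba import GROWTH_THRESHOLD, AuxotrophyProfile
from .model import Medium, StrainModel


@dataclass
class Candidate:
    strain_id: str
    functions: set[str]
    auxotrophic_for: set[str]
    secretes: set[str]
    exclusion: ExclusionReport | None = None
    model: StrainModel | None = None

    @property
    def flagged(self) -> bool:
        return self.exclusion is not None and not self.exclusion.passed


@dataclass
class CandidateSet:
    candidates: dict[str, Candidate]
    profile: FunctionProfile | None = None
    metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        for sid, c in self.candidates.items():
            if sid != c.strain_id:
                raise ValueError(f"candidate key {sid!r} != strain_id {c.strain_id!r}")

    @property
    def strain_ids(self) -> list[str]:
        return sorted(self.candidates)

    def __len__(self) -> int:
        return len(self.candidates)

    def __getitem__(self, sid: str) -> Candidate:
        return self.candidates[sid]

    @classmethod
    def assemble(
        cls,
        profile: FunctionProfile,
        auxotrophies: dict[str, AuxotrophyProfile],
        models: dict[str, StrainModel],
        exclusions: dict[str, ExclusionReport],
        secretes: dict[str, set[str]],
    ) -> "CandidateSet":
        candidates = {}
        for sid in profile.strains:
            candidates[sid] = Candidate(
                strain_id=sid,
                functions=profile.functions_of(sid),
                auxotrophic_for=set(auxotrophies[sid].auxotrophic_for),
                secretes=set(secretes.get(sid, set())),
                exclusion=exclusions.get(sid),
                model=models.get(sid),
            )
        return cls(candidates=candidates, profile=profile)


@dataclass
class SelectionConstraints:
    #: function_id -> redundancy target r_f (number of carrier strains, >= 1)
    required_functions: dict[str, int]
    #: each member's each auxotrophic compound must be secretable by >= k co-members
    complementarity_degree: int = 0
    forbid_flagged: bool = True
    min_size: int = 0
    max_size: int | None = None
    medium: Medium | None = None
    require_community_growth: bool = False

    def __post_init__(self):
        bad = {f: r for f, r in self.required_functions.items() if r < 1}
        if bad:
            raise ValueError(f"redundancy targets must be >= 1: {bad}")
        if self.complementarity_degree < 0:
            raise ValueError("complementarity degree must be >= 0")
        if self.max_size is not None and self.min_size > self.max_size:
            raise ValueError("min_size > max_size")


def default_selection_constraints(
    functions, redundancy: int = 2, complementarity_degree: int = 1, **kwargs
) -> SelectionConstraints:
    """The recommended design defaults: redundancy 2 per required function
    (so one dropout never uncovers a function) and complementarity degree 1
    (every auxotrophy covered by at least one co-member)."""
    return SelectionConstraints(
        required_functions={f: redundancy for f in functions},
        complementarity_degree=complementarity_degree,
        **kwargs,
    )


@dataclass
class VerificationReport:
    function_coverage: dict[str, int]
    coverage_ok: bool
    #: (strain, compound) -> number of co-members able to secrete the compound
    complementation: dict[tuple[str, str], int]
    complementation_ok: bool
    uncomplemented: list[tuple[str, str]]
    exclusion_ok: bool
    flagged_members: list[str]
    size_ok: bool
    community_growth: float | None
    community_ok: bool
    dropout_robust: bool | None
    passes: bool


@dataclass
class ConsortiumDesign:
    selected: list[str]
    status: str  # feasible | infeasible
    verification: VerificationReport | None
    trace: list[str]
    seed: int
    diagnostic: str = ""


def _coverage(selected: list[str], candidates: CandidateSet, required: dict[str, int]):
    return {
        f: sum(1 for s in selected if f in candidates[s].functions) for f in required
    }


def _complementation(selected: list[str], candidates: CandidateSet):
    counts: dict[tuple[str, str], int] = {}
    for s in selected:
        for c in sorted(candidates[s].auxotrophic_for):
            counts[(s, c)] = sum(
                1 for t in selected if t != s and c in candidates[t].secretes
            )
    return counts


def _satisfies(
    selected: list[str],
    candidates: CandidateSet,
    constraints: SelectionConstraints,
    check_viability: bool = False,
) -> bool:
    cov = _coverage(selected, candidates, constraints.required_functions)
    if any(cov[f] < r for f, r in constraints.required_functions.items()):
        return False
    comp = _complementation(selected, candidates)
    if any(n < constraints.complementarity_degree for n in comp.values()):
        return False
    if constraints.forbid_flagged and any(candidates[s].flagged for s in selected):
        return False
    if len(selected) < constraints.min_size:
        return False
    if constraints.max_size is not None and len(selected) > constraints.max_size:
        return False
    if check_viability and constraints.require_community_growth:
        growth = _community_growth(selected, candidates, constraints)
        if growth is None or growth < GROWTH_THRESHOLD:
            return False
    return True


def _community_growth(selected, candidates, constraints) -> float | None:
    models = [candidates[s].model for s in selected]
    if not selected or any(m is None for m in models) or constraints.medium is None:
        return None
    com = merge_models(models, constraints.medium)
    sol = community_fba(com, MAX_MIN)
    return sol.objective_value if sol.status == "optimal" else 0.0


def select_consortium(
    candidates: CandidateSet,
    constraints: SelectionConstraints,
    seed: int = 0,
) -> ConsortiumDesign:
    """Greedy multicover + repair + prune; deterministic given input and seed."""
    if not candidates.candidates:
        raise ValueError("empty candidate set")
    trace: list[str] = [f"seed={seed}"]
    pool = candidates.strain_ids  # sorted for platform stability
    if constraints.forbid_flagged:
        dropped = [s for s in pool if candidates[s].flagged]
        pool = [s for s in pool if not candidates[s].flagged]
        for s in dropped:
            trace.append(f"stage1 drop_flagged {s}")

    def tie_key(sid: str):
        return (len(candidates[sid].auxotrophic_for), sid)

    # stage 2: greedy set-multicover of (function, redundancy) demand
    selected: list[str] = []
    required = constraints.required_functions
    while True:
        cov = _coverage(selected, candidates, required)
        unmet = {f: r - cov[f] for f, r in required.items() if cov[f] < r}
        if not unmet:
            break
        best, best_gain = None, 0
        for s in pool:
            if s in selected:
                continue
            gain = sum(1 for f in unmet if f in candidates[s].functions)
            if gain > best_gain or (
                gain == best_gain and gain > 0 and best is not None and tie_key(s) < tie_key(best)
            ):
                best, best_gain = s, gain
        if best is None or best_gain == 0:
            limiting = sorted(
                f
                for f in unmet
                if not any(f in candidates[s].functions for s in pool if s not in selected)
            )
            return ConsortiumDesign(
                selected=[],
                status="infeasible",
                verification=None,
                trace=trace,
                seed=seed,
                diagnostic=f"unsatisfiable redundancy for functions: {limiting or sorted(unmet)}",
            )
        selected.append(best)
        trace.append(f"stage2 add {best} gain={best_gain}")

    # stage 3: repair auxotrophy complementarity
    k = constraints.complementarity_degree
    guard = 0
    while k > 0:
        comp = _complementation(selected, candidates)
        unmet_pairs = [(s, c) for (s, c), n in comp.items() if n < k]
        if not unmet_pairs:
            break
        guard += 1
        if guard > len(pool) + 1:
            break
        best, best_gain = None, 0
        for s in pool:
            if s in selected:
                continue
            gain = sum(1 for (_, c) in unmet_pairs if c in candidates[s].secretes)
            if gain > best_gain or (
                gain == best_gain and gain > 0 and best is not None and tie_key(s) < tie_key(best)
            ):
                best, best_gain = s, gain
        if best is None or best_gain == 0:
            return ConsortiumDesign(
                selected=[],
                status="infeasible",
                verification=None,
                trace=trace,
                seed=seed,
                diagnostic=f"uncomplementable auxotrophies: {sorted(unmet_pairs)}",
            )
        selected.append(best)
        trace.append(f"stage3 add {best} complements={best_gain}")

    if any(
        n < k for n in _complementation(selected, candidates).values()
    ):
        return ConsortiumDesign(
            selected=[],
            status="infeasible",
            verification=None,
            trace=trace,
            seed=seed,
            diagnostic="complementarity repair did not converge",
        )

    # stage 4: prune in reverse addition order
    for s in list(reversed(selected)):
        trial = [t for t in selected if t != s]
        if _satisfies(trial, candidates, constraints, check_viability=True):
            selected = trial
            trace.append(f"stage4 prune {s}")

    if constraints.max_size is not None and len(selected) > constraints.max_size:
        return ConsortiumDesign(
            selected=selected,
            status="infeasible",
            verification=None,
            trace=trace,
            seed=seed,
            diagnostic=f"selection size {len(selected)} exceeds max_size {constraints.max_size}",
        )

    # stage 5: community viability
    if constraints.require_community_growth:
        growth = _community_growth(selected, candidates, constraints)
        if growth is None or growth < GROWTH_THRESHOLD:
            return ConsortiumDesign(
                selected=selected,
                status="infeasible",
                verification=None,
                trace=trace,
                seed=seed,
                diagnostic=f"community max-min growth {growth} below threshold",
            )
        trace.append(f"stage5 community_growth={growth:.6g}")

    report = verify_consortium(selected, candidates, constraints)
    status = "feasible" if report.passes else "infeasible"
    return ConsortiumDesign(
        selected=selected,
        status=status,
        verification=report,
        trace=trace,
        seed=seed,
        diagnostic="" if report.passes else "verification failed",
    )


def verify_consortium(
    selected: list[str],
    candidates: CandidateSet,
    constraints: SelectionConstraints,
) -> VerificationReport:
    """Recompute every constraint from scratch for a selected strain set."""
    unknown = sorted(set(selected) - set(candidates.candidates))
    if unknown:
        raise KeyError(f"unknown strain ids: {unknown}")
    cov = _coverage(selected, candidates, constraints.required_functions)
    coverage_ok = all(cov[f] >= r for f, r in constraints.required_functions.items())
    comp = _complementation(selected, candidates)
    k = constraints.complementarity_degree
    uncomplemented = sorted([pair for pair, n in comp.items() if n < k])
    complementation_ok = not uncomplemented
    flagged = [s for s in selected if candidates[s].flagged]
    exclusion_ok = not (constraints.forbid_flagged and flagged)
    size_ok = len(selected) >= constraints.min_size and (
        constraints.max_size is None or len(selected) <= constraints.max_size
    )
    growth = None
    community_ok = True
    if constraints.require_community_growth:
        growth = _community_growth(selected, candidates, constraints)
        community_ok = growth is not None and growth >= GROWTH_THRESHOLD
    dropout_robust = None
    if constraints.required_functions and all(
        r >= 2 for r in constraints.required_functions.values()
    ):
        dropout_robust = all(
            all(
                any(f in candidates[t].functions for t in selected if t != s)
                for f in constraints.required_functions
            )
            for s in selected
        )
    passes = (
        coverage_ok
        and complementation_ok
        and exclusion_ok
        and size_ok
        and community_ok
        and (dropout_robust is not False)
    )
    return VerificationReport(
        function_coverage=cov,
        coverage_ok=coverage_ok,
        complementation=comp,
        complementation_ok=complementation_ok,
        uncomplemented=uncomplemented,
        exclusion_ok=exclusion_ok,
        flagged_members=flagged,
        size_ok=size_ok,
        community_growth=growth,
        community_ok=community_ok,
        dropout_robust=dropout_robust,
        passes=passes,
    )


def exhaustive_select(
    candidates: CandidateSet,
    constraints: SelectionConstraints,
    max_pool: int = 15,
) -> ConsortiumDesign:
    """Minimum-cardinality feasible set by exhaustive search (test oracle).

    Ties break by lexicographic id vector.  Limited to small pools.
    """
    pool = candidates.strain_ids
    if len(pool) > max_pool:
        raise ValueError(f"exhaustive search limited to {max_pool} candidates")
    if constraints.forbid_flagged:
        pool = [s for s in pool if not candidates[s].flagged]
    lo = max(constraints.min_size, 0)
    hi = min(len(pool), constraints.max_size if constraints.max_size is not None else len(pool))
    for size in range(lo, hi + 1):
        for combo in itertools.combinations(pool, size):
            sel = list(combo)
            if _satisfies(sel, candidates, constraints, check_viability=True):
                report = verify_consortium(sel, candidates, constraints)
                return ConsortiumDesign(
                    selected=sel,
                    status="feasible",
                    verification=report,
                    trace=[f"exhaustive size={size}"],
                    seed=0,
                )
    return ConsortiumDesign(
        selected=[],
        status="infeasible",
        verification=None,
        trace=["exhaustive"],
        seed=0,
        diagnostic="no feasible subset",
    )
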