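"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's LP path: the FBA oracle enumerates
candidate vertices of the flux polytope {S v = 0, lb <= v <= ub} directly,
and the divergence oracle counts positional mismatches on the un-fragmented
sequence pair.
"""

from __future__ import annotations

import itertools

import numpy as np


def vertex_lp_max(S: np.ndarray, lb, ub, c) -> float | None:
    """Maximum of c.v over {S v = 0, lb <= v <= ub} by vertex enumeration.

    Every vertex fixes at least n - rank(S) variables at a bound with the rest
    solved from the equalities; all such candidate points are enumerated and
    filtered for feasibility.  Returns None when no feasible vertex exists.
    """
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    c = np.asarray(c, dtype=float)
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S) if S.size else 0
    free = n - rank
    best = None
    for k in range(free, n + 1):
        for fixed in itertools.combinations(range(n), k):
            basis = [j for j in range(n) if j not in fixed]
            S_B = S[:, basis]
            if basis and np.linalg.matrix_rank(S_B) < len(basis):
                continue  # no unique completion through these columns
            for assignment in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
                v = np.empty(n)
                for j, val in zip(fixed, assignment):
                    v[j] = val
                rhs = -S[:, fixed] @ np.array(assignment) if fixed else np.zeros(S.shape[0])
                if basis:
                    sol, *_ = np.linalg.lstsq(S_B, rhs, rcond=None)
                    if np.max(np.abs(S_B @ sol - rhs), initial=0.0) > 1e-9:
                        continue
                    for j, val in zip(basis, sol):
                        v[j] = val
                elif np.max(np.abs(rhs), initial=0.0) > 1e-9:
                    continue
                if np.any(v < lb - 1e-9) or np.any(v > ub + 1e-9):
                    continue
                if np.max(np.abs(S @ v), initial=0.0) > 1e-9:
                    continue
                val = float(c @ v)
                if best is None or val > best:
                    best = val
    return best


def fba_oracle(model, medium=None) -> float | None:
    """Vertex-enumeration FBA objective for a small StrainModel."""
    from lbpdesign.fba import stoichiometric_matrix
    from lbpdesign.model import apply_medium

    if medium is not None:
        model = apply_medium(model, medium)
    mets = sorted(model.metabolite_ids)
    S = stoichiometric_matrix(model.reactions, mets)
    lb = [r.lower_bound for r in model.reactions]
    ub = [r.upper_bound for r in model.reactions]
    c = [1.0 if r.id == model.biomass_reaction_id else 0.0 for r in model.reactions]
    return vertex_lp_max(S, lb, ub, c)


def mismatch_fraction(a: str, b: str) -> float:
    """Positional mismatch fraction of two equal-length sequences."""
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b)) / len(a)


def gapfill_oracle(model, medium, db, growth_threshold=1e-6):
    """All minimum-penalty growing subsets, by full enumeration."""
    from lbpdesign.fba import _augment, fba

    ids = sorted(r.id for r in db.reactions)
    best_penalty, best_sets = None, []
    for k in range(0, len(ids) + 1):
        for combo in itertools.combinations(ids, k):
            penalty = sum(db.penalties[i] for i in combo)
            if best_penalty is not None and penalty > best_penalty:
                continue
            aug = _augment(model, db, set(combo))
            sol = fba(aug, medium)
            if sol.status == "optimal" and sol.objective_value >= growth_threshold:
                if best_penalty is None or penalty < best_penalty:
                    best_penalty, best_sets = penalty, [combo]
                elif penalty == best_penalty:
                    best_sets.append(combo)
    return best_penalty, best_sets
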