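"""Independent brute-force oracles used by the test suite.

The LP oracle enumerates every basic feasible point (vertex) of the flux
polytope {A_eq v = b, lb <= v <= ub} directly — no simplex, no interior
point — so it is an implementation-independent check of the solver path.
Only bounded polytopes (all bounds finite) are admissible.
"""

from __future__ import annotations

import itertools

import numpy as np


def lp_vertex_optimum(
    A_eq: np.ndarray,
    b_eq: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    c: np.ndarray,
    sense: str = "max",
    tol: float = 1e-9,
) -> float | None:
    """Optimum of c·v over the polytope by exhaustive vertex enumeration.

    A vertex fixes n − m coordinates at a bound and solves the equality
    system for the rest; every such candidate is checked for feasibility
    and the best objective returned (None if the polytope is empty).
    """
    A_eq = np.asarray(A_eq, dtype=float)
    m, n = A_eq.shape
    lb, ub, c = (np.asarray(x, dtype=float) for x in (lb, ub, c))
    if not (np.isfinite(lb).all() and np.isfinite(ub).all()):
        raise ValueError("oracle needs finite bounds")
    sign = 1.0 if sense == "max" else -1.0
    best = None
    for free in itertools.combinations(range(n), m):
        A = A_eq[:, free]
        if np.linalg.matrix_rank(A) < m:
            continue
        fixed = [j for j in range(n) if j not in free]
        for choices in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            v = np.zeros(n)
            for j, val in zip(fixed, choices):
                v[j] = val
            rhs = b_eq - A_eq[:, fixed] @ np.array(choices) if fixed else b_eq
            try:
                v[list(free)] = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                continue
            if np.all(v >= lb - tol) and np.all(v <= ub + tol):
                val = sign * float(c @ v)
                if best is None or val > best:
                    best = val
    return None if best is None else sign * best


def model_polytope(model) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(S, b, lb, ub) of a MetabolicModel with no media caps applied."""
    S = model.stoichiometric_matrix()
    lb = np.array([r.lb for r in model.reactions])
    ub = np.array([r.ub for r in model.reactions])
    return S, np.zeros(S.shape[0]), lb, ub


def growth_oracle(model) -> float | None:
    """Exhaustive-enumeration maximal growth of a bounded toy model."""
    S, b, lb, ub = model_polytope(model)
    c = np.zeros(len(model.reactions))
    c[model.reaction_index(model.growth_reaction)] = 1.0
    return lp_vertex_optimum(S, b, lb, ub, c, sense="max")


def fva_oracle(model, growth: float, target: str) -> tuple[float, float] | None:
    """Exhaustive min/max of the target flux at growth fixed to `growth`."""
    S, b, lb, ub = model_polytope(model)
    n = len(model.reactions)
    row = np.zeros(n)
    row[model.reaction_index(model.growth_reaction)] = 1.0
    A = np.vstack([S, row])
    b2 = np.append(b, growth)
    c = np.zeros(n)
    c[model.reaction_index(model.targets[target].reaction_id)] = 1.0
    lo = lp_vertex_optimum(A, b2, lb, ub, c, sense="min")
    hi = lp_vertex_optimum(A, b2, lb, ub, c, sense="max")
    if lo is None or hi is None:
        return None
    return lo, hi
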