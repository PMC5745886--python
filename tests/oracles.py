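"""Independent brute-force oracles used by the test suite.

The lexicographic LP oracle enumerates every vertex of the flux polytope
{S v = 0, lb <= v <= ub} by fixing free variables at their bounds and
solving the resulting square systems, then filters the vertex set
objective by objective.  It shares no code with the GLPK solve path.
"""

import itertools

import numpy as np

from gutbiofilm.fba_engine import LexicographicSolver


def enumerate_vertices(S, lb, ub, tol=1e-8):
    """All vertices of {S v = 0, lb <= v <= ub} by brute force."""
    m, n = S.shape
    rank = np.linalg.matrix_rank(S)
    d = n - rank
    vertices = []
    for free in itertools.combinations(range(n), d):
        rest = [j for j in range(n) if j not in free]
        A = S[:, rest]
        if np.linalg.matrix_rank(A) < len(rest):
            continue
        for sides in itertools.product((0, 1), repeat=d):
            vals = np.array([lb[j] if s == 0 else ub[j]
                             for j, s in zip(free, sides)])
            if not np.all(np.isfinite(vals)):
                continue
            b = -S[:, list(free)] @ vals
            x_rest, *_ = np.linalg.lstsq(A, b, rcond=None)
            v = np.zeros(n)
            v[list(free)] = vals
            v[rest] = x_rest
            if np.max(np.abs(S @ v)) > tol:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            if not any(np.allclose(v, w, atol=1e-7) for w in vertices):
                vertices.append(v)
    return vertices


def lexicographic_oracle(net, uptake_bounds, tol=1e-7):
    """Lexicographic optimum by filtering the enumerated vertices."""
    rxns = net.reactions
    n = len(rxns)
    mets = list(net.metabolites)
    S = np.zeros((len(mets), n))
    lb = np.empty(n)
    ub = np.empty(n)
    for j, r in enumerate(rxns):
        for met, c in r.stoichiometry.items():
            S[mets.index(met), j] = c
        lb[j], ub[j] = r.lower_bound, r.upper_bound
        if r.id.startswith("EX_"):
            met = r.id[3:]
            if met in uptake_bounds and r.lower_bound < 0:
                lb[j] = -uptake_bounds[met]
    verts = enumerate_vertices(S, lb, ub)
    if not verts:
        return None
    order = LexicographicSolver(net).objective_order
    idx = {r.id: j for j, r in enumerate(rxns)}
    for rxn_id, sense in order:
        j = idx[rxn_id]
        key = max if sense == "max" else min
        best = key(v[j] for v in verts)
        verts = [v for v in verts if abs(v[j] - best) <= tol * (1 + abs(best))]
    return verts[0]
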