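"""Exact rational-arithmetic LP oracle for tiny flux polytopes.

Independent of the package's LP layer: enumerates all basic feasible
solutions (vertices) of {A x = b, lb <= x <= ub} with ``fractions.Fraction``
arithmetic, so optima of linear functionals over small instances are exact.
Only practical for networks of roughly a dozen reactions.
"""

from fractions import Fraction
from itertools import combinations, product


def _solve_square(A, b):
    """Solve a square rational system by Gaussian elimination.

    Returns the solution list or None when singular."""
    n = len(A)
    M = [row[:] + [b[i]] for i, row in enumerate(A)]
    for col in range(n):
        piv = next((r for r in range(col, n) if M[r][col] != 0), None)
        if piv is None:
            return None
        M[col], M[piv] = M[piv], M[col]
        inv = Fraction(1, 1) / M[col][col]
        M[col] = [v * inv for v in M[col]]
        for r in range(n):
            if r != col and M[r][col] != 0:
                f = M[r][col]
                M[r] = [v - f * w for v, w in zip(M[r], M[col])]
    return [M[i][n] for i in range(n)]


def _rref_rank(A):
    """Row-reduce a rational matrix in place (copy); return (rows, rank)."""
    M = [row[:] for row in A]
    rank = 0
    ncols = len(M[0]) if M else 0
    for col in range(ncols):
        piv = next((r for r in range(rank, len(M)) if M[r][col] != 0), None)
        if piv is None:
            continue
        M[rank], M[piv] = M[piv], M[rank]
        inv = Fraction(1, 1) / M[rank][col]
        M[rank] = [v * inv for v in M[rank]]
        for r in range(len(M)):
            if r != rank and M[r][col] != 0:
                f = M[r][col]
                M[r] = [v - f * w for v, w in zip(M[r], M[rank])]
        rank += 1
    return M, rank


def enumerate_vertices(A, b, lb, ub):
    """All vertices of {A x = b, lb <= x <= ub}, exactly.

    A is a list of rational rows, b the rational right-hand side; bounds are
    rational lists.  A vertex has n - rank(A) variables at a bound and the
    remaining (basic) variables determined by the equalities.
    """
    n = len(lb)
    A = [[Fraction(v) for v in row] for row in A]
    b = [Fraction(v) for v in b]
    lb = [Fraction(v) for v in lb]
    ub = [Fraction(v) for v in ub]
    # independent rows only
    aug, rank = _rref_rank([row + [rhs] for row, rhs in zip(A, b)])
    rows = [r[:-1] for r in aug[:rank]]
    rhs = [r[-1] for r in aug[:rank]]
    if any(all(v == 0 for v in aug[r][:-1]) and aug[r][-1] != 0 for r in range(len(aug))):
        return []
    vertices = set()
    for basic in combinations(range(n), rank):
        Ab = [[rows[r][j] for j in basic] for r in range(rank)]
        nonbasic = [j for j in range(n) if j not in basic]
        for choice in product((0, 1), repeat=len(nonbasic)):
            xN = {j: (lb[j] if c == 0 else ub[j]) for j, c in zip(nonbasic, choice)}
            rhs2 = [
                rhs[r] - sum(rows[r][j] * xN[j] for j in nonbasic)
                for r in range(rank)
            ]
            sol = _solve_square(Ab, rhs2)
            if sol is None:
                continue
            x = [Fraction(0)] * n
            for j, v in zip(basic, sol):
                x[j] = v
            for j in nonbasic:
                x[j] = xN[j]
            if all(lb[j] <= x[j] <= ub[j] for j in range(n)):
                vertices.add(tuple(x))
    return [list(v) for v in vertices]


def optimize(c, vertices, sense="max"):
    """Exact optimum of a linear functional over an explicit vertex list."""
    assert vertices, "empty polytope"
    vals = [sum(Fraction(ci) * xi for ci, xi in zip(c, v)) for v in vertices]
    return max(vals) if sense == "max" else min(vals)


def model_polytope(model, extra_eq=()):
    """Rational (A, b, lb, ub) of a package model's steady-state polytope.

    ``extra_eq`` holds extra equality rows as (coeff-dict keyed by reaction
    id, rhs).  All model data must be exactly representable (integer-valued
    bounds and coefficients)."""
    rids = list(model.reaction_ids)
    A = [[Fraction(float(v)) for v in row] for row in model.S]
    b = [Fraction(0)] * len(A)
    for coeffs, rhs in extra_eq:
        row = [Fraction(0)] * len(rids)
        for rid, cv in coeffs.items():
            row[rids.index(rid)] = Fraction(cv)
        A.append(row)
        b.append(Fraction(rhs))
    lb = [Fraction(float(v)) for v in model.LB]
    ub = [Fraction(float(v)) for v in model.UB]
    return A, b, lb, ub


def with_slack_lower_bound(A, b, lb, ub, var, bound, slack_ub):
    """Append a slack variable encoding x[var] >= bound.

    Adds the row x[var] - s = bound with s in [0, slack_ub]."""
    n = len(lb)
    A2 = [row[:] + [Fraction(0)] for row in A]
    row = [Fraction(0)] * (n + 1)
    row[var] = Fraction(1)
    row[n] = Fraction(-1)
    A2.append(row)
    return A2, b + [Fraction(bound)], lb + [Fraction(0)], ub + [Fraction(slack_ub)]
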