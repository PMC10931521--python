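"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct definition (explicit
selection keys, pair counting, closed-form step-up) so that it shares no
code path with the implementation it checks.
"""

import itertools

import numpy as np

from gemtide.gpr import GPRExpression


def gpr_weight_oracle(expr: GPRExpression, weights: dict[str, float]) -> float:
    """Recursive selection by explicit sort keys.

    AND keeps the child of minimum absolute value, OR of maximum; ties
    resolve toward the positive value, then the leftmost child.
    """
    if expr.kind == "gene":
        return float(weights.get(expr.gene, 0.0))
    values = [gpr_weight_oracle(c, weights) for c in expr.children]
    if expr.kind == "and":
        key = lambda iv: (abs(iv[1]), 0 if iv[1] > 0 else 1, iv[0])  # noqa: E731
    else:
        key = lambda iv: (-abs(iv[1]), 0 if iv[1] > 0 else 1, iv[0])  # noqa: E731
    return min(enumerate(values), key=key)[1]


def random_gpr_tree(rng: np.random.Generator, max_leaves: int = 6) -> GPRExpression:
    """Random tree with 1..max_leaves leaves over a small gene alphabet."""
    n_leaves = int(rng.integers(1, max_leaves + 1))
    genes = [f"g{i}" for i in range(max_leaves + 2)]
    nodes: list[GPRExpression] = [
        GPRExpression("gene", gene=genes[int(rng.integers(len(genes)))])
        for _ in range(n_leaves)
    ]
    while len(nodes) > 1:
        k = int(rng.integers(2, min(3, len(nodes)) + 1))
        picked = [nodes.pop(int(rng.integers(len(nodes)))) for _ in range(k)]
        kind = "and" if rng.random() < 0.5 else "or"
        nodes.append(GPRExpression(kind, children=tuple(picked)))
    return nodes[0]


def mwu_exact_oracle(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by pair counting over all labelings.

    U = #{x_i > y_j} + 0.5 * #{x_i == y_j}; the null enumerates every
    choice of which pooled values are 'x'; two-sided p doubles the
    smaller tail (capped at 1).
    """

    def u_of(xs, ys):
        u = 0.0
        for xi in xs:
            for yj in ys:
                if xi > yj:
                    u += 1.0
                elif xi == yj:
                    u += 0.5
        return u

    pooled = list(x) + list(y)
    n_x = len(x)
    observed = u_of(list(x), list(y))
    null = []
    for combo in itertools.combinations(range(len(pooled)), n_x):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        null.append(u_of(xs, ys))
    null = np.array(null)
    tol = 1e-9
    p_low = np.mean(null <= observed + tol)
    p_high = np.mean(null >= observed - tol)
    return observed, float(min(1.0, 2 * min(p_low, p_high)))


def bh_oracle(pvalues) -> np.ndarray:
    """Closed-form Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def min_total_flux_oracle(model, objective_value: float) -> float:
    """Minimum sum |v| at a fixed objective value, via scipy linprog.

    Splits each reaction into nonnegative forward/reverse parts and
    solves the LP with an independent solver (HiGHS), providing a
    cross-check for parsimonious FBA.
    """
    from cobra.util.array import create_stoichiometric_matrix
    from scipy.optimize import linprog

    S = create_stoichiometric_matrix(model)
    n = S.shape[1]
    c_obj = np.zeros(n)
    from cobra.util.solver import linear_reaction_coefficients

    for rxn, coef in linear_reaction_coefficients(model).items():
        c_obj[model.reactions.index(rxn)] = coef
    # variables: f_i, r_i >= 0 with v_i = f_i - r_i
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(S.shape[0])
    A_eq = np.vstack([A_eq, np.hstack([c_obj, -c_obj])])
    b_eq = np.append(b_eq, objective_value)
    lbs = np.array([r.lower_bound for r in model.reactions])
    ubs = np.array([r.upper_bound for r in model.reactions])
    bounds = [(0, max(0, ub)) for ub in ubs] + [(0, max(0, -lb)) for lb in lbs]
    cost = np.ones(2 * n)
    res = linprog(cost, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    assert res.success, res.message
    return float(res.fun)
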