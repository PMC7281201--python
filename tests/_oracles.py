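"""Independent brute-force oracles for small linear programs.

Vertex enumeration over the flux polytope {v : N v = 0, lb <= v <= ub}:
every vertex has at least n - rank(N) coordinates pinned at a bound, so
enumerating all such pinning patterns and solving the remaining square
system visits every vertex.  Exponential, usable only on toy networks
(n - m small), and entirely independent of any LP solver.
"""

from itertools import combinations, product

import numpy as np


def _vertices(N, lb, ub, tol=1e-9):
    N = np.asarray(N, dtype=float)
    m, n = N.shape
    rank = np.linalg.matrix_rank(N) if m else 0
    k = n - rank  # number of coordinates to pin
    seen = set()
    for pin_idx in combinations(range(n), k):
        free_idx = [j for j in range(n) if j not in pin_idx]
        A_free = N[:, free_idx]
        for choice in product((0, 1), repeat=k):
            x = np.full(n, np.nan)
            for j, c in zip(pin_idx, choice):
                x[j] = lb[j] if c == 0 else ub[j]
            rhs = -N[:, pin_idx] @ x[list(pin_idx)] if k else np.zeros(m)
            sol, residual, *_ = np.linalg.lstsq(A_free, rhs, rcond=None)
            x[free_idx] = sol
            if np.max(np.abs(N @ x)) > 1e-7:
                continue
            if np.any(x < np.asarray(lb) - tol) or np.any(x > np.asarray(ub) + tol):
                continue
            key = tuple(np.round(x, 7))
            if key not in seen:
                seen.add(key)
                yield x


def brute_force_optimum(model, objective, sense="max", bounds=None):
    """Optimal c·v over all vertices of a model's flux polytope."""
    from cyanogem.model import build_matrix

    N, met_ids, rxn_ids = build_matrix(model)
    N = N.toarray()
    if bounds is None:
        bounds = {rid: model.reactions[rid].bounds for rid in rxn_ids}
    lb = [bounds[r][0] for r in rxn_ids]
    ub = [bounds[r][1] for r in rxn_ids]
    c = np.array([objective.get(r, 0.0) for r in rxn_ids])
    best, best_x = None, None
    for x in _vertices(N, lb, ub):
        val = float(c @ x)
        if best is None or (val > best if sense == "max" else val < best):
            best, best_x = val, x
    return best, (dict(zip(rxn_ids, best_x)) if best_x is not None else None)


def brute_force_min_total_flux(model, bounds=None):
    """Minimal Σ|v| over the polytope, via vertices of the split system.

    The split system doubles variables (v = v⁺ − v⁻, both in [0, ·]),
    whose vertices cover all candidate minimizers of the piecewise-linear
    total flux.
    """
    from cyanogem.model import build_matrix

    N, met_ids, rxn_ids = build_matrix(model)
    N = N.toarray()
    if bounds is None:
        bounds = {rid: model.reactions[rid].bounds for rid in rxn_ids}
    n = len(rxn_ids)
    Ns = np.hstack([N, -N])
    lb = [max(bounds[r][0], 0.0) for r in rxn_ids] + [
        max(-bounds[r][1], 0.0) for r in rxn_ids
    ]
    ub = [max(bounds[r][1], 0.0) for r in rxn_ids] + [
        max(-bounds[r][0], 0.0) for r in rxn_ids
    ]
    best, best_v = None, None
    for x in _vertices(Ns, lb, ub):
        v = x[:n] - x[n:]
        total = float(np.sum(np.abs(v)))
        if best is None or total < best:
            best, best_v = total, dict(zip(rxn_ids, v))
    return best, best_v
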