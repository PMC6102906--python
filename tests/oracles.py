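"""Independent brute-force oracles used to cross-check the implementation.

These deliberately recompute everything from scratch with a different code
path (statsmodels OLS fits, exhaustive grid search) so they share no
numerics with the library code they verify.
"""

import numpy as np
import statsmodels.api as sm


def oracle_swlda(X, y, p_enter=0.10, p_remove=0.15, max_features=60):
    """Exhaustive stepwise regression: refits OLS for every candidate at
    every forward step and for the full model at every backward step."""
    n, p = X.shape
    sel: list[int] = []
    seen = set()
    while True:
        moved = False
        if len(sel) < max_features:
            best = None
            for j in range(p):
                if j in sel:
                    continue
                A = sm.add_constant(X[:, sel + [j]], has_constant="add")
                if np.linalg.matrix_rank(A) < A.shape[1]:
                    continue
                pv = sm.OLS(y, A).fit().pvalues[-1]
                if best is None or pv < best[1] - 1e-12 or (
                        abs(pv - best[1]) <= 1e-12 and j < best[0]):
                    best = (j, pv)
            if best is not None and best[1] < p_enter:
                sel.append(best[0])
                moved = True
        while sel:
            A = sm.add_constant(X[:, sel], has_constant="add")
            pvs = dict(zip(sel, sm.OLS(y, A).fit().pvalues[1:]))
            j, pj = max(pvs.items(), key=lambda kv: (kv[1], kv[0]))
            if pj > p_remove:
                sel.remove(j)
                moved = True
            else:
                break
        key = frozenset(sel)
        if not moved or key in seen:
            break
        seen.add(key)
    if sel:
        fit = sm.OLS(y, sm.add_constant(X[:, sel], has_constant="add")).fit()
        return sel, np.asarray(fit.params[1:]), float(fit.params[0])
    return sel, np.zeros(0), float(np.mean(y))


def oracle_principal_axis(points_xy, step_deg=1.0):
    """Axis maximizing projected variance, by exhaustive 1-degree search."""
    pts = np.asarray(points_xy, dtype=float)
    pts = pts - pts.mean(axis=0)
    best, best_var = None, -1.0
    for deg in np.arange(0.0, 180.0, step_deg):
        a = np.array([np.cos(np.radians(deg)), np.sin(np.radians(deg))])
        var = float(np.var(pts @ a))
        if var > best_var:
            best, best_var = a, var
    return best


def oracle_orientation(points_xy, wheelchair_xy, step_deg=1.0):
    """Exhaustive version of the v/vn/f selection rule."""
    pts = np.asarray(points_xy, dtype=float)
    centre = pts.mean(axis=0)
    f = centre - np.asarray(wheelchair_xy, dtype=float)
    f = f / np.linalg.norm(f)
    v = oracle_principal_axis(points_xy, step_deg)
    vn = np.array([-v[1], v[0]])

    def la(u):
        return np.arccos(np.clip(abs(np.dot(u, f)), 0, 1))

    axis = v if la(v) <= la(vn) else vn
    if np.dot(axis, f) > 0:
        axis = -axis
    return axis
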