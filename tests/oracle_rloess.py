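"""Brute-force reference RLOESS, independent of the package implementation.

Plain per-point loops with explicitly assembled normal equations and
explicit tricube/bisquare weight recomputation on every pass.  Used only
as a cross-check oracle in tests.
"""

import numpy as np


def rloess_bruteforce(x, y, span=40.0, robust_iterations=5, outlier_cutoff=6.0,
                      scale_floor_fraction=1e-3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size

    def one_pass(robust_w):
        fitted = np.empty(n)
        for i in range(n):
            mask = np.abs(x - x[i]) <= span / 2.0
            xs = x[mask] - x[i]
            ys = y[mask]
            d = np.abs(xs)
            dmax = d.max()
            tri = (1.0 - (d / dmax) ** 3) ** 3 if dmax > 0 else np.ones_like(d)
            w = tri * robust_w[mask]
            if np.count_nonzero(w) < 3:
                w = np.ones_like(w)
            design = np.empty((xs.size, 3))
            design[:, 0] = 1.0
            design[:, 1] = xs
            design[:, 2] = xs * xs
            normal = design.T @ (w[:, None] * design)
            rhs = design.T @ (w * ys)
            fitted[i] = np.linalg.solve(normal, rhs)[0]
        return fitted

    robust_w = np.ones(n)
    fitted = one_pass(robust_w)
    floor = scale_floor_fraction * np.max(np.abs(y - np.median(y)))
    for _ in range(robust_iterations):
        resid = y - fitted
        if np.all(resid == 0):
            break
        scale = outlier_cutoff * max(np.median(np.abs(resid)), floor)
        if scale == 0:
            robust_w = (resid == 0).astype(float)
        else:
            u = resid / scale
            robust_w = np.where(np.abs(u) < 1.0, (1.0 - u * u) ** 2, 0.0)
        fitted = one_pass(robust_w)
    return fitted
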