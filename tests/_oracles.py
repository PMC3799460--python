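"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the grid search
evaluates the blurred-box model through its own local definition, the OLS
oracle uses closed-form sums, and the quantile oracle sorts by hand.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import erf


def erfbox_local(x, c, w, a, b, s):
    s = np.sqrt(2.0) * max(abs(s), 1e-12)
    return b + 0.5 * a * (erf((x - c + w / 2) / s) - erf((x - c - w / 2) / s))


def grid_search_rss(
    profile: np.ndarray,
    c_range: tuple[float, float],
    w_range: tuple[float, float],
    step: float = 0.1,
    sigma_bounds: tuple[float, float] = (0.3, 6.0),
) -> float:
    """Exhaustive least squares over (c, w) on a fixed lattice.

    For each lattice point the amplitude and background are solved in closed
    form (linear least squares) and the blur width is profiled out with a
    bounded 1D minimization.  Returns the minimal residual sum of squares.
    """
    x = np.arange(profile.size) + 0.5
    cs = np.arange(c_range[0], c_range[1] + step / 2, step)
    ws = np.arange(w_range[0], w_range[1] + step / 2, step)

    def rss_for(c, w, s):
        shape = erfbox_local(x, c, w, 1.0, 0.0, s)
        design = np.column_stack([shape, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(design, profile, rcond=None)
        resid = profile - design @ coef
        return float(resid @ resid)

    best = np.inf
    for c in cs:
        for w in ws:
            res = minimize_scalar(
                lambda s: rss_for(c, w, s),
                bounds=sigma_bounds,
                method="bounded",
                options={"xatol": 1e-4},
            )
            if res.fun < best:
                best = res.fun
    return best


def ols_closed_form(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Intercept and slope from the textbook normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sx, sy, sxy, sxx = x.sum(), y.sum(), (x * y).sum(), (x * x).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return intercept, slope


def empirical_quantile(values, q: float) -> float:
    """Linear-interpolated empirical quantile computed by explicit sorting."""
    v = np.sort(np.asarray(values, dtype=float))
    h = (v.size - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, v.size - 1)
    return float(v[lo] + (h - lo) * (v[hi] - v[lo]))
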