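"""Canonical intensity-profile model for a nanochannel-confined molecule.

A uniformly emitting molecule of extension ``w`` centred at ``c`` produces a
box-shaped emission profile along the channel.  Blurring by a Gaussian
point-spread function of width ``sigma`` turns the box into a difference of
two error functions::

    I(x) = b + (A/2) * [ erf((x - c + w/2) / (sqrt(2)*sigma))
                       - erf((x - c - w/2) / (sqrt(2)*sigma)) ]

with plateau amplitude ``A`` and additive background ``b``.  The same closed
form is used as the forward model by the simulator and as the fit model by
the profile fitter, so the two stages share a single definition.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["erf_box", "erf_box_jacobian"]

_SQRT2 = np.sqrt(2.0)
_GAUSS_NORM = 2.0 / np.sqrt(np.pi)


def erf_box(x, center, width, plateau, background, sigma):
    """Evaluate the blurred-box profile at positions ``x``.

    All of ``x``, ``center``, ``width`` and ``sigma`` must share one unit
    (pixels or microns).  ``sigma`` is taken in absolute value so the model
    is well defined for any real argument the optimizer tries.
    """
    x = np.asarray(x, dtype=float)
    s = _SQRT2 * max(abs(float(sigma)), 1e-12)
    half = 0.5 * float(width)
    rise = erf((x - center + half) / s)
    fall = erf((x - center - half) / s)
    return background + 0.5 * plateau * (rise - fall)


def erf_box_jacobian(x, center, width, plateau, background, sigma):
    """Analytic Jacobian of :func:`erf_box`, shape (len(x), 5).

    Columns are the partial derivatives with respect to
    (center, width, plateau, background, sigma).
    """
    x = np.asarray(x, dtype=float)
    sig = max(abs(float(sigma)), 1e-12)
    s = _SQRT2 * sig
    up = (x - center + 0.5 * width) / s
    un = (x - center - 0.5 * width) / s
    gp = _GAUSS_NORM * np.exp(-up * up)
    gn = _GAUSS_NORM * np.exp(-un * un)
    a = float(plateau)
    d_center = -a / (2.0 * s) * (gp - gn)
    d_width = a / (4.0 * s) * (gp + gn)
    d_plateau = 0.5 * (erf(up) - erf(un))
    d_background = np.ones_like(x)
    d_sigma = -a / (2.0 * sig) * (gp * up - gn * un)
    return np.column_stack([d_center, d_width, d_plateau, d_background, d_sigma])
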