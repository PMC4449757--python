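"""Density-dependent immigration between a controlled and an uncontrolled patch.

The dispersal mechanism shared by every model tier is ideal-free-style
habitat selection: animals move toward the patch with more per-capita
resource.  The signed resource gradient

    G = (Ac / Nc) - (Au / Nu)

compares carrying capacity per head between the controlled patch (``c``)
and the uncontrolled patch (``u``); ``G > 0`` means the controlled patch
offers more resource per individual, which is exactly what control
mortality produces, and is what turns the controlled patch into an
attractive sink.  The gradient is mapped onto a bounded immigration rate
with a hyperbolic-tangent response, ``f = tanh(gamma * G)``, where
``gamma`` sets how strongly animals respond to the gradient.

All functions accept scalars or NumPy arrays and broadcast like ufuncs, so
the same code drives both the deterministic tier and the vectorised
Monte-Carlo replicates of the stochastic tier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DispersalParams",
    "resource_gap",
    "immigration_rate",
    "dispersal_flux",
]

#: Default ceiling for a per-capita resource quotient.  When a patch
#: empties its quotient diverges; capping it keeps the gradient finite
#: while leaving tanh fully saturated (tanh saturates near |x| ~ 20, so
#: any large finite cap gives an immigration rate indistinguishable from 1).
DEFAULT_GAP_CAP = 1.0e6


@dataclass(frozen=True)
class DispersalParams:
    """Parameters of the density-dependent immigration response.

    Parameters
    ----------
    gamma : float
        Strength of density dependence, dimensionless and positive.  The
        two study values are 0.1 (weak) and 1.0 (strong).
    gap_cap : float, optional
        Finite ceiling applied to each per-capita resource quotient and to
        the gradient itself.
    flux_convention : str, optional
        How the rate is turned into moved individuals.  Only
        ``"fraction_of_source"`` is defined: a rate ``f`` moves ``f``
        times the source-patch abundance per step.
    """

    gamma: float
    gap_cap: float = DEFAULT_GAP_CAP
    flux_convention: str = "fraction_of_source"

    def __post_init__(self) -> None:
        if not (self.gamma > 0 and math.isfinite(self.gamma)):
            raise ValueError(f"gamma must be positive and finite, got {self.gamma}")
        if not (self.gap_cap > 0 and math.isfinite(self.gap_cap)):
            raise ValueError(f"gap_cap must be positive and finite, got {self.gap_cap}")
        if self.flux_convention != "fraction_of_source":
            raise ValueError(
                f"unknown flux convention {self.flux_convention!r}; "
                "only 'fraction_of_source' is supported"
            )


def _capped_quotient(num, den, cap):
    """num / den with the quotient replaced by ``cap`` where den == 0."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast(num, den).shape, float(cap))
    np.divide(num, den, out=out, where=den > 0)
    return np.minimum(out, cap)


def resource_gap(cap_c, n_c, cap_u, n_u, cap: float = DEFAULT_GAP_CAP):
    """Signed per-capita resource gradient between the two patches.

    ``G = cap_c/n_c - cap_u/n_u``, with each quotient replaced by ``cap``
    when its denominator is zero (an empty patch offers effectively
    unlimited per-capita resource) and the result clipped to
    ``[-cap, +cap]``.

    Parameters
    ----------
    cap_c, cap_u : array_like
        Carrying capacity (or expected no-control abundance) of the
        controlled and uncontrolled patch; strictly positive.
    n_c, n_u : array_like
        Current abundance in each patch; non-negative.
    cap : float, optional
        Quotient and gradient ceiling.

    Returns
    -------
    float or ndarray
        The gradient; positive when the controlled patch has more
        per-capita resource.
    """
    arrs = [np.asarray(a, dtype=float) for a in (cap_c, n_c, cap_u, n_u)]
    for a in arrs:
        if not np.all(np.isfinite(a)):
            raise ValueError("resource_gap: non-finite input")
    cc, nc, cu, nu = arrs
    if np.any(cc <= 0) or np.any(cu <= 0):
        raise ValueError("resource_gap: carrying capacities must be positive")
    if np.any(nc < 0) or np.any(nu < 0):
        raise ValueError("resource_gap: abundances must be non-negative")
    g = _capped_quotient(cc, nc, cap) - _capped_quotient(cu, nu, cap)
    g = np.clip(g, -cap, cap)
    return g if g.ndim else float(g)


def immigration_rate(gap, params: DispersalParams):
    """Bounded immigration rate ``f = tanh(gamma * G)``.

    Odd and strictly increasing in the gradient, saturating at +/-1.  The
    sign gives the direction of flow: positive moves animals from the
    uncontrolled into the controlled patch.
    """
    if not isinstance(params, DispersalParams):
        raise TypeError("params must be a DispersalParams")
    f = np.tanh(params.gamma * np.asarray(gap, dtype=float))
    return f if f.ndim else float(f)


def dispersal_flux(f, n_source, n_dest):
    """Apply an immigration rate and return the conserved post-flux state.

    With the fraction-of-source convention a non-negative rate moves
    ``f * n_source`` individuals from the (uncontrolled) source into the
    (controlled) destination; a negative rate reverses the flow with
    magnitude ``|f| * n_dest``.

    Parameters
    ----------
    f : array_like
        Immigration rate in [-1, 1].
    n_source, n_dest : array_like
        Abundance of the source (uncontrolled) and destination
        (controlled) patch; non-negative.

    Returns
    -------
    moved, n_source_new, n_dest_new
        Signed number moved (positive toward the destination) and the two
        updated abundances.  ``n_source_new + n_dest_new`` equals the
        pre-flux total exactly.
    """
    f = np.asarray(f, dtype=float)
    ns = np.asarray(n_source, dtype=float)
    nd = np.asarray(n_dest, dtype=float)
    if np.any(np.abs(f) > 1):
        raise ValueError("dispersal_flux: |f| must not exceed 1")
    if np.any(ns < 0) or np.any(nd < 0):
        raise ValueError("dispersal_flux: abundances must be non-negative")
    moved = np.where(f >= 0, f * ns, f * nd)
    ns_new = ns - moved
    nd_new = nd + moved
    if np.any(ns_new < 0) or np.any(nd_new < 0):  # |f| <= 1 makes this unreachable
        raise RuntimeError("dispersal_flux: conservation violated (negative patch)")
    if moved.ndim:
        return moved, ns_new, nd_new
    return float(moved), float(ns_new), float(nd_new)
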