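"""Quasi-steady concentration gradients along the tumor microvasculature.

Plasma traverses the capillary bed of the imaged tumor segment in one
transit time; the normalized coordinate ``x`` in [0, 1] is equivalent to
the fractional residence time.  Along ``x`` two coupled linear ODEs hold
instantaneously at each moment of the (much slower) compartmental
dynamics:

* free drug:      dc_p/dx = k (c_e - c_p) + r * c_dds_sys   (while DDS payload remains)
* encapsulated:   dc_dds/dx = -r * c_dds_sys                (floored at 0)

with ``k = PS/F_p`` the permeability index and ``r = TT/t_rel`` the
normalized zero-order release rate.  Because the system is linear with a
piecewise-constant release term it has an exact piecewise-exponential
solution, used both for speed (the compartment model re-solves the
gradient at every ODE evaluation) and for the plateau fixed point, which
is linear in the unknown plateau concentration and solves in closed
form.

Boundary conditions: the free drug enters at the systemic free plasma
concentration and the encapsulated drug at the systemic encapsulated
concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Optional

import numpy as np

from .errors import InvalidParameterError


@dataclass
class GradientInputs:
    """Instantaneous inputs to the gradient solve.

    ``k``: permeability index PS/F_p; ``r``: normalized release rate
    TT/t_rel (0 = no release); ``c_e_T``: tumor EES concentration;
    ``c_p_in``: inlet free concentration (systemic free plasma);
    ``c_dds_sys``: systemic encapsulated concentration entering the
    release term; ``c_dds_in``: inlet encapsulated concentration
    (defaults to ``c_dds_sys``).
    """

    k: float
    r: float = 0.0
    c_e_T: float = 0.0
    c_p_in: float = 0.0
    c_dds_sys: float = 0.0
    c_dds_in: Optional[float] = None

    def __post_init__(self):
        if self.c_dds_in is None:
            self.c_dds_in = self.c_dds_sys
        if self.k < 0 or self.r < 0:
            raise InvalidParameterError("k and r must be >= 0")
        for name in ("c_e_T", "c_p_in", "c_dds_sys", "c_dds_in"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")


class GradientEndpoint(NamedTuple):
    """Outlet values and capillary means of one gradient solve."""

    c_p_out: float       # free concentration at x=1
    c_dds_out: float     # encapsulated concentration at x=1
    c_extr: float        # cumulative extracted amount at x=1 (may be < 0)
    mean_c_p: float      # spatial mean of the free profile
    mean_c_dds: float    # spatial mean of the encapsulated profile


@dataclass
class GradientProfile:
    """Sampled profiles along the capillary plus the closed-form summary."""

    x: np.ndarray
    c_p_T: np.ndarray
    c_p_DDS_T: np.ndarray
    c_extr_T: np.ndarray
    inputs: GradientInputs
    endpoint: GradientEndpoint = None


def _segment1(k, r_eff, c_e, c_p_in, x):
    """Closed form on the release-active segment: (c_p, c_extr, int c_p)."""
    if k > 0.0:
        s = c_e + r_eff / k
        em = np.exp(-k * x) if isinstance(x, np.ndarray) else math.exp(-k * x)
        c_p = s + (c_p_in - s) * em
        c_extr = r_eff * x + (c_p_in - s) * (1.0 - em)
        integral = s * x + (c_p_in - s) * (1.0 - em) / k
    else:
        c_p = c_p_in + r_eff * x
        c_extr = 0.0 * x
        integral = c_p_in * x + 0.5 * r_eff * x * x
    return c_p, c_extr, integral


def _segment2(k, c_e, p1, e1, i1, dx):
    """Closed form past payload exhaustion (pure exchange)."""
    if k > 0.0:
        em = np.exp(-k * dx) if isinstance(dx, np.ndarray) else math.exp(-k * dx)
        c_p = c_e + (p1 - c_e) * em
        c_extr = e1 + (p1 - c_e) * (1.0 - em)
        integral = i1 + c_e * dx + (p1 - c_e) * (1.0 - em) / k
    else:
        c_p = p1 + 0.0 * dx
        c_extr = e1 + 0.0 * dx
        integral = i1 + p1 * dx
    return c_p, c_extr, integral


def solve_endpoint(inputs: GradientInputs) -> GradientEndpoint:
    """Outlet concentrations, extracted amount and capillary means.

    Scalar fast path evaluated at every compartment-model ODE step.
    """
    k = inputs.k
    r_eff = inputs.r * inputs.c_dds_sys
    c_e = inputs.c_e_T
    c_p_in = inputs.c_p_in
    c_dds_in = inputs.c_dds_in

    if r_eff > 0.0 and c_dds_in > 0.0:
        x_star = c_dds_in / r_eff
    else:
        x_star = math.inf
        r_eff = 0.0

    if x_star >= 1.0:
        c_p1, extr1, int1 = _segment1(k, r_eff, c_e, c_p_in, 1.0)
        c_dds_out = c_dds_in - r_eff
        mean_dds = c_dds_in - 0.5 * r_eff
        return GradientEndpoint(c_p1, c_dds_out, extr1, int1, mean_dds)

    p1, e1, i1 = _segment1(k, r_eff, c_e, c_p_in, x_star)
    c_p1, extr1, int1 = _segment2(k, c_e, p1, e1, i1, 1.0 - x_star)
    mean_dds = 0.5 * c_dds_in * x_star   # triangle, zero afterwards
    return GradientEndpoint(c_p1, 0.0, extr1, int1, mean_dds)


def solve_profile(inputs: GradientInputs, n_grid: int = 101) -> GradientProfile:
    """Sample the exact piecewise closed-form profiles on a uniform grid."""
    if n_grid < 2:
        raise InvalidParameterError("n_grid must be >= 2")
    x = np.linspace(0.0, 1.0, n_grid)
    k = inputs.k
    r_eff = inputs.r * inputs.c_dds_sys
    c_e = inputs.c_e_T
    c_dds_in = inputs.c_dds_in

    if r_eff > 0.0 and c_dds_in > 0.0:
        x_star = c_dds_in / r_eff
    else:
        x_star = math.inf
        r_eff = 0.0

    c_p = np.empty_like(x)
    c_extr = np.empty_like(x)
    m1 = x <= x_star
    cp1, ce1, _ = _segment1(k, r_eff, c_e, inputs.c_p_in, x[m1])
    c_p[m1], c_extr[m1] = cp1, ce1
    if not m1.all():
        p1, e1, i1 = _segment1(k, r_eff, c_e, inputs.c_p_in, x_star)
        cp2, ce2, _ = _segment2(k, c_e, p1, e1, i1, x[~m1] - x_star)
        c_p[~m1], c_extr[~m1] = cp2, ce2
    c_dds = np.maximum(0.0, c_dds_in - r_eff * x)

    return GradientProfile(
        x=x, c_p_T=c_p, c_p_DDS_T=c_dds, c_extr_T=c_extr,
        inputs=inputs, endpoint=solve_endpoint(inputs))


def extracted_amount(profile: GradientProfile) -> float:
    """Cumulative extracted amount at the venous end, from the closed form.

    Negative values mean net back-diffusion from the EES into plasma.
    """
    return profile.endpoint.c_extr


def plateau_concentration(RI: float, PI: float) -> float:
    """Plateau concentration as a fraction of the maximum possible.

    At the quasi-steady plateau the EES and capillary-mean plasma
    concentrations coincide and net extraction vanishes, so the plateau
    ``C`` satisfies the fixed point ``C = \\int_0^1 c_p(x; C) dx`` under
    the plateau assumptions: systemic encapsulated concentration
    constant (normalized to 1) and zero inlet free concentration.  The
    profile is linear in ``C``; writing ``c_p = C u(x) + v(x)`` with
    ``u' = k(1-u)``, ``v' = -k v + r 1[x < x*]`` gives
    ``C = V / (1 - U)`` with ``U = \\int u``, ``V = \\int v``.

    The result is the hard ceiling on tumor uptake for a delivery system
    with release index ``RI = t_rel/TT`` in a tissue with permeability
    index ``PI = PS/F_p``; it depends on those two ratios only.
    """
    if not (RI > 0 and PI > 0):
        raise InvalidParameterError("RI and PI must be > 0")
    k = PI
    r = 1.0 / RI
    x_star = RI   # where the payload runs out (c_dds = 1 - r x)

    U = 1.0 - (-math.expm1(-k)) / k          # int of 1 - e^{-kx}
    if x_star >= 1.0:
        V = (r / k) * (1.0 - (-math.expm1(-k)) / k)
    else:
        V = (r / k) * (x_star - (-math.expm1(-k * x_star)) / k)
        v_star = (r / k) * (-math.expm1(-k * x_star))
        V += v_star * (-math.expm1(-k * (1.0 - x_star))) / k
    return V / (1.0 - U)


def plateau_profile(RI: float, PI: float, n_grid: int = 101) -> GradientProfile:
    """The gradient profile at the plateau fixed point (c_max normalized 1)."""
    C = plateau_concentration(RI, PI)
    return solve_profile(
        GradientInputs(k=PI, r=1.0 / RI, c_e_T=C, c_p_in=0.0, c_dds_sys=1.0),
        n_grid=n_grid)
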