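"""Closed-form worked examples and figure-reproduction setups.

Three canonical scenarios exercise the whole solution machinery; each is
redundant by construction with the generic Green's-function propagator and
serves as its verification surface.

1. *Delta start*: all carriers begin with all cargo external.  The density
   stays a delta in ``v`` and is a pure Gaussian in ``u`` whose mean slides
   from ``M/N`` to ``muE - muI`` while its variance grows as ``sigma(t)``.
2. *Opposite-preference Gaussian start* (rates ``KEI = 1/(3 tau)``,
   ``KIE = 2/(3 tau)``, so ``muE = 2 muI``): the initial loads are the
   mirror image of the equilibrium ones, and the full space-time density
   has the compact closed form ``y_eq(x,z) * exp(-(N/4M) e^{-2t/tau} (x+z)
   [(x+z) + 2 e^{t/tau} (x - 2z)])``.  The maximum travels along the linear
   path ``ME(t)/N = (M/3N)(2 - e^{-t/tau})`` (slope -1 in the (x, z) plane)
   and the u-variance dips to ``(8/9) M/N`` at ``t = tau ln 2``.
3. *Two-Gaussian mixtures*: redistributing the initial mixture along lines
   of constant total cargo leaves ``f(v)`` -- and hence the equilibrium --
   unchanged; redistributing along the ``x`` axis changes both.
"""

from __future__ import annotations

import math

import numpy as np

from .conditions import DeltaIC, GaussianIC, MixtureIC, ProductBinomialIC
from .core import TwoCompartmentParams
from .errors import DegenerateDeltaError, ParameterError
from .fokker_planck import equilibrium_continuum, f_of_v, sigma

__all__ = [
    "example1_ic",
    "example1_marginal",
    "example2_params",
    "example2_ic",
    "example2_field",
    "example2_path",
    "example2_variances",
    "example3_ic",
    "figure3_master_setup",
    "FIGURE_TIMES_TAU",
]

#: figure times in units of tau (infinity = the equilibrium field)
FIGURE_TIMES_TAU = (0.0, math.log(4 / 3), math.log(2), math.log(4), math.inf)


def example1_ic(params: TwoCompartmentParams) -> DeltaIC:
    """All cargo external and identical across carriers: delta at u = v = M/N."""
    c = params.cargo_per_carrier
    return DeltaIC(u0=c, v0=c)


def example1_marginal(u, t, params: TwoCompartmentParams):
    """u-marginal of the delta-start solution: ``2N G(u, M/N, t | M/N)``.

    A Gaussian with mean ``muE - muI (1 - 2 e^{-t/tau})`` and variance
    ``sigma(t)``; at t <= 0 the distribution is still the initial delta.
    """
    if t <= 0:
        raise DegenerateDeltaError("the delta-start marginal is a delta peak at t <= 0")
    m = params.muE - params.muI * (1.0 - 2.0 * math.exp(-t / params.tau))
    s2 = sigma(t, params)
    u = np.asarray(u, dtype=float)
    out = 2.0 * params.N * np.exp(-((u - m) ** 2) / (2 * s2)) / np.sqrt(2 * np.pi * s2)
    return float(out) if out.ndim == 0 else out


def example2_params(
    M_over_N: float = 100.0,
    N: int = 100,
    tau: float = 1.0,
    mE=math.inf,
    mI=math.inf,
) -> TwoCompartmentParams:
    """Rates ``KEI = 1/(3 tau)``, ``KIE = 2/(3 tau)`` so that muE = (2/3) M/N."""
    return TwoCompartmentParams(
        mE=mE, mI=mI, KEI=1.0 / (3.0 * tau), KIE=2.0 / (3.0 * tau), N=N, M=M_over_N * N
    )


def _require_example2(params: TwoCompartmentParams):
    if abs(params.KEI / params.KIE - 0.5) > 1e-12:
        raise ParameterError("example 2 requires KEI/KIE = 1/2 (muE = 2 muI)")


def example2_ic(params: TwoCompartmentParams) -> GaussianIC:
    """Initial loads opposite to equilibrium: etaE = muI = M/(3N), etaI = muE."""
    _require_example2(params)
    c = params.cargo_per_carrier
    return GaussianIC(etaE=c / 3.0, etaI=2.0 * c / 3.0)


def example2_field(x, z, t, params: TwoCompartmentParams):
    """Closed-form density of the opposite-preference Gaussian start.

    ``y(x,z,t) = y_eq(x,z) exp(-(N/4M) e^{-2t/tau} (x+z)
    [(x+z) + 2 e^{t/tau} (x-2z)])``; reduces to the initial product
    Gaussian (means M/3N, 2M/3N) at t=0 and to the equilibrium product
    Gaussian (means 2M/3N, M/3N) as t -> inf.
    """
    _require_example2(params)
    if t < 0:
        raise ParameterError("t must be >= 0")
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    c = params.cargo_per_carrier
    muE, muI = params.muE, params.muI
    y_eq = (
        params.N
        / (2 * np.pi * np.sqrt(muE * muI))
        * np.exp(-((x - muE) ** 2) / (2 * muE) - ((z - muI) ** 2) / (2 * muI))
    )
    # exponent written with decaying factors only so large t cannot overflow
    E = math.exp(-t / params.tau)
    out = y_eq * np.exp(-(1.0 / (4.0 * c)) * (x + z) * (E * E * (x + z) + 2.0 * E * (x - 2 * z)))
    return float(out) if out.ndim == 0 else out


def example2_path(t, params: TwoCompartmentParams):
    """Mean path ``(ME/N, MI/N) = (M/3N)(2 - E, 1 + E)``, slope -1 in (x, z)."""
    _require_example2(params)
    t = np.asarray(t, dtype=float)
    c3 = params.cargo_per_carrier / 3.0
    E = np.exp(-t / params.tau)
    ME_over_N = c3 * (2.0 - E)
    MI_over_N = c3 * (1.0 + E)
    if ME_over_N.ndim == 0:
        return float(ME_over_N), float(MI_over_N)
    return ME_over_N, MI_over_N


def example2_variances(t, params: TwoCompartmentParams):
    """``(var_v, var_u)``: var_v = M/N throughout; var_u dips to (8/9) M/N.

    ``var_u(t) = (M/N) (1 - (4/9)(E - E^2))``, E = e^{-t/tau}; the minimum
    sits at E = 1/2, i.e. t = tau ln 2.
    """
    _require_example2(params)
    t = np.asarray(t, dtype=float)
    c = params.cargo_per_carrier
    E = np.exp(-t / params.tau)
    var_u = c * (1.0 - (4.0 / 9.0) * (E - E * E))
    var_v = np.full_like(var_u, c)
    if var_u.ndim == 0:
        return float(var_v), float(var_u)
    return var_v, var_u


def example3_ic(kind: str, params: TwoCompartmentParams) -> MixtureIC:
    """Two-Gaussian mixture starts (equal weights).

    ``fig4-left``: the second component shifts cargo from internal to
    external along fixed total load -- etaE2 = etaE1 (1 + e^{-0.4}),
    etaI2 = etaI1 (1 - e^{-0.4}/2) -- so each component keeps
    etaE + etaI = M/N, f(v) matches the single-Gaussian start, and the
    equilibrium is unchanged.

    ``fig4-right``: the components are separated along the x axis --
    etaE = (1/3 -+ 1/10) M/N with etaI = (2/3) M/N for both -- which alters
    f(v) and therefore the equilibrium.
    """
    _require_example2(params)
    c = params.cargo_per_carrier
    if kind == "fig4-left":
        e1, i1 = c / 3.0, 2.0 * c / 3.0
        shift = math.exp(-0.4)
        e2 = e1 * (1.0 + shift)
        i2 = i1 * (1.0 - shift / 2.0)
    elif kind == "fig4-right":
        e1 = (1.0 / 3.0 - 1.0 / 10.0) * c
        e2 = (1.0 / 3.0 + 1.0 / 10.0) * c
        i1 = i2 = 2.0 * c / 3.0
    else:
        raise ParameterError(f"unknown example-3 kind {kind!r}")
    return MixtureIC(weights=(0.5, 0.5), etaEs=(e1, e2), etaIs=(i1, i2))


def figure3_master_setup(
    scale: float = 1.0, tau: float = 1.0
) -> tuple[TwoCompartmentParams, ProductBinomialIC]:
    """Finite-grid configuration matched against the continuum closed form.

    ``KEI = 1/(3 tau)``, ``KIE = 2/(3 tau)``, N = 100 carriers, M = 10,000
    cargo items, site counts mE = mI = 2500 (scaled by ``scale`` for smaller
    runs), and a product-binomial start with ``p0 = M/(3 N mE)``,
    ``q0 = 2M/(3 N mI)`` (mean loads M/3, 2M/3).
    """
    m = int(round(2500 * scale))
    if m < 1:
        raise ParameterError("scale too small: no sites left")
    N, M = 100, 10_000
    params = example2_params(M_over_N=M / N, N=N, tau=tau, mE=m, mI=m)
    ic = ProductBinomialIC(p0=M / (3.0 * N * m), q0=2.0 * M / (3.0 * N * m))
    return params, ic


def cross_section(dist, v: int):
    """Anti-diagonal slice ``(i, y[i, v-i])`` of a discrete distribution."""
    mE, mI = int(dist.params.mE), int(dist.params.mI)
    i = np.arange(max(0, v - mI), min(v, mE) + 1)
    return i, dist.y[i, v - i]


def equilibrium_field_example2(params: TwoCompartmentParams):
    """Equilibrium mixture field of the example-2 start (product Gaussian)."""
    return equilibrium_continuum(f_of_v(example2_ic(params), params), params)
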