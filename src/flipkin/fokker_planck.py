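"""Analytic solution of the continuum (Fokker-Planck) limit.

In the Gaussian regime at low occupation the master equation becomes a
drift-diffusion equation for the density ``y(x, z, t)`` of carriers over
the continuous compartment loads ``x`` (external) and ``z`` (internal).
In the rotated coordinates ``u = x - z``, ``v = x + z`` the equation acts
only on ``u`` (``v``, the total cargo of a carrier, is conserved) and is an
Ornstein-Uhlenbeck process with propagator

    G(u, v, t | u') = Normal(u; mu(v, t | u'), sigma(t)),
    mu(v, t | u')   = u' e^{-t/tau} + v r (1 - e^{-t/tau}),
    sigma(t)        = sigma_inf (1 - e^{-2 t/tau}),

where ``r = (muE - muI)/(muE + muI)`` and
``sigma_inf = 4 muE muI / (muE + muI)``.

Normalization convention: the (u, v)-chart density ``y~(u, v, t)`` takes the
same values as ``y(x, z, t)`` and integrates to ``2N`` over du dv, so that
``(1/2) integral = N`` (Jacobian dx dz = du dv / 2).  The u-marginal
``f(v) = integral y~ du`` is time-invariant and normalizes as
``(1/2) integral f dv = N``.

Every initial condition used in practice is a finite Gaussian mixture in
(u, v) (a delta is a zero-covariance component), for which the propagator
integral is a closed-form Gaussian convolution: the kernel acts on a
component as the affine map

    mean  -> A mean,   cov -> A cov A^T + Q,
    A = [[e^{-t/tau}, r (1 - e^{-t/tau})], [0, 1]],   Q = diag(sigma(t), 0).

Arbitrary gridded initial data are handled by per-``v``-slice quadrature
against the same kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .conditions import InitialCondition
from .core import TwoCompartmentParams
from .errors import DegenerateDeltaError, ParameterError

__all__ = [
    "GreensKernel",
    "GaussianComponent",
    "GaussianMixtureField",
    "GriddedField",
    "MomentRecord",
    "sigma",
    "green",
    "propagate",
    "f_of_v",
    "equilibrium_continuum",
    "mean_u",
    "second_moment_u",
    "moments_of_field",
    "to_uv",
    "to_xz",
    "xz_to_uv",
    "uv_to_xz",
]


# -- coordinate charts ----------------------------------------------------

def xz_to_uv(x, z):
    """Map compartment loads to difference/sum coordinates (u, v)."""
    return np.asarray(x) - np.asarray(z), np.asarray(x) + np.asarray(z)


def uv_to_xz(u, v):
    """Inverse of :func:`xz_to_uv` (exact round trip)."""
    u, v = np.asarray(u), np.asarray(v)
    return (v + u) / 2, (v - u) / 2


_T_UV = np.array([[1.0, -1.0], [1.0, 1.0]])  # (x,z) -> (u,v)
_T_XZ = np.array([[0.5, 0.5], [-0.5, 0.5]])  # (u,v) -> (x,z)


# -- Green's function ------------------------------------------------------

def sigma(t, params: TwoCompartmentParams):
    """Variance of the propagator: ``sigma_inf (1 - e^{-2t/tau})``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("t must be >= 0")
    out = params.sigma_inf * (1.0 - np.exp(-2.0 * t / params.tau))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GreensKernel:
    """The analytic propagator of the u-direction Ornstein-Uhlenbeck process."""

    params: TwoCompartmentParams

    def sigma(self, t):
        return sigma(t, self.params)

    def mu(self, v, t, uprime):
        """Mean of the propagated delta peak started at ``u'`` on the slice ``v``."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ParameterError("t must be >= 0")
        decay = np.exp(-t / self.params.tau)
        return np.asarray(uprime) * decay + np.asarray(v) * self.params.drift_ratio * (1.0 - decay)

    def __call__(self, u, v, t, uprime):
        return green(u, v, t, uprime, self.params)


def green(u, v, t, uprime, params: TwoCompartmentParams):
    """Gaussian propagator density ``G(u, v, t | u')`` (normalized over u).

    Requires ``t > 0``; at ``t = 0`` the kernel is a Dirac delta and is
    handled symbolically by :func:`propagate`.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ParameterError("t must be >= 0")
    if np.any(t_arr == 0):
        raise DegenerateDeltaError("green(t=0) is a delta; use propagate() for exact t=0")
    s2 = sigma(t_arr, params)
    m = GreensKernel(params).mu(v, t_arr, uprime)
    out = np.exp(-((np.asarray(u) - m) ** 2) / (2.0 * s2)) / np.sqrt(2.0 * np.pi * s2)
    return float(out) if np.ndim(out) == 0 else out


# -- field representations -------------------------------------------------

@dataclass(frozen=True)
class GaussianComponent:
    """One mixture component: relative weight, mean (2,), covariance (2,2).

    Coordinates are those of the owning field's chart.  Zero rows/columns of
    the covariance encode delta factors (e.g. a delta in v for an ensemble
    whose carriers all hold the same total cargo).
    """

    weight: float
    mean: np.ndarray
    cov: np.ndarray


@dataclass(frozen=True)
class GaussianMixtureField:
    """Closed-form carrier density as a finite Gaussian mixture.

    In the ``uv`` chart the field integrates to ``2N`` over du dv; in the
    ``xz`` chart to ``N`` over dx dz (same function values, factor-1/2
    Jacobian convention).
    """

    components: list[GaussianComponent]
    params: TwoCompartmentParams
    t: float = 0.0
    chart: str = "uv"

    def __post_init__(self):
        if self.chart not in ("uv", "xz"):
            raise ParameterError(f"unknown chart {self.chart!r}")
        w = sum(c.weight for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ParameterError(f"component weights sum to {w}, expected 1")

    # mass carried by the density in its native chart
    @property
    def mass(self) -> float:
        return (2.0 if self.chart == "uv" else 1.0) * self.params.N

    def _uv_components(self) -> list[GaussianComponent]:
        if self.chart == "uv":
            return self.components
        return [
            GaussianComponent(c.weight, _T_UV @ c.mean, _T_UV @ c.cov @ _T_UV.T)
            for c in self.components
        ]

    def density_uv(self, u, v):
        """Density values at (u, v); integrates to 2N over du dv."""
        u, v = np.broadcast_arrays(np.asarray(u, float), np.asarray(v, float))
        out = np.zeros(u.shape)
        for c in self._uv_components():
            out += 2.0 * self.params.N * c.weight * _gauss2(u, v, c.mean, c.cov)
        return float(out) if out.ndim == 0 else out

    def density_xz(self, x, z):
        """Same function values addressed by compartment loads (x, z)."""
        u, v = xz_to_uv(x, z)
        return self.density_uv(u, v)

    def marginal_u(self, u):
        """u-marginal ``integral y~ dv`` (well defined even for delta-in-v)."""
        u = np.asarray(u, dtype=float)
        out = np.zeros(u.shape if u.ndim else ())
        for c in self._uv_components():
            var = c.cov[0, 0]
            if var <= 0:
                raise DegenerateDeltaError("u-marginal is a delta peak (t=0 delta condition)")
            out = out + 2.0 * self.params.N * c.weight * _gauss1(u, c.mean[0], var)
        return float(out) if np.ndim(out) == 0 else out

    def f_of_v(self):
        """The conserved v-marginal as a 1-D Gaussian/delta mixture."""
        comps = [
            (2.0 * self.params.N * c.weight, float(c.mean[1]), float(c.cov[1, 1]))
            for c in self._uv_components()
        ]
        return VMarginal(comps)

    def moments(self) -> "MomentRecord":
        return moments_of_field(self)


def _gauss1(x, m, var):
    return np.exp(-((x - m) ** 2) / (2 * var)) / math.sqrt(2 * math.pi * var)


def _gauss2(u, v, mean, cov):
    det = cov[0, 0] * cov[1, 1] - cov[0, 1] * cov[1, 0]
    if det <= 0:
        raise DegenerateDeltaError("singular covariance: density is a (partial) delta")
    du, dv = u - mean[0], v - mean[1]
    q = (cov[1, 1] * du * du - 2 * cov[0, 1] * du * dv + cov[0, 0] * dv * dv) / det
    return np.exp(-q / 2) / (2 * math.pi * math.sqrt(det))


def _component_uv(weight: float, etaE: float, etaI: float) -> GaussianComponent:
    """(u,v)-chart image of independent Poisson-variance loads (etaE, etaI)."""
    s, d = etaE + etaI, etaE - etaI
    return GaussianComponent(
        weight=weight,
        mean=np.array([d, s]),
        cov=np.array([[s, d], [d, s]]),
    )


class VMarginal:
    """Mixture representation of ``f(v)``; normalized as (1/2) integral = N."""

    def __init__(self, components: list[tuple[float, float, float]]):
        # (mass, mean, var); var == 0 encodes a delta
        self.components = components

    @property
    def mass(self) -> float:
        return sum(m for m, _, _ in self.components)

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        out = np.zeros(v.shape if v.ndim else ())
        for m, mu_, var in self.components:
            if var <= 0:
                raise DegenerateDeltaError("f(v) contains a delta component")
            out = out + m * _gauss1(v, mu_, var)
        return float(out) if np.ndim(out) == 0 else out

    def moment(self, k: int) -> float:
        """(1/(2N-mass)) weighted raw moment E[v^k] (k <= 4)."""
        tot = self.mass
        acc = 0.0
        for m, mu_, var in self.components:
            acc += m * _gauss_raw_moment(mu_, var, k)
        return acc / tot


def _gauss_raw_moment(m, var, k):
    if k == 0:
        return 1.0
    if k == 1:
        return m
    if k == 2:
        return var + m * m
    if k == 3:
        return m**3 + 3 * m * var
    if k == 4:
        return m**4 + 6 * m * m * var + 3 * var * var
    raise NotImplementedError("raw moments implemented up to order 4")


@dataclass(frozen=True)
class GriddedField:
    """Rectangular (u, v)-grid samples of the density ``y~(u, v, t)``."""

    u: np.ndarray
    v: np.ndarray
    Y: np.ndarray
    params: TwoCompartmentParams
    t: float = 0.0

    def __post_init__(self):
        if self.Y.shape != (len(self.u), len(self.v)):
            raise ParameterError("Y must have shape (len(u), len(v))")
        if np.any(np.asarray(self.Y) < -1e-9):
            raise ParameterError("densities must be non-negative")

    @classmethod
    def from_function(cls, fn_uv, u, v, params, t=0.0):
        U, V = np.meshgrid(u, v, indexing="ij")
        return cls(np.asarray(u, float), np.asarray(v, float), fn_uv(U, V), params, t)

    def carriers(self) -> float:
        """(1/2) double integral of the density (should equal N)."""
        return 0.5 * np.trapezoid(np.trapezoid(self.Y, self.v, axis=1), self.u)

    def f_of_v_values(self) -> np.ndarray:
        return np.trapezoid(self.Y, self.u, axis=0)

    def density_uv(self, u, v):
        from scipy.interpolate import RegularGridInterpolator

        itp = RegularGridInterpolator((self.u, self.v), self.Y, bounds_error=False, fill_value=0.0)
        pts = np.stack(np.broadcast_arrays(np.asarray(u, float), np.asarray(v, float)), axis=-1)
        return itp(pts)


# -- operations ------------------------------------------------------------

def propagate(ic, t: float, params: TwoCompartmentParams | None = None):
    """Advance an initial condition or field by time ``t`` under the kernel.

    ``t = 0`` returns the initial state unchanged (exact delta kernel).
    Gaussian-mixture inputs stay Gaussian mixtures (closed-form convolution);
    gridded inputs are convolved slice by slice in ``u`` by trapezoid
    quadrature.
    """
    if t < 0:
        raise ParameterError("t must be >= 0")
    if isinstance(ic, InitialCondition):
        if params is None:
            raise ParameterError("params required when propagating an InitialCondition")
        fld = ic.to_field(params)
    else:
        fld = ic
        params = fld.params

    if isinstance(fld, GaussianMixtureField):
        if fld.chart != "uv":
            fld = to_uv(fld)
        if t == 0:
            return fld
        s = math.exp(-t / params.tau)
        r = params.drift_ratio
        A = np.array([[s, r * (1.0 - s)], [0.0, 1.0]])
        Q = np.array([[sigma(t, params), 0.0], [0.0, 0.0]])
        comps = [
            GaussianComponent(c.weight, A @ c.mean, A @ c.cov @ A.T + Q)
            for c in fld.components
        ]
        return GaussianMixtureField(comps, params, t=fld.t + t)

    if isinstance(fld, GriddedField):
        if t == 0:
            return fld
        s = math.exp(-t / params.tau)
        r = params.drift_ratio
        s2 = sigma(t, params)
        wq = _trapezoid_weights(fld.u)
        out = np.empty_like(fld.Y)
        for j, vj in enumerate(fld.v):
            m = s * fld.u + r * (1.0 - s) * vj  # kernel means for each source u'
            K = np.exp(-((fld.u[:, None] - m[None, :]) ** 2) / (2 * s2)) / math.sqrt(
                2 * math.pi * s2
            )
            out[:, j] = K @ (wq * fld.Y[:, j])
        return GriddedField(fld.u, fld.v, out, params, t=fld.t + t)

    raise ParameterError(f"cannot propagate object of type {type(fld).__name__}")


def _trapezoid_weights(x):
    w = np.empty_like(x)
    w[1:-1] = (x[2:] - x[:-2]) / 2
    w[0] = (x[1] - x[0]) / 2
    w[-1] = (x[-1] - x[-2]) / 2
    return w


def f_of_v(ic, params: TwoCompartmentParams | None = None):
    """Conserved v-marginal of an initial condition or field."""
    if isinstance(ic, InitialCondition):
        return ic.to_field(params).f_of_v()
    if isinstance(ic, GaussianMixtureField):
        return ic.f_of_v()
    if isinstance(ic, GriddedField):
        return ic.f_of_v_values()
    raise ParameterError(f"cannot take f(v) of {type(ic).__name__}")


def equilibrium_continuum(f, params: TwoCompartmentParams, *, grid=None):
    """Stationary field with the prescribed v-marginal ``f``.

    ``y~_eq(u, v) = f(v) Normal(u; r v, sigma_inf)``: within every
    total-cargo class the loads settle into the same Gaussian regardless of
    how cargo was initially split, while the class populations ``f(v)``
    never change.  ``f`` may be a :class:`VMarginal` (exact mixture result)
    or a callable evaluated on ``grid=(u, v)``.
    """
    r = params.drift_ratio
    s_inf = params.sigma_inf
    if isinstance(f, VMarginal):
        comps = []
        for mass, mv, sv in f.components:
            w = mass / (2.0 * params.N)
            mean = np.array([r * mv, mv])
            cov = np.array([[s_inf + r * r * sv, r * sv], [r * sv, sv]])
            comps.append(GaussianComponent(w, mean, cov))
        return GaussianMixtureField(comps, params, t=math.inf)
    if callable(f):
        if grid is None:
            raise ParameterError("grid=(u, v) required for a callable f")
        u, v = (np.asarray(g, float) for g in grid)
        Y = f(v)[None, :] * _gauss1(u[:, None], r * v[None, :], s_inf)
        return GriddedField(u, v, Y, params, t=math.inf)
    raise ParameterError("f must be a VMarginal or a callable")


def mean_u(t, etaE: float, etaI: float, params: TwoCompartmentParams):
    """First u-moment: ``muE - muI + e^{-t/tau} (etaE - etaI - muE + muI)``.

    Equals ``ME(t)/N - MI(t)/N`` of the first-moment kinetics.
    """
    t = np.asarray(t, dtype=float)
    d_eq = params.muE - params.muI
    out = d_eq + np.exp(-t / params.tau) * ((etaE - etaI) - d_eq)
    return float(out) if out.ndim == 0 else out


def second_moment_u(t, m2u0: float, m11_0: float, m2v0: float, params: TwoCompartmentParams):
    """Second u-moment propagated from the initial moments.

    ``<u^2>(t) = sigma_inf (1 - E^2) + E^2 <u^2>_0
    + 2 r (E - E^2) <uv>_0 + r^2 (1 - E)^2 <v^2>_0`` with
    ``E = e^{-t/tau}``; the ``t -> inf`` limit
    ``sigma_inf + r^2 <v^2>_0`` retains the initial spread of total cargo.
    """
    t = np.asarray(t, dtype=float)
    E = np.exp(-t / params.tau)
    r = params.drift_ratio
    out = (
        params.sigma_inf * (1.0 - E * E)
        + E * E * m2u0
        + 2.0 * r * (E - E * E) * m11_0
        + r * r * (1.0 - E) ** 2 * m2v0
    )
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MomentRecord:
    """Time-stamped moment set of a carrier density (per-carrier averages)."""

    t: float
    ME: float
    MI: float
    mean_u: float
    mean_v: float
    m2_u: float
    m2_v: float
    m11: float
    var_u: float
    var_v: float

    @classmethod
    def from_uv_moments(cls, t, N, mean_u, mean_v, m2_u, m2_v, m11):
        return cls(
            t=t,
            ME=N * (mean_v + mean_u) / 2,
            MI=N * (mean_v - mean_u) / 2,
            mean_u=mean_u,
            mean_v=mean_v,
            m2_u=m2_u,
            m2_v=m2_v,
            m11=m11,
            var_u=m2_u - mean_u**2,
            var_v=m2_v - mean_v**2,
        )


def moments_of_field(field) -> MomentRecord:
    """All standard moments of a field (closed form or 2-D quadrature)."""
    if isinstance(field, GaussianMixtureField):
        mu1 = mv1 = m2u = m2v = m11 = 0.0
        for c in field._uv_components():
            w = c.weight
            mu1 += w * c.mean[0]
            mv1 += w * c.mean[1]
            m2u += w * (c.cov[0, 0] + c.mean[0] ** 2)
            m2v += w * (c.cov[1, 1] + c.mean[1] ** 2)
            m11 += w * (c.cov[0, 1] + c.mean[0] * c.mean[1])
        return MomentRecord.from_uv_moments(field.t, field.params.N, mu1, mv1, m2u, m2v, m11)
    if isinstance(field, GriddedField):
        U, V = np.meshgrid(field.u, field.v, indexing="ij")

        def integ(W):
            return 0.5 * np.trapezoid(np.trapezoid(W * field.Y, field.v, axis=1), field.u)

        N = integ(np.ones_like(U))
        return MomentRecord.from_uv_moments(
            field.t,
            field.params.N,
            integ(U) / N,
            integ(V) / N,
            integ(U * U) / N,
            integ(V * V) / N,
            integ(U * V) / N,
        )
    raise ParameterError(f"cannot compute moments of {type(field).__name__}")


def v_moment(field: GaussianMixtureField, k: int) -> float:
    """Raw v-moment of order k (conserved under propagation for all k)."""
    return sum(
        c.weight * _gauss_raw_moment(float(c.mean[1]), float(c.cov[1, 1]), k)
        for c in field._uv_components()
    )


def to_uv(field: GaussianMixtureField) -> GaussianMixtureField:
    """Re-express an (x, z)-chart mixture field in the (u, v) chart."""
    if field.chart == "uv":
        return field
    comps = [
        GaussianComponent(c.weight, _T_UV @ c.mean, _T_UV @ c.cov @ _T_UV.T)
        for c in field.components
    ]
    return GaussianMixtureField(comps, field.params, field.t, chart="uv")


def to_xz(field: GaussianMixtureField) -> GaussianMixtureField:
    """Re-express a (u, v)-chart mixture field in the (x, z) chart."""
    if field.chart == "xz":
        return field
    comps = [
        GaussianComponent(c.weight, _T_XZ @ c.mean, _T_XZ @ c.cov @ _T_XZ.T)
        for c in field.components
    ]
    return GaussianMixtureField(comps, field.params, field.t, chart="xz")
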