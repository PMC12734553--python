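"""Model parameters, first-moment kinetics, and the detailed-balance equilibrium.

The model describes an ensemble of ``N`` identical nanocarriers (e.g. lipid
vesicles).  Each carrier has an *external* compartment with ``mE`` binding
sites and an *internal* compartment with ``mI`` sites; every site holds at
most one cargo item (e.g. an amphipathic drug molecule embedded in the outer
or inner bilayer leaflet).  Cargo hops between the two compartments of its
own carrier with rate constants ``KEI`` (external -> internal) and ``KIE``
(internal -> external); there is no transfer between different carriers.

The ensemble-level first moments relax exponentially with characteristic
time ``tau = 1/(KEI + KIE)`` toward the equilibrium per-carrier loads

    muE = (M/N) * KIE / (KEI + KIE),    muI = (M/N) * KEI / (KEI + KIE),

and the full equilibrium state distribution is a product of binomials in the
two compartments with site-occupation probabilities ``(p, q)`` fixed by
detailed balance together with cargo conservation:

    mE*KEI*p*(1-q) = mI*KIE*(1-p)*q,        p*mE + q*mI = M/N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    BoundaryOccupancyError,
    InconsistentInitialConditionError,
    InfeasibleEquilibriumError,
    ParameterError,
)

__all__ = [
    "TwoCompartmentParams",
    "EquilibriumOccupancy",
    "derived_quantities",
    "first_moments_analytic",
    "solve_pq",
]

#: absolute tolerance for algebraic residuals (detailed balance, conservation)
DEFAULT_ABS_TOL = 1e-12


def _is_infinite(m) -> bool:
    return m is None or (isinstance(m, float) and math.isinf(m)) or m == "inf"


@dataclass(frozen=True)
class TwoCompartmentParams:
    """Static parameters of the two-compartment transfer model.

    Parameters
    ----------
    mE, mI : int or math.inf
        Number of binding sites in the external / internal compartment.
        ``math.inf`` selects the continuum (Gaussian-limit) regime where
        only the Fokker-Planck machinery applies.
    KEI, KIE : float
        Transfer rate constants (1/time), external->internal and
        internal->external.  Both must be positive.
    N : int
        Number of carriers in the ensemble.
    M : float
        Total number of cargo items across the whole ensemble.
    """

    mE: float
    mI: float
    KEI: float
    KIE: float
    N: int
    M: float

    def __post_init__(self):
        mE = math.inf if _is_infinite(self.mE) else self.mE
        mI = math.inf if _is_infinite(self.mI) else self.mI
        object.__setattr__(self, "mE", mE)
        object.__setattr__(self, "mI", mI)
        for name, m in (("mE", mE), ("mI", mI)):
            if not math.isinf(m):
                if m != int(m) or m < 1:
                    raise ParameterError(f"{name} must be a positive integer or inf, got {m!r}")
        if not (self.KEI > 0 and self.KIE > 0):
            raise ParameterError(f"rate constants must be positive: KEI={self.KEI}, KIE={self.KIE}")
        if not (self.N >= 1 and float(self.N) == int(self.N)):
            raise ParameterError(f"N must be a positive integer, got {self.N!r}")
        if self.M < 0:
            raise ParameterError(f"M must be non-negative, got {self.M}")
        if self.finite and self.M > self.N * (mE + mI):
            raise ParameterError(
                f"M={self.M} exceeds total site capacity N*(mE+mI)={self.N * (mE + mI)}"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def finite(self) -> bool:
        """True when both site counts are finite (discrete machinery usable)."""
        return not (math.isinf(self.mE) or math.isinf(self.mI))

    @property
    def tau(self) -> float:
        """Relaxation time of the first moments, 1/(KEI+KIE)."""
        return 1.0 / (self.KEI + self.KIE)

    @property
    def cargo_per_carrier(self) -> float:
        """Total cargo per carrier, M/N (conserved)."""
        return self.M / self.N

    @property
    def muE(self) -> float:
        """Equilibrium cargo per carrier in the external compartment."""
        return self.cargo_per_carrier * self.KIE / (self.KEI + self.KIE)

    @property
    def muI(self) -> float:
        """Equilibrium cargo per carrier in the internal compartment.

        Computed as ``M/N - muE`` so the conservation identity
        ``muE + muI == M/N`` holds exactly in floating point.
        """
        return self.cargo_per_carrier - self.muE

    @property
    def drift_ratio(self) -> float:
        """(muE - muI)/(muE + muI): slope of the equilibrium u-mean versus v."""
        return (self.KIE - self.KEI) / (self.KEI + self.KIE)

    @property
    def sigma_inf(self) -> float:
        """Equilibrium variance of u = x - z at fixed v: 4*muE*muI/(muE+muI)."""
        c = self.cargo_per_carrier
        if c == 0:
            return 0.0
        return 4.0 * self.muE * self.muI / c

    def with_(self, **kw) -> "TwoCompartmentParams":
        d = dict(mE=self.mE, mI=self.mI, KEI=self.KEI, KIE=self.KIE, N=self.N, M=self.M)
        d.update(kw)
        return TwoCompartmentParams(**d)


@dataclass(frozen=True)
class EquilibriumOccupancy:
    """Equilibrium site-occupation probabilities of the two compartments."""

    p: float  # probability that a given external site is occupied
    q: float  # probability that a given internal site is occupied

    def residuals(self, params: TwoCompartmentParams) -> tuple[float, float]:
        """(detailed-balance residual, cargo-conservation residual)."""
        db = params.mE * params.KEI * self.p * (1 - self.q) - params.mI * params.KIE * (
            1 - self.p
        ) * self.q
        cons = self.p * params.mE + self.q * params.mI - params.cargo_per_carrier
        return db, cons


def derived_quantities(params: TwoCompartmentParams) -> tuple[float, float, float]:
    """Return ``(tau, muE, muI)``.

    ``tau = 1/(KEI+KIE)`` is the relaxation time; ``muE`` and ``muI`` are the
    equilibrium numbers of cargo per carrier in the external and internal
    compartment.  ``muE + muI == M/N`` exactly.
    """
    return params.tau, params.muE, params.muI


def first_moments_analytic(
    t,
    etaE: float,
    etaI: float,
    params: TwoCompartmentParams,
    *,
    tol: float = 1e-9,
):
    """Exponential relaxation of the compartment loads (per carrier).

    ``ME(t)/N = muE + exp(-t/tau) (etaE - muE)`` and the mirror expression
    for ``MI``; their sum equals M/N at all times.  ``etaE``/``etaI`` are the
    initial per-carrier loads.  ``t`` may be a scalar or array (>= 0).

    Exact for infinite site counts or when ``KEI*mE == KIE*mI``; otherwise it
    is the leading large-m approximation of the master-equation moments.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("t must be >= 0")
    if etaE < 0 or etaI < 0:
        raise InconsistentInitialConditionError("etaE, etaI must be non-negative")
    c = params.cargo_per_carrier
    if abs((etaE + etaI) - c) > tol * max(1.0, c):
        raise InconsistentInitialConditionError(
            f"etaE+etaI={etaE + etaI} does not match M/N={c}"
        )
    decay = np.exp(-t / params.tau)
    ME_over_N = params.muE + decay * (etaE - params.muE)
    MI_over_N = params.muI + decay * (etaI - params.muI)
    if ME_over_N.ndim == 0:
        return float(ME_over_N), float(MI_over_N)
    return ME_over_N, MI_over_N


def solve_pq(params: TwoCompartmentParams, *, tol: float = DEFAULT_ABS_TOL) -> EquilibriumOccupancy:
    """Solve detailed balance + cargo conservation for the occupancies (p, q).

    Eliminating ``q = (M/N - p*mE)/mI`` from the conservation relation turns
    detailed balance into a quadratic in ``p``; the unique root in (0,1) is
    returned (its existence follows from the sign change of the quadratic
    between p=0 and p=1 whenever 0 < M < N*(mE+mI)).  A Newton polish brings
    both residuals to ~1e-15 absolute.

    For ``mE, mI`` large at fixed M/N, ``(p*mE, q*mI) -> (muE, muI)``.
    """
    if not params.finite:
        raise ParameterError("solve_pq requires finite site counts")
    mE, mI = float(params.mE), float(params.mI)
    KEI, KIE = params.KEI, params.KIE
    c = params.cargo_per_carrier
    if c <= 0 or c >= mE + mI:
        raise BoundaryOccupancyError(
            f"M/N={c} must lie strictly between 0 and mE+mI={mE + mI}"
        )

    # mE*KEI*p*(mI - c + p*mE) - KIE*(1-p)*(c - p*mE)*mI ... expanded in p:
    a = mE * (KEI * mE - KIE * mI)
    b = KEI * mE * (mI - c) + KIE * mI * (mE + c)
    d = -KIE * mI * c

    if a == 0.0:
        p = -d / b
    else:
        # numerically stable quadratic roots
        disc = b * b - 4.0 * a * d
        if disc < 0:
            raise InfeasibleEquilibriumError("negative discriminant in occupancy quadratic")
        sq = math.sqrt(disc)
        r1 = (-b - math.copysign(sq, b)) / (2.0 * a)
        r2 = d / (a * r1)
        roots = [r for r in (r1, r2) if 0.0 < r < 1.0 and 0.0 < (c - r * mE) / mI < 1.0]
        if not roots:
            raise InfeasibleEquilibriumError(f"no occupancy root in (0,1)^2 for params {params}")
        if len(roots) > 1 and abs(roots[0] - roots[1]) > 1e-9:
            raise InfeasibleEquilibriumError("degenerate parameters: two interior roots")
        p = roots[0]

    # Newton polish on F(p) = mE*KEI*p*(mI-c+p*mE) - KIE*(1-p)*(c-p*mE)*mI
    for _ in range(3):
        F = mE * KEI * p * (mI - c + p * mE) - KIE * (1 - p) * (c - p * mE) * mI
        dF = mE * KEI * (mI - c + 2 * p * mE) - KIE * mI * (-(c - p * mE) + (1 - p) * (-mE))
        if dF != 0:
            p -= F / dF
    q = (c - p * mE) / mI
    occ = EquilibriumOccupancy(p=p, q=q)
    db, cons = occ.residuals(params)
    scale = max(1.0, mE * KEI, mI * KIE)
    if abs(db) > tol * scale or abs(cons) > tol * max(1.0, c):
        raise InfeasibleEquilibriumError(
            f"occupancy solution failed residual check: db={db}, cons={cons}"
        )
    return occ
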