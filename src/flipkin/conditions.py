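"""Initial cargo distributions over the carrier ensemble.

Four variants cover every setup used by the worked examples:

* ``DeltaIC``      -- all carriers identical (a delta peak in the (u, v)
  plane, ``u = x - z``, ``v = x + z``);
* ``GaussianIC``   -- independent Gaussians in the two compartment loads
  with Poisson-like variances equal to their means (the low-occupation
  continuum analogue of a product of binomials);
* ``MixtureIC``    -- a finite mixture of such Gaussians;
* ``ProductBinomialIC`` -- the discrete product-binomial state
  ``y0[i,n] = N B(mE, p0; i) B(mI, q0; n)`` (master-equation context).

Each variant can express itself as a continuum Gaussian-mixture field in
the (u, v) chart (for the Fokker-Planck propagator), as a discrete
occupancy matrix (for the master equation), and as an i.i.d. per-carrier
sampler (for the Gillespie oracle).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import binom

from .core import TwoCompartmentParams
from .errors import InconsistentInitialConditionError, ParameterError

__all__ = ["InitialCondition", "DeltaIC", "GaussianIC", "MixtureIC", "ProductBinomialIC"]


class InitialCondition:
    """Base class; see module docstring for the variants."""

    def validate(self, params: TwoCompartmentParams, tol: float = 1e-9) -> None:
        c = sum(w * (e + i) for w, e, i in self.components(params))
        if abs(c - params.cargo_per_carrier) > tol * max(1.0, params.cargo_per_carrier):
            raise InconsistentInitialConditionError(
                f"initial cargo per carrier {c} does not match M/N={params.cargo_per_carrier}"
            )

    def components(self, params) -> list[tuple[float, float, float]]:
        """List of (weight, etaE, etaI) mixture components (weights sum to 1)."""
        raise NotImplementedError

    def mean_loads(self, params) -> tuple[float, float]:
        """Mean initial per-carrier loads (etaE, etaI)."""
        comps = self.components(params)
        return (
            sum(w * e for w, e, _ in comps),
            sum(w * i for w, _, i in comps),
        )

    def to_field(self, params):
        """Continuum Gaussian-mixture representation in the (u, v) chart."""
        from .fokker_planck import GaussianMixtureField, _component_uv

        self.validate(params)
        comps = [_component_uv(w, e, i) for w, e, i in self.components(params)]
        return GaussianMixtureField(components=comps, params=params, t=0.0)

    def to_discrete(self, params):
        """Occupancy matrix representation (finite grids only)."""
        raise NotImplementedError(f"{type(self).__name__} has no discrete representation")

    def sample(self, params, n_carriers: int, rng: np.random.Generator):
        """Draw i.i.d. per-carrier integer states (i, n)."""
        raise NotImplementedError


@dataclass(frozen=True)
class DeltaIC(InitialCondition):
    """Every carrier starts in the same state; coordinates given in (u, v)."""

    u0: float
    v0: float

    @classmethod
    def from_loads(cls, etaE: float, etaI: float) -> "DeltaIC":
        return cls(u0=etaE - etaI, v0=etaE + etaI)

    @property
    def etaE(self) -> float:
        return (self.v0 + self.u0) / 2

    @property
    def etaI(self) -> float:
        return (self.v0 - self.u0) / 2

    def components(self, params):
        return [(1.0, self.etaE, self.etaI)]

    def to_field(self, params):
        from .fokker_planck import GaussianComponent, GaussianMixtureField

        self.validate(params)
        comp = GaussianComponent(
            weight=1.0,
            mean=np.array([self.u0, self.v0]),
            cov=np.zeros((2, 2)),
        )
        return GaussianMixtureField(components=[comp], params=params, t=0.0)

    def to_discrete(self, params):
        from .master import OccupancyDistribution

        i0, n0 = self.etaE, self.etaI
        if abs(i0 - round(i0)) > 1e-9 or abs(n0 - round(n0)) > 1e-9:
            raise ParameterError("delta initial condition needs integer loads on a finite grid")
        y = np.zeros((int(params.mE) + 1, int(params.mI) + 1))
        y[int(round(i0)), int(round(n0))] = params.N
        return OccupancyDistribution(y, 0.0, params)

    def sample(self, params, n_carriers, rng):
        i = np.full(n_carriers, int(round(self.etaE)), dtype=np.int64)
        n = np.full(n_carriers, int(round(self.etaI)), dtype=np.int64)
        return i, n


@dataclass(frozen=True)
class GaussianIC(InitialCondition):
    """Independent Gaussian loads with variance = mean in each compartment."""

    etaE: float
    etaI: float

    def __post_init__(self):
        if self.etaE < 0 or self.etaI < 0:
            raise ParameterError("etaE, etaI must be non-negative")

    def components(self, params):
        return [(1.0, self.etaE, self.etaI)]

    def sample(self, params, n_carriers, rng):
        # rounded/clipped normals: an approximation documented for oracle use
        i = np.rint(rng.normal(self.etaE, np.sqrt(max(self.etaE, 0.0)), n_carriers))
        n = np.rint(rng.normal(self.etaI, np.sqrt(max(self.etaI, 0.0)), n_carriers))
        hi_i = params.mE if params.finite else np.inf
        hi_n = params.mI if params.finite else np.inf
        return (
            np.clip(i, 0, hi_i).astype(np.int64),
            np.clip(n, 0, hi_n).astype(np.int64),
        )


@dataclass(frozen=True)
class MixtureIC(InitialCondition):
    """Finite mixture of :class:`GaussianIC` components."""

    weights: tuple[float, ...]
    etaEs: tuple[float, ...]
    etaIs: tuple[float, ...]

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if len(w) != len(self.etaEs) or len(w) != len(self.etaIs):
            raise ParameterError("weights/etaEs/etaIs must have equal length")
        if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ParameterError("mixture weights must be positive and sum to 1")
        if any(e < 0 for e in self.etaEs) or any(i < 0 for i in self.etaIs):
            raise ParameterError("component loads must be non-negative")

    def components(self, params):
        return list(zip(self.weights, self.etaEs, self.etaIs))

    def sample(self, params, n_carriers, rng):
        choice = rng.choice(len(self.weights), size=n_carriers, p=self.weights)
        etaE = np.asarray(self.etaEs)[choice]
        etaI = np.asarray(self.etaIs)[choice]
        i = np.rint(rng.normal(etaE, np.sqrt(etaE)))
        n = np.rint(rng.normal(etaI, np.sqrt(etaI)))
        hi_i = params.mE if params.finite else np.inf
        hi_n = params.mI if params.finite else np.inf
        return (
            np.clip(i, 0, hi_i).astype(np.int64),
            np.clip(n, 0, hi_n).astype(np.int64),
        )


@dataclass(frozen=True)
class ProductBinomialIC(InitialCondition):
    """Discrete product-binomial ensemble with site probabilities (p0, q0)."""

    p0: float
    q0: float

    def __post_init__(self):
        if not (0 < self.p0 < 1 and 0 < self.q0 < 1):
            raise ParameterError("p0 and q0 must lie in (0, 1)")

    def validate(self, params, tol: float = 1e-9):
        if not params.finite:
            raise ParameterError("product-binomial initial condition needs finite site counts")
        c = self.p0 * params.mE + self.q0 * params.mI
        if abs(c - params.cargo_per_carrier) > tol * max(1.0, params.cargo_per_carrier):
            raise InconsistentInitialConditionError(
                f"p0*mE + q0*mI = {c} does not match M/N={params.cargo_per_carrier}"
            )

    def components(self, params):
        return [(1.0, self.p0 * params.mE, self.q0 * params.mI)]

    def to_field(self, params):
        """Gaussian (CLT) image with the exact binomial variances."""
        from .fokker_planck import GaussianComponent, GaussianMixtureField

        self.validate(params)
        mE, mI = params.mE, params.mI
        me_, mi_ = self.p0 * mE, self.q0 * mI
        ve = mE * self.p0 * (1 - self.p0)
        vi = mI * self.q0 * (1 - self.q0)
        comp = GaussianComponent(
            weight=1.0,
            mean=np.array([me_ - mi_, me_ + mi_]),
            cov=np.array([[ve + vi, ve - vi], [ve - vi, ve + vi]]),
        )
        return GaussianMixtureField(components=[comp], params=params, t=0.0)

    def to_discrete(self, params):
        from .master import OccupancyDistribution

        self.validate(params)
        mE, mI = int(params.mE), int(params.mI)
        bE = binom.pmf(np.arange(mE + 1), mE, self.p0)
        bI = binom.pmf(np.arange(mI + 1), mI, self.q0)
        return OccupancyDistribution(params.N * np.outer(bE, bI), 0.0, params)

    def sample(self, params, n_carriers, rng):
        self.validate(params)
        i = rng.binomial(int(params.mE), self.p0, n_carriers).astype(np.int64)
        n = rng.binomial(int(params.mI), self.q0, n_carriers).astype(np.int64)
        return i, n


def make_ic(tag: str, **kw) -> InitialCondition:
    """Construct an initial condition from a config tag + parameters."""
    tag = tag.replace("-", "_")
    table = {
        "delta": DeltaIC,
        "gaussian": GaussianIC,
        "mixture": MixtureIC,
        "product_binomial": ProductBinomialIC,
    }
    if tag not in table:
        raise ParameterError(f"unknown initial-condition tag {tag!r}")
    if tag == "mixture":
        kw = {k: tuple(v) if isinstance(v, Sequence) else v for k, v in kw.items()}
    return table[tag](**kw)
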