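"""Exact stochastic simulation (Gillespie direct method) of the jump process.

Carriers are statistically independent, so each carrier runs its own
two-reaction SSA with propensities

    a_EI = KEI * i * (1 - n/mI),      a_IE = KIE * n * (1 - i/mE),

from its own counter-derived random substream (splitmix64 keyed by the
master seed and the carrier index).  Results are therefore bit-identical
for identical (seed, number of carriers, parameters) regardless of
execution order, and the per-carrier total cargo i + n is conserved in
exact integer arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .conditions import InitialCondition
from .core import TwoCompartmentParams
from .errors import ParameterError
from .fokker_planck import MomentRecord

__all__ = ["CarrierEnsembleState", "sample_initial", "run", "empirical_moments", "histogram"]


@dataclass
class CarrierEnsembleState:
    """Per-carrier integer states (i, n) plus RNG bookkeeping."""

    i: np.ndarray
    n: np.ndarray
    t: float
    params: TwoCompartmentParams
    seed: int
    stream: np.ndarray  # per-carrier splitmix64 state (uint64)

    def __post_init__(self):
        if self.i.shape != self.n.shape or self.i.ndim != 1:
            raise ParameterError("i and n must be 1-D arrays of equal length")

    @property
    def n_carriers(self) -> int:
        return len(self.i)

    @property
    def total_cargo(self) -> np.ndarray:
        return self.i + self.n


_GOLDEN = np.uint64(0x9E3779B97F4A7C15)


@njit(cache=False)
def _splitmix_next(state):
    state = state + np.uint64(0x9E3779B97F4A7C15)
    z = state
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    return state, z


@njit(cache=False)
def _uniform(state):
    state, z = _splitmix_next(state)
    # 53-bit mantissa in (0, 1]; never 0 so log() is safe
    return state, (np.float64(z >> np.uint64(11)) + 1.0) * (2.0**-53)


@njit(cache=False)
def _ssa_kernel(i_arr, n_arr, stream, mE, mI, KEI, KIE, t0, t_end):
    for c in range(i_arr.shape[0]):
        t = t0
        i = i_arr[c]
        n = n_arr[c]
        s = stream[c]
        while True:
            a_ei = KEI * i * (1.0 - n / mI)
            a_ie = KIE * n * (1.0 - i / mE)
            a = a_ei + a_ie
            if a <= 0.0:
                break
            s, u1 = _uniform(s)
            t = t - np.log(u1) / a
            if t > t_end:
                break
            s, u2 = _uniform(s)
            if u2 * a < a_ei:
                i -= 1
                n += 1
            else:
                i += 1
                n -= 1
        i_arr[c] = i
        n_arr[c] = n
        stream[c] = s


def _init_streams(seed: int, n_carriers: int) -> np.ndarray:
    idx = np.arange(n_carriers, dtype=np.uint64)
    base = np.uint64(np.uint64(seed & 0xFFFFFFFFFFFFFFFF))
    # key each carrier stream by mixing seed and index once through splitmix
    state = base + idx * _GOLDEN
    z = state + _GOLDEN
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def sample_initial(
    ic: InitialCondition,
    params: TwoCompartmentParams,
    n_carriers: int,
    seed: int,
) -> CarrierEnsembleState:
    """Draw an i.i.d. carrier ensemble from the initial condition.

    Continuous (Gaussian/mixture) conditions are discretized by rounding to
    the nearest integer and clipping to [0, m] -- an approximation used only
    for oracle comparisons.
    """
    if not params.finite:
        raise ParameterError("the stochastic oracle needs finite site counts")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5A5A]))
    i, n = ic.sample(params, n_carriers, rng)
    if np.any(i < 0) or np.any(i > params.mE) or np.any(n < 0) or np.any(n > params.mI):
        raise ParameterError("sampled states leave the grid")
    return CarrierEnsembleState(
        i=i.astype(np.int64),
        n=n.astype(np.int64),
        t=0.0,
        params=params,
        seed=seed,
        stream=_init_streams(seed, n_carriers),
    )


def run(state: CarrierEnsembleState, t_end: float) -> CarrierEnsembleState:
    """Advance the ensemble to ``t_end`` by the exact direct-method SSA."""
    if t_end < state.t:
        raise ParameterError("t_end must be >= current time")
    i = state.i.copy()
    n = state.n.copy()
    stream = state.stream.copy()
    p = state.params
    _ssa_kernel(
        i, n, stream, float(p.mE), float(p.mI), p.KEI, p.KIE, float(state.t), float(t_end)
    )
    return CarrierEnsembleState(i, n, t_end, p, state.seed, stream)


def empirical_moments(state: CarrierEnsembleState):
    """Plug-in per-carrier moments with jackknife standard errors.

    Returns ``(MomentRecord, se)`` where ``se`` maps field names to
    delete-one jackknife standard errors over carriers.  Moments are
    per-carrier: ME and MI are scaled to the model ensemble size N.
    """
    i = state.i.astype(float)
    n = state.n.astype(float)
    nc = len(i)
    u = i - n
    v = i + n
    N = state.params.N

    def jack_se(stat_full, leave_one):
        # delete-one jackknife: se^2 = (nc-1)/nc * sum (theta_(j) - mean)^2
        m = leave_one.mean()
        return float(np.sqrt((nc - 1) / nc * ((leave_one - m) ** 2).sum()))

    se = {}
    rec_fields = {}
    for name, arr in (("mean_u", u), ("mean_v", v)):
        s = arr.sum()
        loo = (s - arr) / (nc - 1)
        rec_fields[name] = float(arr.mean())
        se[name] = jack_se(rec_fields[name], loo)
    for name, arr in (("m2_u", u * u), ("m2_v", v * v), ("m11", u * v)):
        s = arr.sum()
        loo = (s - arr) / (nc - 1)
        rec_fields[name] = float(arr.mean())
        se[name] = jack_se(rec_fields[name], loo)
    # variances: jackknife on the unbiased-variance functional
    for name, arr in (("var_u", u), ("var_v", v)):
        s1, s2 = arr.sum(), (arr * arr).sum()
        loo_mean = (s1 - arr) / (nc - 1)
        loo_m2 = (s2 - arr * arr) / (nc - 1)
        loo = loo_m2 - loo_mean**2
        full = float(arr.var())
        rec_fields[name] = full
        se[name] = jack_se(full, loo)

    rec = MomentRecord(
        t=state.t,
        ME=N * (rec_fields["mean_v"] + rec_fields["mean_u"]) / 2,
        MI=N * (rec_fields["mean_v"] - rec_fields["mean_u"]) / 2,
        **rec_fields,
    )
    se["ME"] = N * float(i.std(ddof=1)) / np.sqrt(nc)
    se["MI"] = N * float(n.std(ddof=1)) / np.sqrt(nc)
    return rec, se


def histogram(state: CarrierEnsembleState) -> np.ndarray:
    """Carrier counts over the (i, n) grid, shape (mE+1, mI+1)."""
    p = state.params
    mE, mI = int(p.mE), int(p.mI)
    flat = state.i * (mI + 1) + state.n
    return np.bincount(flat, minlength=(mE + 1) * (mI + 1)).reshape(mE + 1, mI + 1).astype(float)
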