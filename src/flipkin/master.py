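"""Discrete combinatorial master equation for the carrier-population matrix.

State of the ensemble: ``y[i, n]`` = number of carriers holding ``i`` cargo
items in the external compartment (0..mE) and ``n`` in the internal one
(0..mI).  Intra-carrier transfer moves single items between the two
compartments, so the dynamics are a linear jump process on the
``(mE+1) x (mI+1)`` grid:

    dy[i,n]/dt = KEI * ( gEI(i+1, n-1) y[i+1,n-1] - gEI(i, n) y[i,n] )
               + KIE * ( gIE(n+1, i-1) y[i-1,n+1] - gIE(n, i) y[i,n] )

with the combinatorial factors ``gEI(i,n) = i (1 - n/mI)`` (a transfer out
of the external compartment needs an occupied external site and a vacant
internal site) and ``gIE(n,i) = n (1 - i/mE)``.

Because transfer is intra-carrier only, every anti-diagonal subpopulation
``S_v = sum_i y[i, v-i]`` (carriers with total cargo ``v = i + n``) is
conserved, in addition to the carrier count N and the total cargo M.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp
from scipy.special import logsumexp
from scipy.stats import binom, norm

from .core import EquilibriumOccupancy, TwoCompartmentParams, solve_pq
from .errors import ConvergenceError, NumericalUnderflowError, ParameterError

__all__ = [
    "OccupancyDistribution",
    "TruncationWindow",
    "factor_EI",
    "factor_IE",
    "rhs",
    "build_generator",
    "integrate",
    "antidiagonal_sums",
    "moments_discrete",
    "equilibrium_discrete",
    "truncate",
]


@dataclass
class OccupancyDistribution:
    """Carrier-population matrix ``y[i, n]`` at one instant.

    Entries are real (the master equation evolves expected counts) and
    non-negative up to integrator slack; ``clipped()`` returns a copy with
    tiny negative entries zeroed for reporting.
    """

    y: np.ndarray
    t: float
    params: TwoCompartmentParams

    def __post_init__(self):
        if not self.params.finite:
            raise ParameterError("OccupancyDistribution requires finite site counts")
        shape = (int(self.params.mE) + 1, int(self.params.mI) + 1)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != shape:
            raise ParameterError(f"y has shape {self.y.shape}, expected {shape}")

    def clipped(self) -> np.ndarray:
        return np.clip(self.y, 0.0, None)

    @property
    def carriers(self) -> float:
        return float(self.y.sum())


@dataclass
class TruncationWindow:
    """Active sub-grid ``[iLo..iHi] x [nLo..nHi]`` plus a neglected-mass bound.

    The low-occupation regime concentrates all probability mass in a small
    corner of a potentially huge grid (e.g. mE=mI=2500); integrating on the
    window makes such runs cheap without changing the result beyond
    ``mass_bound``.
    """

    iLo: int
    iHi: int
    nLo: int
    nHi: int
    mass_bound: float = 0.0

    def slices(self) -> tuple[slice, slice]:
        return slice(self.iLo, self.iHi + 1), slice(self.nLo, self.nHi + 1)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.iHi - self.iLo + 1, self.nHi - self.nLo + 1)


def _check_index(i, lo, hi, name):
    arr = np.asarray(i)
    if np.any(arr < lo) or np.any(arr > hi):
        raise IndexError(f"{name} out of range [{lo}, {hi}]")


def factor_EI(i, n, params: TwoCompartmentParams):
    """Combinatorial multiplier for an external->internal transfer from (i, n).

    ``i * (1 - n/mI)``: the number of occupied external sites times the
    fraction of vacant internal sites.  Zero when the internal compartment
    is full (n == mI) or the external one empty (i == 0).
    """
    _check_index(i, 0, params.mE, "i")
    _check_index(n, 0, params.mI, "n")
    return np.asarray(i, dtype=float) * (1.0 - np.asarray(n, dtype=float) / params.mI)


def factor_IE(n, i, params: TwoCompartmentParams):
    """Mirror of :func:`factor_EI` for internal->external: ``n * (1 - i/mE)``."""
    _check_index(i, 0, params.mE, "i")
    _check_index(n, 0, params.mI, "n")
    return np.asarray(n, dtype=float) * (1.0 - np.asarray(i, dtype=float) / params.mE)


def rhs(dist: OccupancyDistribution) -> np.ndarray:
    """Right-hand side of the master equation, element-wise on the full grid.

    The four flux terms cancel in the total sum and along every
    anti-diagonal, so ``rhs`` conserves N and all ``S_v`` exactly (to float
    rounding).
    """
    p = dist.params
    mE, mI = int(p.mE), int(p.mI)
    y = dist.y
    i = np.arange(mE + 1)[:, None].astype(float)
    n = np.arange(mI + 1)[None, :].astype(float)
    gEI = i * (1.0 - n / mI)  # rate multiplier for (i,n) -> (i-1,n+1)
    gIE = n * (1.0 - i / mE)  # rate multiplier for (i,n) -> (i+1,n-1)

    out = -(p.KEI * gEI + p.KIE * gIE) * y
    # gain into (i,n) from (i+1,n-1) via E->I and from (i-1,n+1) via I->E
    out[: mE, 1:] += p.KEI * (gEI[1:, : mI] * y[1:, : mI])
    out[1:, : mI] += p.KIE * (gIE[: mE, 1:] * y[: mE, 1:])
    return out


def build_generator(
    params: TwoCompartmentParams, window: TruncationWindow | None = None
) -> sp.csr_matrix:
    """Sparse generator L with ``dy/dt = L y`` on the (windowed) grid.

    Jumps that would leave the window are dropped; the associated
    probability-mass leak is bounded by the window's ``mass_bound`` and is
    monitored by :func:`integrate`.
    """
    mE, mI = int(params.mE), int(params.mI)
    if window is None:
        window = TruncationWindow(0, mE, 0, mI)
    ni, nn = window.shape
    ii, nn_idx = np.meshgrid(
        np.arange(window.iLo, window.iHi + 1),
        np.arange(window.nLo, window.nHi + 1),
        indexing="ij",
    )
    flat = np.arange(ni * nn).reshape(ni, nn)
    gEI = params.KEI * ii * (1.0 - nn_idx / mI)
    gIE = params.KIE * nn_idx * (1.0 - ii / mE)

    rows, cols, vals = [], [], []
    # diagonal loss
    rows.append(flat.ravel())
    cols.append(flat.ravel())
    vals.append(-(gEI + gIE).ravel())
    # E->I jump: (i,n) -> (i-1, n+1); target must stay inside the window
    src = flat[1:, : nn - 1]
    dst = flat[: ni - 1, 1:]
    rows.append(dst.ravel())
    cols.append(src.ravel())
    vals.append(gEI[1:, : nn - 1].ravel())
    # I->E jump: (i,n) -> (i+1, n-1)
    src = flat[: ni - 1, 1:]
    dst = flat[1:, : nn - 1]
    rows.append(dst.ravel())
    cols.append(src.ravel())
    vals.append(gIE[: ni - 1, 1:].ravel())

    L = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ni * nn, ni * nn),
    )
    return L.tocsr()


def integrate(
    y0: OccupancyDistribution,
    times,
    rtol: float = 1e-8,
    atol: float | None = None,
    window: TruncationWindow | str | None = "auto",
    method: str = "DOP853",
) -> list[OccupancyDistribution]:
    """Integrate the master equation, returning one snapshot per requested time.

    ``times`` must be non-decreasing with ``times[0] >= 0``.  When
    ``window='auto'`` a truncation window is derived from the initial state
    and the equilibrium occupancies whenever the full grid is large;
    ``window=None`` forces the full grid.
    """
    params = y0.params
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0 or np.any(np.diff(times) < 0) or times[0] < 0:
        raise ParameterError("times must be a non-decreasing 1-D sequence with times[0] >= 0")
    if atol is None:
        atol = 1e-12 * params.N
    mE, mI = int(params.mE), int(params.mI)

    if window == "auto":
        window = None
        if (mE + 1) * (mI + 1) > 250_000:
            window = window_from_state(y0, epsilon=1e-12)
    if window is None:
        window = TruncationWindow(0, mE, 0, mI)

    sl = window.slices()
    outside = y0.y.sum() - y0.y[sl].sum()
    L = build_generator(params, window)
    v0 = y0.y[sl].ravel()

    out: list[OccupancyDistribution] = []
    t_solve = times
    prepend_initial = times[0] == 0.0
    if prepend_initial:
        out.append(OccupancyDistribution(y0.y.copy(), 0.0, params))
        t_solve = times[1:]
    if len(t_solve):
        sol = solve_ivp(
            lambda _t, v: L @ v,
            (0.0, float(t_solve[-1])),
            v0,
            method=method,
            t_eval=t_solve,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise ConvergenceError(f"master-equation integration failed: {sol.message}")
        for k in range(sol.y.shape[1]):
            full = np.zeros((mE + 1, mI + 1))
            full[sl] = sol.y[:, k].reshape(window.shape)
            out.append(OccupancyDistribution(full, float(sol.t[k]), params))

    leak = abs(out[-1].y.sum() + outside - y0.y.sum())
    if leak > max(100 * rtol * params.N, 10 * window.mass_bound * params.N + 1e-9 * params.N):
        raise ConvergenceError(
            f"carrier-count leak {leak:.3e} exceeds the truncation bound; widen the window"
        )
    return out


def antidiagonal_sums(dist: OccupancyDistribution) -> np.ndarray:
    """Conserved subpopulation sizes ``S_v = sum_i y[i, v-i]``, v = 0..mE+mI."""
    mE, mI = int(dist.params.mE), int(dist.params.mI)
    i = np.arange(mE + 1)[:, None]
    n = np.arange(mI + 1)[None, :]
    v = (i + n).ravel()
    return np.bincount(v, weights=dist.y.ravel(), minlength=mE + mI + 1)


def moments_discrete(dist: OccupancyDistribution) -> tuple[float, float]:
    """Total external and internal cargo ``(ME, MI)`` of the ensemble."""
    mE, mI = int(dist.params.mE), int(dist.params.mI)
    i = np.arange(mE + 1)[:, None]
    n = np.arange(mI + 1)[None, :]
    ME = float((i * dist.y).sum())
    MI = float((n * dist.y).sum())
    return ME, MI


def equilibrium_discrete(
    S: np.ndarray,
    occ: EquilibriumOccupancy,
    params: TwoCompartmentParams,
) -> OccupancyDistribution:
    """Stationary state with the prescribed anti-diagonal subpopulations.

    The equilibrium within each total-cargo class ``v`` is the product of
    two binomials, Binom(mE, p) x Binom(mI, q), conditioned on ``i+n = v``
    and scaled to the conserved subpopulation size ``S_v``:

        y_eq[i, n] = g(i+n) * B(mE, p; i) * B(mI, q; n),

    where ``g(v)`` normalizes each anti-diagonal to ``S_v``.  The dependence
    on the initial condition enters solely through ``S``.  All work is done
    in log space so that far-out anti-diagonals do not underflow.
    """
    mE, mI = int(params.mE), int(params.mI)
    S = np.asarray(S, dtype=float)
    if S.shape != (mE + mI + 1,):
        raise ParameterError(f"S must have length mE+mI+1={mE + mI + 1}")
    if abs(S.sum() - params.N) > 1e-9 * max(1.0, params.N):
        raise ParameterError(f"S sums to {S.sum()}, expected N={params.N}")

    logbE = binom.logpmf(np.arange(mE + 1), mE, occ.p)
    logbI = binom.logpmf(np.arange(mI + 1), mI, occ.q)
    logw = logbE[:, None] + logbI[None, :]

    i = np.arange(mE + 1)[:, None]
    n = np.arange(mI + 1)[None, :]
    v = (i + n).ravel()
    # log-normalizer per anti-diagonal
    order = np.argsort(v, kind="stable")
    logw_flat = logw.ravel()[order]
    v_sorted = v[order]
    bounds = np.searchsorted(v_sorted, np.arange(mE + mI + 2))
    log_g = np.full(mE + mI + 1, -np.inf)
    y = np.zeros((mE + 1) * (mI + 1))
    for vv in range(mE + mI + 1):
        seg = slice(bounds[vv], bounds[vv + 1])
        if S[vv] == 0.0:
            continue
        lse = logsumexp(logw_flat[seg])
        if not np.isfinite(lse):
            raise NumericalUnderflowError(
                f"anti-diagonal v={vv} carries S_v={S[vv]} but its binomial mass underflowed"
            )
        log_g[vv] = np.log(S[vv]) - lse
        y[order[seg]] = np.exp(logw_flat[seg] + log_g[vv])
    return OccupancyDistribution(y.reshape(mE + 1, mI + 1), np.inf, params)


# -- truncation windows ---------------------------------------------------


def _window_union(params, centers_sds, epsilon):
    """Rectangle covering every (mean, sd) pair to a Gaussian-tail bound < epsilon."""
    mE, mI = int(params.mE), int(params.mI)
    # two-sided Gaussian tail bound: need k with 4*(#bounds)*Phi(-k) < epsilon
    k = float(-norm.ppf(epsilon / (8 * max(1, len(centers_sds)))))
    k = max(k, 10.0)
    iLo, iHi, nLo, nHi = mE, 0, mI, 0
    for (ci, sdi, cn, sdn) in centers_sds:
        iLo = min(iLo, int(np.floor(ci - k * max(sdi, 1.0))))
        iHi = max(iHi, int(np.ceil(ci + k * max(sdi, 1.0))))
        nLo = min(nLo, int(np.floor(cn - k * max(sdn, 1.0))))
        nHi = max(nHi, int(np.ceil(cn + k * max(sdn, 1.0))))
    return TruncationWindow(
        max(0, iLo), min(mE, iHi), max(0, nLo), min(mI, nHi), mass_bound=epsilon
    )


def window_from_state(
    y0: OccupancyDistribution, epsilon: float = 1e-12
) -> TruncationWindow:
    """Truncation window from an explicit initial matrix plus the equilibrium."""
    params = y0.params
    mE, mI = int(params.mE), int(params.mI)
    N = y0.y.sum()
    mi = y0.y.sum(axis=1) / N
    mn = y0.y.sum(axis=0) / N
    i = np.arange(mE + 1)
    n = np.arange(mI + 1)
    ci, cn = float(mi @ i), float(mn @ n)
    sdi = float(np.sqrt(max(mi @ (i - ci) ** 2, 1e-12)))
    sdn = float(np.sqrt(max(mn @ (n - cn) ** 2, 1e-12)))
    occ = solve_pq(params)
    ce, se = mE * occ.p, np.sqrt(mE * occ.p * (1 - occ.p))
    cI, sI = mI * occ.q, np.sqrt(mI * occ.q * (1 - occ.q))
    win = _window_union(params, [(ci, sdi, cn, sdn), (ce, se, cI, sI)], epsilon)
    # make sure the explicit support of y0 (above threshold) is inside
    thresh = epsilon * N / y0.y.size
    rows = np.nonzero(y0.y.sum(axis=1) > thresh)[0]
    cols = np.nonzero(y0.y.sum(axis=0) > thresh)[0]
    if len(rows):
        win.iLo, win.iHi = min(win.iLo, rows[0]), max(win.iHi, rows[-1])
    if len(cols):
        win.nLo, win.nHi = min(win.nLo, cols[0]), max(win.nHi, cols[-1])
    outside = N - y0.y[win.slices()].sum()
    win.mass_bound = max(epsilon, float(outside / N))
    return win


def truncate(ic, params: TwoCompartmentParams, epsilon: float = 1e-12) -> TruncationWindow:
    """Truncation window for an :class:`~flipkin.conditions.InitialCondition`.

    Covers the initial and the equilibrium means to ``mean +/- k*sd`` with
    ``k`` chosen so the combined Gaussian tail bound stays below ``epsilon``.
    """
    occ = solve_pq(params)
    mE, mI = int(params.mE), int(params.mI)
    centers = [
        (
            mE * occ.p,
            np.sqrt(mE * occ.p * (1 - occ.p)),
            mI * occ.q,
            np.sqrt(mI * occ.q * (1 - occ.q)),
        ),
        # continuum-limit equilibrium with Poisson spread
        (params.muE, np.sqrt(max(params.muE, 1.0)), params.muI, np.sqrt(max(params.muI, 1.0))),
    ]
    for _w, e, i_ in ic.components(params):
        centers.append((e, np.sqrt(max(e, 1.0)), i_, np.sqrt(max(i_, 1.0))))
    return _window_union(params, centers, epsilon)
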