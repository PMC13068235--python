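"""Probability generating functions of K-state promoter models.

The PGF ``G(z, t) = Σ_n P(n, t) zⁿ`` packs the whole mRNA copy-number
distribution into one analytic function.  For the telegraph model the
steady-state PGF is the Kummer confluent hypergeometric function
``M(σ_on, σ_on + σ_off, ρ(z − 1))`` (all rates in units of the
degradation rate); for a general K-state promoter the time-dependent PGF
is obtained numerically by integrating the per-state generating
functions along the characteristics of the transformed master equation.

The module also provides the PGF algebra used to compose solutions —
binomial thinning, zero inflation, products of independent counts,
marginalization — and a stable FFT-based inversion back to a probability
mass function, which deliberately avoids high-order differentiation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numba
import numpy as np

from .models import GeneStateModel

__all__ = [
    "PGFunction",
    "kummer_m",
    "telegraph_pgf_steady",
    "model_pgf_time",
    "model_pgf_steady",
    "pgf_time_grid",
    "poisson_pgf",
    "thin_pgf",
    "zero_inflate_pgf",
    "product_pgf",
    "marginalize",
    "pgf_to_pmf",
    "pgf_moments",
]

_ODE_RTOL = 1e-10
_ODE_ATOL = 1e-10


# ---------------------------------------------------------------------------
# Kummer confluent hypergeometric function
# ---------------------------------------------------------------------------

def kummer_m(a: float, b: float, x) -> np.ndarray:
    """Kummer's M(a, b, x) = ₁F₁(a; b; x) for real or complex x.

    Direct power series in the right half-plane; for Re(x) < 0 the Kummer
    transformation ``M(a, b, x) = eˣ M(b − a, b, −x)`` avoids the
    catastrophic cancellation of the alternating series.  The arguments
    arising here satisfy |x| ≤ 2ρ, well within double-precision range.
    """
    x = np.asarray(x)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.empty(x.shape, dtype=complex)
    neg = np.real(x) < 0
    if np.any(~neg):
        out[~neg] = _kummer_series(a, b, x[~neg])
    if np.any(neg):
        out[neg] = np.exp(x[neg]) * _kummer_series(b - a, b, -x[neg])
    if not np.iscomplexobj(np.asarray(x)):
        out = np.real(out)
    return out[0] if scalar else out


def _kummer_series(a: float, b: float, x: np.ndarray, max_terms: int = 2000) -> np.ndarray:
    if b <= 0 and b == np.floor(b):
        raise ValueError("Kummer M undefined for non-positive integer b")
    term = np.ones(x.shape, dtype=complex)
    total = term.copy()
    for n in range(1, max_terms):
        term = term * ((a + n - 1) / (b + n - 1)) * x / n
        total += term
        if np.all(np.abs(term) <= 1e-17 * np.maximum(np.abs(total), 1e-300)):
            return total
    raise FloatingPointError(
        f"Kummer series did not converge within {max_terms} terms "
        f"(a={a}, b={b}, max|x|={np.max(np.abs(x)):.3g})"
    )


def telegraph_pgf_steady(theta, z):
    """Steady-state telegraph PGF M(σ_on, σ_on+σ_off, ρ(z−1)) with d = 1.

    ``theta`` is ``(rho, s_on, s_off)``; rates are already normalized by
    the degradation rate, which steady-state data cannot identify.
    """
    rho, s_on, s_off = (float(v) for v in theta)
    if rho <= 0 or s_on <= 0 or s_off < 0:
        raise ValueError("require rho > 0, s_on > 0, s_off >= 0")
    return kummer_m(s_on, s_on + s_off, rho * (np.asarray(z) - 1.0))


# ---------------------------------------------------------------------------
# Time-dependent PGF by the method of characteristics
# ---------------------------------------------------------------------------

# Dormand–Prince 5(4) tableau
_DP_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_DP_A = np.array(
    [
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [1 / 5, 0.0, 0.0, 0.0, 0.0, 0.0],
        [3 / 40, 9 / 40, 0.0, 0.0, 0.0, 0.0],
        [44 / 45, -56 / 15, 32 / 9, 0.0, 0.0, 0.0],
        [19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729, 0.0, 0.0],
        [9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656, 0.0],
    ]
)
_DP_B5 = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84, 0.0])
_DP_B4 = np.array(
    [5179 / 57600, 0.0, 7571 / 16695, 393 / 640, -92097 / 339200, 187 / 2100, 1 / 40]
)


@numba.njit(fastmath=False)
def _char_rhs(s, R, M, rho, zm1, d):
    dR = R @ M
    nz, K = R.shape
    for i in range(nz):
        c = zm1[i] * np.exp(-d * s)
        for k in range(K):
            dR[i, k] += c * R[i, k] * rho[k]
    return dR


@numba.njit(fastmath=False)
def _char_integrate(M, rho, d, zm1, times, rtol, atol, y, out, ks):
    """Adaptive Dormand–Prince integration of the characteristic system,
    recording the state at each (ascending) output time.

    ``y``, ``out`` and ``ks`` are caller-allocated work arrays whose
    dtype (float64 or complex128) fixes the arithmetic.
    """
    nz = zm1.shape[0]
    K = rho.shape[0]
    s = 0.0
    h = 0.05
    for it in range(times.shape[0]):
        t_target = times[it]
        while s < t_target - 1e-14:
            if h > t_target - s:
                h = t_target - s
            # seven stages
            ks[0] = _char_rhs(s, y, M, rho, zm1, d)
            for stage in range(1, 6):
                acc = y * 0.0
                for j in range(stage):
                    a = _DP_A[stage, j]
                    if a != 0.0:
                        acc += a * ks[j]
                ks[stage] = _char_rhs(s + _DP_C[stage] * h, y + h * acc, M, rho, zm1, d)
            y5 = y.copy()
            for j in range(6):
                b = _DP_B5[j]
                if b != 0.0:
                    y5 += h * b * ks[j]
            ks[6] = _char_rhs(s + h, y5, M, rho, zm1, d)
            # embedded 4th-order error estimate
            err_num = 0.0
            for i in range(nz):
                for k in range(K):
                    e = y[i, k] * 0.0
                    for j in range(7):
                        db = _DP_B5[j] - _DP_B4[j]
                        if db != 0.0:
                            e += db * ks[j, i, k]
                    scale = atol + rtol * max(abs(y[i, k]), abs(y5[i, k]))
                    r = abs(h * e) / scale
                    if r > err_num:
                        err_num = r
            if err_num <= 1.0:
                s += h
                y = y5
                factor = 5.0 if err_num == 0.0 else min(5.0, 0.9 * err_num ** -0.2)
                h *= max(0.2, factor)
            else:
                h *= max(0.2, 0.9 * err_num ** -0.2)
                if h < 1e-12:
                    raise ValueError("characteristics step size underflow")
        out[it] = y
    return out


def pgf_time_grid(model: GeneStateModel, z, times) -> np.ndarray:
    """Evaluate G(z, t) on the product of ``z`` nodes and ``times``.

    Along the characteristic through a target (z, t) the per-state
    generating functions obey a linear K-dimensional ODE.  In the
    time-to-target variable s the coefficient matrix
    ``A(s) = Qᵀ + (z−1) e^{−ds} diag(ρ)`` no longer depends on t, so the
    row-vector system ``dr/ds = r·A(s)``, ``r(0) = 𝟙ᵀ`` yields
    ``G(z, t) = r(t)·e_init`` for *every* requested time in a single
    integration, with all z nodes stacked into one state vector.

    Returns an array of shape ``(len(times), len(z))``.
    """
    z = np.atleast_1d(np.asarray(z))
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    order = np.argsort(times)
    t_sorted = np.ascontiguousarray(times[order])

    dtype = np.complex128 if np.iscomplexobj(z) else np.float64
    nz, K = z.size, model.K
    zm1 = np.ascontiguousarray((z - 1.0).astype(dtype))
    M = np.ascontiguousarray(model.Q.T.astype(dtype))
    try:
        r_sorted = _char_integrate(
            M, model.rho, float(model.d), zm1, t_sorted, _ODE_RTOL, _ODE_ATOL,
            np.ones((nz, K), dtype=dtype),
            np.empty((times.size, nz, K), dtype=dtype),
            np.empty((7, nz, K), dtype=dtype),
        )
    except ValueError as exc:
        raise RuntimeError(f"characteristics integration failed: {exc}") from exc
    r_at = r_sorted[np.argsort(order)]

    G = r_at[:, :, model.init_state]
    if model.init_mrna > 0:
        u0 = 1.0 + np.exp(-d * times)[:, None] * zm1[None, :]
        G = G * u0 ** model.init_mrna
    return G


def model_pgf_time(model: GeneStateModel, z, t: float):
    """G(z, t) for a single time; ``z`` may be scalar or an array."""
    z_arr = np.atleast_1d(np.asarray(z))
    out = pgf_time_grid(model, z_arr, [float(t)])[0]
    return out[0] if np.ndim(z) == 0 else out


def _telegraph_rates(model: GeneStateModel):
    """Return (rho, s_on, s_off) if the model is a telegraph instance."""
    if model.K != 2 or model.rho[0] != 0.0 or model.rho[1] <= 0.0:
        return None
    return model.rho[1], model.Q[0, 1], model.Q[1, 0]


def model_pgf_steady(model: GeneStateModel, z, _tol: float = 1e-8):
    """Steady-state PGF: closed form for the telegraph model, otherwise
    the long-time limit of the transient PGF (time doubled until two
    successive evaluations agree below ``_tol``)."""
    model.stationary_occupancy()  # raises for non-ergodic promoters
    tele = _telegraph_rates(model)
    if tele is not None:
        rho, s_on, s_off = tele
        d = model.d
        return telegraph_pgf_steady((rho / d, s_on / d, s_off / d), z)
    z_arr = np.atleast_1d(np.asarray(z))
    t = 8.0 / model.d
    prev = pgf_time_grid(model, z_arr, [t])[0]
    for _ in range(40):
        t *= 2.0
        cur = pgf_time_grid(model, z_arr, [t])[0]
        if np.max(np.abs(cur - prev)) < _tol:
            return cur[0] if np.ndim(z) == 0 else cur
        prev = cur
    raise RuntimeError("steady-state PGF did not converge under time doubling")


# ---------------------------------------------------------------------------
# PGF algebra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PGFunction:
    """A probability generating function as a vectorized evaluator.

    ``fn`` maps z (scalar or ndarray; for joint PGFs a tuple with one
    entry per species) to G(z).  Valid at least on the closed unit disc.
    """

    fn: Callable
    ndim: int = 1

    def __call__(self, z):
        if self.ndim == 1:
            return self.fn(z)
        if len(z) != self.ndim:
            raise ValueError(f"joint PGF expects {self.ndim} arguments")
        return self.fn(tuple(z))


def poisson_pgf(lam: float) -> PGFunction:
    """PGF of Poisson(λ): exp(λ(z−1)); the birth–death steady state."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return PGFunction(lambda z: np.exp(lam * (np.asarray(z) - 1.0)))


def thin_pgf(G: PGFunction, p: float) -> PGFunction:
    """Binomial thinning: each molecule kept with probability p,
    G(z) -> G(1 − p + p z).  Models sequencing capture inefficiency."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("capture probability p must lie in [0, 1]")
    return PGFunction(lambda z: G(1.0 - p + p * np.asarray(z)), ndim=G.ndim)


def zero_inflate_pgf(G: PGFunction, w: float) -> PGFunction:
    """Mixture with a point mass at zero: w + (1 − w) G(z)."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("zero-inflation weight w must lie in [0, 1]")
    return PGFunction(lambda z: w + (1.0 - w) * G(z), ndim=G.ndim)


def product_pgf(G1: PGFunction, G2: PGFunction) -> PGFunction:
    """PGF of the sum of two independent counts: G1(z)·G2(z)."""
    if G1.ndim != G2.ndim:
        raise ValueError("operands must share dimensionality")
    return PGFunction(lambda z: G1(z) * G2(z), ndim=G1.ndim)


def marginalize(G_joint: PGFunction, keep) -> PGFunction:
    """Marginal PGF over ``keep`` species; dropped arguments pinned to 1."""
    keep = tuple(keep)
    if not keep or any(k < 0 or k >= G_joint.ndim for k in keep):
        raise ValueError("keep indices out of range")

    def build_args(zs):
        args = [1.0] * G_joint.ndim
        for i, k in enumerate(keep):
            args[k] = np.asarray(zs[i])
        return tuple(args)

    if len(keep) == 1:
        return PGFunction(lambda z: G_joint.fn(build_args((z,))), ndim=1)
    return PGFunction(lambda zs: G_joint.fn(build_args(zs)), ndim=len(keep))


# ---------------------------------------------------------------------------
# Inversion and moments
# ---------------------------------------------------------------------------

def pgf_to_pmf(G, n_max: int) -> np.ndarray:
    """Recover P(0..n_max) from a PGF by sampling the unit circle.

    The power-series coefficients are extracted with a discrete Fourier
    inverse on ``n_fft >= 4 (n_max+1)`` equispaced points of the complex
    unit circle — numerically stable where repeated differentiation is
    not.  Tiny negative coefficients from roundoff are clipped to zero.
    A warning is emitted if the recovered mass falls short of 1 − 1e−6,
    i.e. if ``n_max`` truncates real probability.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    n_fft = 1
    while n_fft < 4 * (n_max + 1):
        n_fft *= 2
    zk = np.exp(2j * np.pi * np.arange(n_fft) / n_fft)
    vals = np.asarray(G(zk), dtype=complex)
    coeffs = np.real(np.fft.fft(vals)) / n_fft
    pmf = coeffs[: n_max + 1]
    if np.any(pmf < -1e-10):
        warnings.warn("PGF inversion produced coefficients below -1e-10", RuntimeWarning)
    pmf = np.clip(pmf, 0.0, None)
    if pmf.sum() < 1.0 - 1e-6:
        warnings.warn(
            f"pgf_to_pmf: only {pmf.sum():.8f} of probability mass captured by n_max={n_max}",
            RuntimeWarning,
        )
    return pmf


def pgf_moments(G, n_max: int = 64):
    """(mean, variance, third central moment) of the distribution G encodes.

    Computed from the inverted PMF, growing the truncation until the tail
    is negligible, rather than by symbolic differentiation.
    """
    while True:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            pmf = pgf_to_pmf(G, n_max)
        if pmf.sum() >= 1.0 - 1e-10 and pmf[-1] < 1e-13:
            break
        if n_max >= 2 ** 15:
            raise RuntimeError("distribution tail too heavy for moment extraction")
        n_max *= 2
    n = np.arange(pmf.size)
    mean = float(np.dot(n, pmf))
    var = float(np.dot((n - mean) ** 2, pmf))
    mu3 = float(np.dot((n - mean) ** 3, pmf))
    return mean, var, mu3
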