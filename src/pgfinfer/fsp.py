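"""Finite state projection of the chemical master equation, and the
maximum-likelihood baseline built on it.

The CME is truncated at mRNA copy number ``n_T``, giving a linear ODE
system ``dP/dt = A P`` on the K·(n_T+1) states (gene state block-major,
mRNA index fastest).  ``A``'s columns sum to zero except at the
transcription boundary, where probability leaks out of the projection;
the leaked mass bounds the truncation error.  The steady state is
obtained algebraically by replacing the first row of ``A`` with ones
and solving against the unit vector, which enforces normalization
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply, spsolve

from .data import CountDataset
from .families import get_family
from .inference import InferenceResults, _NelderMeadModel, _NM_OPTIONS
from .models import GeneStateModel, ParamVector

__all__ = [
    "FspSystem",
    "build_fsp",
    "fsp_steady",
    "fsp_time",
    "choose_truncation",
    "FspMaximumLikelihood",
    "mle_infer",
]

_MASS_TOL = 1e-8
_PROB_FLOOR = 1e-300


@dataclass(frozen=True)
class FspSystem:
    """Truncated CME generator for a K-state promoter model."""

    model: GeneStateModel
    n_T: int
    A: sp.csc_matrix

    @property
    def size(self) -> int:
        return self.model.K * (self.n_T + 1)

    def marginal_mrna(self, p: np.ndarray) -> np.ndarray:
        """Sum a full state-space vector over gene states."""
        return p.reshape(self.model.K, self.n_T + 1).sum(axis=0)

    def initial_vector(self) -> np.ndarray:
        p0 = np.zeros(self.size)
        if self.model.init_mrna > self.n_T:
            raise ValueError("init_mrna exceeds the truncation level")
        p0[self.model.init_state * (self.n_T + 1) + self.model.init_mrna] = 1.0
        return p0


def build_fsp(model: GeneStateModel, n_T: int) -> FspSystem:
    """Assemble the truncated generator.

    Within each gene-state block: degradation ``n·d`` on the upper
    off-diagonal, transcription ``ρ_s`` on the lower off-diagonal, and
    a balancing diagonal ``−(exit_s + ρ_s + n·d)`` (the ``−ρ_s`` at
    ``n = n_T`` is the probability leak).  Promoter switching couples
    blocks through identity-scaled rates.
    """
    if n_T < 1:
        raise ValueError("n_T must be >= 1")
    K = model.K
    nb = n_T + 1
    n = np.arange(nb, dtype=float)
    d = model.d
    exit_rate = -np.diag(model.Q)
    blocks = [[None] * K for _ in range(K)]
    for s in range(K):
        rho_s = model.rho[s]
        diag = -(exit_rate[s] + rho_s + n * d)
        upper = n[1:] * d  # degradation n -> n-1
        lower = np.full(n_T, rho_s)  # transcription n -> n+1
        blocks[s][s] = sp.diags([diag, upper, lower], [0, 1, -1], format="csc")
        for s2 in range(K):
            if s2 != s:
                # transitions s2 -> s feed block row s
                blocks[s][s2] = model.Q[s2, s] * sp.identity(nb, format="csc")
    A = sp.bmat(blocks, format="csc")
    return FspSystem(model, n_T, A)


def fsp_steady(system: FspSystem) -> np.ndarray:
    """Stationary distribution over the truncated state space via the
    first-row replacement trick; sums to one by construction."""
    system.model.stationary_occupancy()  # ergodicity check
    A = system.A.tolil(copy=True)
    A[0, :] = 1.0
    b = np.zeros(system.size)
    b[0] = 1.0
    p = spsolve(A.tocsc(), b)
    if np.any(~np.isfinite(p)):
        raise np.linalg.LinAlgError("singular stationary system")
    if np.any(p < -1e-9):
        raise np.linalg.LinAlgError(
            "stationary solve produced large negative probabilities; "
            "increase the truncation level"
        )
    return np.clip(p, 0.0, None)


def fsp_time(system: FspSystem, times) -> np.ndarray:
    """Transient solutions at each time (rows), by stepping the matrix
    exponential from the model's initial state.  Raises if the leaked
    probability mass ever exceeds 1e−8 (truncation too small)."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    order = np.argsort(times)
    p = system.initial_vector()
    out = np.empty((times.size, system.size))
    t_prev = 0.0
    for i in order:
        dt = times[i] - t_prev
        if dt > 0:
            p = expm_multiply(system.A * dt, p)
            t_prev = times[i]
        mass_loss = 1.0 - p.sum()
        if mass_loss > _MASS_TOL:
            raise RuntimeError(
                f"FSP mass loss {mass_loss:.2e} at t={times[i]:g} exceeds {_MASS_TOL:g}"
            )
        out[i] = np.clip(p, 0.0, None)
    return out


def choose_truncation(data: CountDataset = None, model: GeneStateModel = None) -> int:
    """Initial truncation level: at least the largest observed count and
    (for a telegraph-form model) the steady-state mean + 10 SD."""
    n_T = 1
    if data is not None:
        n_T = max(n_T, int(max(data.at(j).max() for j in range(data.n_times))))
    if model is not None:
        from .pgf import _telegraph_rates

        tele = _telegraph_rates(model)
        if tele is not None:
            from .moments import telegraph_moments_steady

            rho, s_on, s_off = tele
            mu1, mu2, _ = telegraph_moments_steady(
                (rho / model.d, s_on / model.d, s_off / model.d)
            )
            n_T = max(n_T, int(np.ceil(mu1 + 10.0 * np.sqrt(mu2))))
    return n_T


class FspMaximumLikelihood(_NelderMeadModel):
    """Maximum-likelihood inference with FSP-computed probabilities.

    The negative log-likelihood −Σ log P(n_i | θ) (marginalized over
    gene states) is minimized with Nelder–Mead over log-parameters.
    Probabilities are floored at 1e−300 before the log; the truncation
    level doubles automatically whenever the projection leaks more than
    1e−8 of mass or the steady tail is non-negligible.
    """

    method = "mle"

    def __init__(self, data: CountDataset, family="telegraph", mode: str = None, n_T: int = None):
        if data.n_species != 1:
            raise ValueError("FSP likelihood here is single-species")
        self.data = data
        self.family = get_family(family)
        self.mode = mode or ("steady" if data.is_steady else "time")
        if (self.mode == "steady") != data.is_steady:
            raise ValueError(f"{self.mode} mode does not match the dataset")
        # count histograms: likelihood is evaluated once per distinct count
        self.histograms = []
        for j in range(data.n_times):
            vals, mult = np.unique(data.at(j)[:, 0], return_counts=True)
            self.histograms.append((vals, mult))
        max_count = int(max(v.max() for v, _ in self.histograms))
        self.n_T = max(n_T or 0, max_count, 4)

    def _template(self) -> ParamVector:
        return self.family.template(self.mode)

    def loss(self, theta_values) -> float:
        return self._objective(np.asarray(theta_values, dtype=float))

    def nll(self, theta_values) -> float:
        """Negative log-likelihood J_MLE(θ)."""
        return self._objective(np.asarray(theta_values, dtype=float))

    def _objective(self, theta_values: np.ndarray) -> float:
        model = self.family.make_model(theta_values)
        for _ in range(12):
            system = build_fsp(model, self.n_T)
            try:
                pmfs = self._distributions(system)
            except RuntimeError:
                self.n_T *= 2
                continue
            tail = max(p[-1] for p in pmfs)
            if tail > 1e-10:
                self.n_T *= 2
                continue
            break
        else:
            raise RuntimeError("FSP truncation escalation did not terminate")
        total = 0.0
        for (vals, mult), pmf in zip(self.histograms, pmfs):
            total -= float(np.dot(mult, np.log(np.maximum(pmf[vals], _PROB_FLOOR))))
        return total

    def _distributions(self, system: FspSystem):
        if self.mode == "steady":
            return [system.marginal_mrna(fsp_steady(system))]
        sols = fsp_time(system, self.data.times)
        return [system.marginal_mrna(sols[j]) for j in range(self.data.n_times)]

    def _settings(self, start, maxiter) -> dict:
        return {
            "method": self.method,
            "family": getattr(self.family, "name", type(self.family).__name__),
            "mode": self.mode,
            "n_T": self.n_T,
            "init": "unit-log" if start is None else str(start),
            "maxiter": maxiter,
            **_NM_OPTIONS[self.mode],
        }


def mle_infer(data: CountDataset, **config) -> InferenceResults:
    """Functional wrapper over :class:`FspMaximumLikelihood`."""
    start = config.pop("start", None)
    maxiter = config.pop("maxiter", 2000)
    return FspMaximumLikelihood(data, **config).fit(start, maxiter)
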