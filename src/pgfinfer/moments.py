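"""Method-of-moments inference for the telegraph model.

Low-order empirical moments are matched to the model's moments through
a Gaussian synthetic likelihood: minimizing

    J_MOM(θ) = Σ_j Σ_k (μ_k(t_j) − μ̂_k(θ, t_j))² / σ²_k(t_j)

over log-parameters.  Steady-state mode uses the first three central
moments and the closed-form telegraph moments (d fixed at 1);
time-resolved mode uses the first two moments per snapshot, with the
model moments obtained from the linear moment ODE system and d free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .data import CountDataset
from .families import TelegraphFamily, get_family
from .inference import InferenceResults, _NelderMeadModel, _NM_OPTIONS
from .models import ParamVector

__all__ = [
    "MomentSummary",
    "empirical_moments",
    "moment_variances",
    "telegraph_moments_steady",
    "telegraph_moments_time",
    "MomentInference",
    "mom_infer",
]

_VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class MomentSummary:
    """Empirical moments of one snapshot: the mean μ1, central moments
    μ2, μ3 (and μ4, μ6, needed by the moment-variance formulas), the
    cell count, and the variance estimates of μ1..μ3."""

    mu1: float
    mu2: float
    mu3: float
    mu4: float
    mu6: float
    n_c: int
    var: tuple = None  # (σ²_1, σ²_2, σ²_3), filled by moment_variances


def empirical_moments(counts) -> MomentSummary:
    """Mean and central moments of a 1-D count vector (n_c >= 2)."""
    x = np.asarray(counts, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least two cells for moments")
    mu1 = float(np.mean(x))
    c = x - mu1
    summary = MomentSummary(
        mu1=mu1,
        mu2=float(np.mean(c ** 2)),
        mu3=float(np.mean(c ** 3)),
        mu4=float(np.mean(c ** 4)),
        mu6=float(np.mean(c ** 6)),
        n_c=x.size,
    )
    return moment_variances(summary)


def moment_variances(summary: MomentSummary) -> MomentSummary:
    """Sampling variances of the first three empirical moments:

        σ²_1 = μ2 / n_c
        σ²_2 = (μ4 − ((n_c−3)/(n_c−1)) μ2²) / n_c
        σ²_3 = (μ6 − μ3²) / n_c

    Non-positive estimates (possible on degenerate snapshots) are
    floored at 1e−12 so the synthetic likelihood stays finite.
    """
    n = summary.n_c
    raw = (
        summary.mu2 / n,
        (summary.mu4 - (n - 3) / (n - 1) * summary.mu2 ** 2) / n,
        (summary.mu6 - summary.mu3 ** 2) / n,
    )
    if any(v <= 0 for v in raw):
        warnings.warn("degenerate moment variance floored at 1e-12", RuntimeWarning)
    var = tuple(max(v, _VAR_FLOOR) for v in raw)
    return MomentSummary(
        summary.mu1, summary.mu2, summary.mu3, summary.mu4, summary.mu6, n, var
    )


def telegraph_moments_steady(theta, d: float = 1.0):
    """Closed-form steady-state telegraph moments (μ̂1 and the second and
    third *central* moments), derived from the Kummer PGF."""
    rho, s_on, s_off = (float(v) for v in theta)
    s = s_on + s_off
    mu1 = rho * s_on / (d * s)
    burst = rho ** 2 * s_off * s_on / (d * s ** 2 * (d + s))
    mu2 = mu1 + burst
    mu3 = (
        mu1
        + 3.0 * burst
        + 2.0 * rho ** 3 * s_off * s_on * (s_off - s_on) / (d * s ** 3 * (d + s) * (2 * d + s))
    )
    return mu1, mu2, mu3


_MOMENT_ODE_CACHE = {}


def telegraph_moments_time(theta, times):
    """First moment and central second moment of the telegraph model at
    each time, starting from an active gene with no mRNA.

    The raw moments (⟨n_m⟩, ⟨n_g⟩, ⟨n_m²⟩, ⟨n_m n_g⟩) obey a closed
    linear ODE system; it is solved exactly with the matrix exponential
    of the affine-augmented generator.
    """
    rho, s_on, s_off, d = (float(v) for v in theta)
    A = np.zeros((5, 5))
    # x = (<nm>, <ng>, <nm^2>, <nm ng>, 1)
    A[0, 0], A[0, 1] = -d, rho
    A[1, 1], A[1, 4] = -(s_on + s_off), s_on
    A[2, 0], A[2, 1], A[2, 2], A[2, 3] = d, rho, -2 * d, 2 * rho
    A[3, 0], A[3, 1], A[3, 3] = s_on, rho, -(d + s_off + s_on)
    x0 = np.array([0.0, 1.0, 0.0, 0.0, 1.0])
    out = []
    for t in np.atleast_1d(times):
        x = expm(A * float(t)) @ x0
        mu1 = x[0]
        mu2 = x[2] - x[0] ** 2
        out.append((float(mu1), float(mu2)))
    return out


class MomentInference(_NelderMeadModel):
    """Moment-matching inference model (telegraph family only).

    Steady mode fits (ρ, σ_on, σ_off) with d = 1 against the first
    three moments; time mode fits all four rates against the first two
    moments per snapshot.
    """

    method = "mom"

    def __init__(self, data: CountDataset, family="telegraph", mode: str = None):
        family = get_family(family)
        if not isinstance(family, TelegraphFamily):
            raise ValueError("moment-based inference is telegraph-specific")
        if data.n_species != 1:
            raise ValueError("moment-based inference is single-species")
        self.data = data
        self.family = family
        self.mode = mode or ("steady" if data.is_steady else "time")
        if (self.mode == "steady") != data.is_steady:
            raise ValueError(f"{self.mode} mode does not match the dataset")
        self.summaries = [
            empirical_moments(data.at(j)[:, 0]) for j in range(data.n_times)
        ]
        self.n_k = 3 if self.mode == "steady" else 2

    def _template(self) -> ParamVector:
        return self.family.template(self.mode)

    def loss(self, theta_values) -> float:
        return self._objective(np.asarray(theta_values, dtype=float))

    def _objective(self, theta_values: np.ndarray) -> float:
        rho, s_on, s_off, d = theta_values
        total = 0.0
        if self.mode == "steady":
            s = self.summaries[0]
            model_mu = telegraph_moments_steady((rho, s_on, s_off), d=d)
            emp = (s.mu1, s.mu2, s.mu3)
            for k in range(3):
                total += (emp[k] - model_mu[k]) ** 2 / s.var[k]
        else:
            model_mu = telegraph_moments_time(theta_values, self.data.times)
            for s, (m1, m2) in zip(self.summaries, model_mu):
                emp = (s.mu1, s.mu2)
                for k in range(2):
                    total += (emp[k] - (m1, m2)[k]) ** 2 / s.var[k]
        return float(total)

    def set_moments(self, summaries) -> None:
        """Replace the empirical moment summaries (used for
        self-consistency checks with exact model moments)."""
        self.summaries = list(summaries)

    def _settings(self, start, maxiter) -> dict:
        return {
            "method": self.method,
            "family": self.family.name,
            "mode": self.mode,
            "n_k": self.n_k,
            "init": "unit-log" if start is None else str(start),
            "maxiter": maxiter,
            **_NM_OPTIONS[self.mode],
        }


def mom_infer(data: CountDataset, **config) -> InferenceResults:
    """Functional wrapper over :class:`MomentInference`."""
    start = config.pop("start", None)
    maxiter = config.pop("maxiter", 2000)
    return MomentInference(data, **config).fit(start, maxiter)
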