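"""K-state promoter models of stochastic gene expression.

A gene promoter switches between ``K`` discrete states according to a
continuous-time Markov chain with generator ``Q``; in state ``s`` mRNA is
transcribed at rate ``rho[s]`` and every mRNA molecule degrades
independently at rate ``d``.  The canonical members of the family are the
two-state telegraph model (one inactive, one active state) and the
three-state refractory model (two sequential inactive states visited
cyclically before the active one).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneStateModel",
    "ParamVector",
    "make_telegraph",
    "make_refractory",
    "to_log",
    "from_log",
]


@dataclass(frozen=True)
class GeneStateModel:
    """A K-state promoter with transcription and first-order degradation.

    Parameters
    ----------
    Q : (K, K) ndarray
        Promoter-switching generator. ``Q[s, s']`` is the rate of the
        ``s -> s'`` transition for ``s != s'``; diagonal entries balance
        each row to zero.
    rho : (K,) ndarray
        Transcription rate in each promoter state (molecules / time).
    d : float
        mRNA degradation rate (1 / time).
    init_state : int
        Promoter state occupied at ``t = 0`` (0-based).
    init_mrna : int
        mRNA copy number at ``t = 0``.
    labels : tuple of str, optional
        Human-readable state names, serialized with the model so the
        orientation of ``Q`` is never ambiguous.
    """

    Q: np.ndarray
    rho: np.ndarray
    d: float
    init_state: int = 0
    init_mrna: int = 0
    labels: tuple = field(default=None)

    def __post_init__(self):
        Q = np.asarray(self.Q, dtype=float)
        rho = np.asarray(self.rho, dtype=float)
        if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
            raise ValueError("Q must be a square matrix")
        K = Q.shape[0]
        if rho.shape != (K,):
            raise ValueError(f"rho must have length {K}")
        off = Q - np.diag(np.diag(Q))
        if np.any(off < 0):
            raise ValueError("off-diagonal entries of Q must be >= 0")
        if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-10):
            raise ValueError("rows of Q must sum to zero")
        if np.any(rho < 0):
            raise ValueError("transcription rates must be >= 0")
        if not (self.d > 0 and np.isfinite(self.d)):
            raise ValueError("degradation rate d must be positive and finite")
        if not 0 <= self.init_state < K:
            raise ValueError("init_state out of range")
        if self.init_mrna < 0:
            raise ValueError("init_mrna must be >= 0")
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "rho", rho)
        if self.labels is not None and len(self.labels) != K:
            raise ValueError("labels must name every state")

    @property
    def K(self) -> int:
        return self.Q.shape[0]

    def stationary_occupancy(self) -> np.ndarray:
        """Stationary distribution of the promoter chain (null space of Qᵀ)."""
        K = self.K
        A = np.vstack([self.Q.T, np.ones(K)])
        b = np.zeros(K + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.any(pi < -1e-9):
            raise ValueError("promoter chain is not ergodic")
        return np.clip(pi, 0.0, None) / pi.sum()

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "Q": self.Q.tolist(),
            "rho": self.rho.tolist(),
            "d": self.d,
            "init_state": self.init_state,
            "init_mrna": self.init_mrna,
            "labels": list(self.labels) if self.labels else None,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, obj: dict) -> "GeneStateModel":
        return cls(
            Q=np.asarray(obj["Q"], dtype=float),
            rho=np.asarray(obj["rho"], dtype=float),
            d=float(obj["d"]),
            init_state=int(obj.get("init_state", 0)),
            init_mrna=int(obj.get("init_mrna", 0)),
            labels=tuple(obj["labels"]) if obj.get("labels") else None,
        )

    @classmethod
    def from_json(cls, s: str) -> "GeneStateModel":
        return cls.from_dict(json.loads(s))


def make_telegraph(rho: float, s_on: float, s_off: float, d: float = 1.0) -> GeneStateModel:
    """Two-state telegraph model: inactive <-> active, transcription only
    while active.

    State 0 is inactive, state 1 active; ``s_on`` drives 0 -> 1 and
    ``s_off`` drives 1 -> 0.  The initial condition is the active state
    with no mRNA, the convention used by the time-resolved protocols.
    """
    if not (rho > 0 and np.isfinite(rho)):
        raise ValueError("rho must be positive and finite")
    if not (s_on > 0 and np.isfinite(s_on)):
        raise ValueError("s_on must be positive and finite")
    if s_off < 0 or not np.isfinite(s_off):
        raise ValueError("s_off must be >= 0 and finite")
    Q = np.array([[-s_on, s_on], [s_off, -s_off]], dtype=float)
    return GeneStateModel(
        Q=Q,
        rho=np.array([0.0, rho]),
        d=d,
        init_state=1,
        init_mrna=0,
        labels=("inactive", "active"),
    )


def make_refractory(k12: float, k23: float, k31: float, rho: float, d: float = 1.0) -> GeneStateModel:
    """Three-state refractory model: G1 -> G2 -> G3 -> G1 cyclically,
    transcription only in G3.

    Two sequential inactive states make the off-time distribution
    non-exponential (hypoexponential), which is what distinguishes the
    model from the telegraph model in time-resolved data.  The initial
    condition is G1 with no mRNA.
    """
    for name, v in (("k12", k12), ("k23", k23), ("k31", k31), ("rho", rho), ("d", d)):
        if not (v > 0 and np.isfinite(v)):
            raise ValueError(f"{name} must be positive and finite")
    Q = np.array(
        [
            [-k12, k12, 0.0],
            [0.0, -k23, k23],
            [k31, 0.0, -k31],
        ]
    )
    return GeneStateModel(
        Q=Q,
        rho=np.array([0.0, 0.0, rho]),
        d=d,
        init_state=0,
        init_mrna=0,
        labels=("G1", "G2", "G3"),
    )


@dataclass
class ParamVector:
    """Named positive kinetic parameters with an inference mask.

    ``free_mask`` marks which entries enter the optimization vector;
    for steady-state inference ``d`` is fixed at 1 (only ratios to the
    degradation rate are identifiable) so it is excluded.
    """

    names: tuple
    values: np.ndarray
    free_mask: np.ndarray = None

    def __post_init__(self):
        self.names = tuple(self.names)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("one value per name required")
        if np.any(self.values <= 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("parameter values must be positive and finite")
        if self.free_mask is None:
            self.free_mask = np.ones(len(self.names), dtype=bool)
        else:
            self.free_mask = np.asarray(self.free_mask, dtype=bool)
            if self.free_mask.shape != self.values.shape:
                raise ValueError("free_mask shape mismatch")

    @property
    def free_names(self) -> tuple:
        return tuple(n for n, f in zip(self.names, self.free_mask) if f)

    @property
    def free_values(self) -> np.ndarray:
        return self.values[self.free_mask]

    def replace_free(self, free_values: np.ndarray) -> "ParamVector":
        values = self.values.copy()
        values[self.free_mask] = free_values
        return ParamVector(self.names, values, self.free_mask.copy())

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values.tolist()))


def to_log(params: ParamVector) -> np.ndarray:
    """Natural log of the free parameters — the optimizer's coordinates."""
    v = params.free_values
    if np.any(v <= 0):
        raise ValueError("cannot log-transform non-positive parameters")
    return np.log(v)


def from_log(v: np.ndarray, template: ParamVector) -> ParamVector:
    """Exponentiate an optimization vector back into the template's frame."""
    v = np.asarray(v, dtype=float)
    if v.shape != (int(template.free_mask.sum()),):
        raise ValueError("log-vector length does not match free parameters")
    return template.replace_free(np.exp(v))
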