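"""Empirical PGF and the generating-function mismatch objectives.

Inference minimizes the mean squared mismatch between the empirical PGF
of the count data,

    G(z) = (1/n_c) Σ_i Π_j z_j^{n_ij},

and the model PGF 𝒢_θ(z), integrated over the box Γ = [z_min, z_max]^N.
The integral is evaluated with a tensor Gauss–Legendre rule, so the
steady-state objective is

    J(θ) = a_z^N Σ_i ω_i ‖G(z_i) − 𝒢_θ(z_i)‖²,

and the time-resolved objective adds a sum over snapshot times.
Empirical PGF values on the grid do not depend on θ and are cached on
the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CountDataset

__all__ = ["QuadratureGrid", "gauss_grid", "empirical_pgf", "loss_steady", "loss_time"]


@dataclass(frozen=True)
class QuadratureGrid:
    """Tensor Gauss–Legendre rule on [z_min, z_max]^N.

    ``nodes`` has shape (n_nodes, N); ``weights`` are the tensorized
    products of the one-dimensional weights.  The affine map
    ``z = a_z y + b_z`` carries the reference nodes y ∈ [−1, 1] onto the
    integration box; the Jacobian factor ``a_z^N`` is applied by
    :meth:`integrate`, so a polynomial of degree ≤ 2·order − 1 per
    dimension is integrated exactly.
    """

    order: int
    z_min: float
    z_max: float
    ndim: int
    nodes_1d: np.ndarray
    weights_1d: np.ndarray
    nodes: np.ndarray
    weights: np.ndarray

    @property
    def a_z(self) -> float:
        return (self.z_max - self.z_min) / 2.0

    @property
    def b_z(self) -> float:
        return (self.z_max + self.z_min) / 2.0

    def integrate(self, values: np.ndarray):
        """∫_Γ f dz ≈ a_z^N Σ_i ω_i f(z_i) for f sampled on the nodes."""
        return self.a_z ** self.ndim * np.sum(self.weights * np.asarray(values), axis=-1)

    def key(self) -> tuple:
        return (self.order, self.z_min, self.z_max, self.ndim)


def gauss_grid(order: int, z_min: float = 0.0, z_max: float = 1.0, ndim: int = 1) -> QuadratureGrid:
    """Build the tensor Gauss–Legendre grid.

    The tensor product is capped at three dimensions: its cost grows as
    ``order**ndim`` and the experiments here are one-species.
    """
    if order < 1:
        raise ValueError("quadrature order must be >= 1")
    if not z_min < z_max:
        raise ValueError("require z_min < z_max")
    if not 1 <= ndim <= 3:
        raise ValueError("tensor grids are limited to 1..3 dimensions")
    y, w = np.polynomial.legendre.leggauss(order)
    a = (z_max - z_min) / 2.0
    b = (z_max + z_min) / 2.0
    z1d = a * y + b
    mesh = np.meshgrid(*([z1d] * ndim), indexing="ij")
    nodes = np.stack([m.ravel() for m in mesh], axis=1)
    wmesh = np.meshgrid(*([w] * ndim), indexing="ij")
    weights = np.ones(nodes.shape[0])
    for wm in wmesh:
        weights = weights * wm.ravel()
    return QuadratureGrid(order, float(z_min), float(z_max), ndim, z1d, w, nodes, weights)


def empirical_pgf(counts, z_points) -> np.ndarray:
    """Empirical PGF of one snapshot at the given z points.

    ``counts`` is an (n_c, N) matrix (or a steady-state
    :class:`CountDataset`); ``z_points`` has shape (n_pts, N) or
    (n_pts,) for one species.  Evaluation goes through the count
    histogram, so duplicated count vectors cost nothing extra.
    """
    if isinstance(counts, CountDataset):
        counts = counts.steady_matrix
    counts = np.asarray(counts)
    if counts.ndim == 1:
        counts = counts[:, None]
    if counts.size == 0:
        raise ValueError("empty dataset")
    z = np.asarray(z_points)
    if z.ndim == 1:
        z = z[:, None]
    if z.shape[1] != counts.shape[1]:
        raise ValueError("z dimensionality does not match the species count")
    uniq, mult = np.unique(counts, axis=0, return_counts=True)
    n_c = counts.shape[0]
    # (n_pts, n_uniq): Π_j z_j^{v_j} per unique count vector v
    powers = np.ones((z.shape[0], uniq.shape[0]), dtype=z.dtype if np.iscomplexobj(z) else float)
    for j in range(z.shape[1]):
        powers = powers * z[:, j][:, None] ** uniq[:, j][None, :]
    return powers @ (mult / n_c)


def _cached_epgf(data: CountDataset, grid: QuadratureGrid, j: int) -> np.ndarray:
    cache = getattr(data, "_epgf_cache", None)
    if cache is None:
        cache = {}
        data._epgf_cache = cache
    key = grid.key() + (j,)
    if key not in cache:
        cache[key] = empirical_pgf(data.at(j), grid.nodes)
    return cache[key]


def _model_nodes(grid: QuadratureGrid, capture_p) -> np.ndarray:
    """Grid nodes at which the model PGF is evaluated; under a capture
    probability p the model PGF is binomially thinned, i.e. read at
    1 − p + p·z."""
    z = grid.nodes[:, 0] if grid.ndim == 1 else grid.nodes
    if capture_p is None:
        return z
    if not 0.0 <= capture_p <= 1.0:
        raise ValueError("capture_p must lie in [0, 1]")
    return 1.0 - capture_p + capture_p * z


def loss_steady(theta, family, data: CountDataset, grid: QuadratureGrid, capture_p=None) -> float:
    """Steady-state PGF-mismatch objective J(θ)."""
    emp = _cached_epgf(data, grid, 0)
    model_vals = family.steady_pgf(theta, _model_nodes(grid, capture_p))
    return float(grid.integrate(np.abs(emp - model_vals) ** 2))


def loss_time(theta, family, data: CountDataset, grid: QuadratureGrid, capture_p=None) -> float:
    """Time-resolved objective: the steady-state mismatch summed over
    all snapshot times, sharing one quadrature grid."""
    if data.is_steady:
        raise ValueError("time-resolved loss needs a time-resolved dataset")
    z = _model_nodes(grid, capture_p)
    model_vals = family.time_pgf(theta, z, data.times)  # (n_t, n_nodes)
    total = 0.0
    for j in range(data.n_times):
        emp = _cached_epgf(data, grid, j)
        total += float(grid.integrate(np.abs(emp - model_vals[j]) ** 2))
    return total
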