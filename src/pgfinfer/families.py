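"""Inference-ready model families.

A family binds a parameter vector layout to the PGF evaluators the
objectives need: ``steady_pgf(theta, z)`` and
``time_pgf(theta, z, times)``, with ``theta`` ordered as
``param_names``.  The last parameter is always the degradation rate
``d``, fixed at 1 in steady-state mode (only rate ratios are
identifiable there) and free in time-resolved mode.
"""

from __future__ import annotations

import numpy as np

from .models import GeneStateModel, ParamVector, make_refractory, make_telegraph
from .pgf import model_pgf_steady, pgf_time_grid, telegraph_pgf_steady

__all__ = ["TelegraphFamily", "RefractoryFamily", "get_family"]


class TelegraphFamily:
    """Two-state promoter: θ = (ρ, σ_on, σ_off, d)."""

    name = "telegraph"
    param_names = ("rho", "s_on", "s_off", "d")

    def make_model(self, theta) -> GeneStateModel:
        rho, s_on, s_off, d = theta
        return make_telegraph(rho, s_on, s_off, d)

    def steady_pgf(self, theta, z):
        rho, s_on, s_off, d = theta
        return telegraph_pgf_steady((rho / d, s_on / d, s_off / d), z)

    def time_pgf(self, theta, z, times):
        return pgf_time_grid(self.make_model(theta), z, times)

    def template(self, mode: str) -> ParamVector:
        free = [True, True, True, mode == "time"]
        return ParamVector(self.param_names, np.ones(4), np.array(free))


class RefractoryFamily:
    """Cyclic three-state promoter: θ = (k12, k23, k31, ρ, d);
    transcription only in the third state."""

    name = "refractory"
    param_names = ("k12", "k23", "k31", "rho", "d")

    def make_model(self, theta) -> GeneStateModel:
        k12, k23, k31, rho, d = theta
        return make_refractory(k12, k23, k31, rho, d)

    def steady_pgf(self, theta, z):
        return model_pgf_steady(self.make_model(theta), z)

    def time_pgf(self, theta, z, times):
        return pgf_time_grid(self.make_model(theta), z, times)

    def template(self, mode: str) -> ParamVector:
        free = [True, True, True, True, mode == "time"]
        return ParamVector(self.param_names, np.ones(5), np.array(free))


_FAMILIES = {"telegraph": TelegraphFamily, "refractory": RefractoryFamily}


def get_family(tag):
    """Resolve a family tag (or pass a family instance through)."""
    if isinstance(tag, str):
        try:
            return _FAMILIES[tag]()
        except KeyError:
            raise ValueError(f"unknown family {tag!r}; choose from {sorted(_FAMILIES)}")
    return tag
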