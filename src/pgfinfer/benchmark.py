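"""Scaled-down benchmark sweeps comparing the inference methods.

Each experiment mirrors one of the evaluation protocols: the
integration-range sweep on clean steady-state data, the accuracy vs
sample-size comparison, binomial downsampling, outlier contamination,
and the cells-per-snapshot × number-of-snapshots budget trade-off for
time-resolved data.  Defaults are deliberately small (a few parameter
sets × a few replicate batches) so a full sweep finishes in minutes on
one CPU; paper-scale settings are plain arguments away.

Results come back as a tidy DataFrame with one row per
(experiment, method, condition, parameter set, batch); per-condition
failures are isolated and recorded rather than aborting the sweep.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .fsp import FspMaximumLikelihood
from .inference import PGFInference, relative_error
from .moments import MomentInference
from .simulate import (
    SimProtocol,
    downsample,
    inject_outliers,
    sample_parameters,
    simulate_snapshots,
)

__all__ = ["run_benchmark"]

logger = logging.getLogger(__name__)

_FITTERS = {
    "pgf": PGFInference,
    "mom": MomentInference,
    "mle": FspMaximumLikelihood,
}


def _fit_re(method, dataset, theta, **kwargs):
    model = _FITTERS[method](dataset, **kwargs)
    res = model.fit()
    return relative_error(theta, res.params)


def _make_model(theta):
    from .models import make_telegraph

    rho, s_on, s_off, d = theta.values
    return make_telegraph(rho, s_on, s_off, d)


def run_benchmark(
    experiments=("range", "sample_size", "downsample", "outlier", "time_budget"),
    n_param_sets: int = 5,
    n_batches: int = 3,
    seed: int = 0,
    methods=("pgf", "mom", "mle"),
    sample_sizes=(1000, 10000),
) -> pd.DataFrame:
    """Run the requested experiment sweeps; returns one tidy table."""
    thetas = sample_parameters(n_sets=n_param_sets, seed=seed)
    rows = []
    for exp in experiments:
        fn = {
            "range": _exp_range,
            "sample_size": lambda t, b, s, m: _exp_sample_size(t, b, s, m, sample_sizes),
            "downsample": _exp_downsample,
            "outlier": _exp_outlier,
            "time_budget": _exp_time_budget,
        }[exp]
        rows.extend(fn(thetas, n_batches, seed, methods))
    return pd.DataFrame(rows)


def _record(rows, exp, method, condition, pset, batch, value, error=None):
    rows.append(
        {
            "experiment": exp,
            "method": method,
            "condition": condition,
            "param_set": pset,
            "batch": batch,
            "relative_error": value,
            "error": error,
        }
    )


def _steady_batches(theta, n_c, n_batches, seed):
    proto = SimProtocol(_make_model(theta), n_c=n_c, seed=seed, batches=n_batches)
    out = simulate_snapshots(proto)
    return out if isinstance(out, list) else [out]


def _exp_range(thetas, n_batches, seed, methods):
    """Integration-range sweep on clean 1000-cell steady data (PGF only)."""
    ranges = [(i / 10, i / 10 + 0.1) for i in range(10)] + [(0.0, 1.0)]
    rows = []
    for p, theta in enumerate(thetas):
        for b, ds in enumerate(_steady_batches(theta, 1000, n_batches, seed + 100 + p)):
            for z_min, z_max in ranges:
                cond = f"[{z_min:g},{z_max:g}]"
                try:
                    re = _fit_re("pgf", ds, theta, z_min=z_min, z_max=z_max)
                    _record(rows, "range", "pgf", cond, p, b, re)
                except Exception as exc:
                    _record(rows, "range", "pgf", cond, p, b, np.nan, str(exc))
    return rows


def _exp_sample_size(thetas, n_batches, seed, methods, sample_sizes=(1000, 10000)):
    rows = []
    for n_c in sample_sizes:
        for p, theta in enumerate(thetas):
            for b, ds in enumerate(_steady_batches(theta, n_c, n_batches, seed + 200 + p)):
                for method in methods:
                    try:
                        re = _fit_re(method, ds, theta)
                        _record(rows, "sample_size", method, str(n_c), p, b, re)
                    except Exception as exc:
                        _record(rows, "sample_size", method, str(n_c), p, b, np.nan, str(exc))
    return rows


def _exp_downsample(thetas, n_batches, seed, methods):
    """Binomial(n, 0.5) capture on the 1000-cell datasets."""
    rows = []
    for p, theta in enumerate(thetas):
        for b, ds in enumerate(_steady_batches(theta, 1000, n_batches, seed + 300 + p)):
            thinned = downsample(ds, 0.5, seed=seed + 900 + 10 * p + b)
            for method in methods:
                for cond, dset in (("clean", ds), ("downsampled_p0.5", thinned)):
                    try:
                        re = _fit_re(method, dset, theta)
                        _record(rows, "downsample", method, cond, p, b, re)
                    except Exception as exc:
                        _record(rows, "downsample", method, cond, p, b, np.nan, str(exc))
    return rows


def _exp_outlier(thetas, n_batches, seed, methods):
    """One outlier count of 30 per 3000-cell batch."""
    rows = []
    for p, theta in enumerate(thetas):
        for b, ds in enumerate(_steady_batches(theta, 3000, n_batches, seed + 400 + p)):
            dirty = inject_outliers(ds, value=30, k_per_batch=1, seed=seed + 950 + 10 * p + b)
            for method in methods:
                for cond, dset in (("clean", ds), ("outlier30", dirty)):
                    try:
                        re = _fit_re(method, dset, theta)
                        _record(rows, "outlier", method, cond, p, b, re)
                    except Exception as exc:
                        _record(rows, "outlier", method, cond, p, b, np.nan, str(exc))
    return rows


def _exp_time_budget(thetas, n_batches, seed, methods):
    """n_c × n_t = 6000 budget split for time-resolved data (PGF and MOM;
    the FSP likelihood is far slower here and is skipped by default in
    the scaled-down sweep)."""
    from .models import ParamVector

    splits = [(500, 12), (1000, 6), (2000, 3)]
    rows = []
    methods = [m for m in methods if m != "mle"]
    for p, theta in enumerate(thetas):
        model = _make_model(theta)
        theta_free_d = ParamVector(theta.names, theta.values)
        for n_c, n_t in splits:
            times = tuple(np.linspace(6.0 / n_t, 6.0, n_t))
            proto = SimProtocol(model, n_c=n_c, times=times, seed=seed + 500 + p, batches=n_batches)
            out = simulate_snapshots(proto)
            batches = out if isinstance(out, list) else [out]
            for b, ds in enumerate(batches):
                for method in methods:
                    cond = f"nc{n_c}_nt{n_t}"
                    try:
                        re = _fit_re(method, ds, theta_free_d)
                        _record(rows, "time_budget", method, cond, p, b, re)
                    except Exception as exc:
                        _record(rows, "time_budget", method, cond, p, b, np.nan, str(exc))
    return rows
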