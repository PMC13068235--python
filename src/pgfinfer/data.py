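"""Snapshot count data and its file formats.

A :class:`CountDataset` holds cells × species molecule-count matrices,
either a single steady-state snapshot or one matrix per measurement
time.  On disk the canonical representation is a long-format delimited
table (columns ``time``, ``cell_id``, one column per species); a wide
per-snapshot matrix and sparse Matrix Market gene×cell input (with a
selected gene row) are also supported.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = ["CountDataset", "read_counts", "write_counts", "write_pmf_table"]


class CountDataset:
    """Snapshot molecule-count data.

    Parameters
    ----------
    counts : ndarray or sequence of ndarray
        For steady-state data a single (n_c, N) integer matrix; for
        time-resolved data one matrix per measurement time.
    times : sequence of float, optional
        Strictly increasing measurement times; ``None`` marks
        steady-state data.
    species : sequence of str, optional
        Species names; defaults to ``("mRNA",)``-style generic names.
    """

    def __init__(self, counts, times=None, species=None):
        if times is None:
            mats = [np.asarray(counts)]
        else:
            times = tuple(float(t) for t in times)
            if len(times) == 0:
                raise ValueError("times must be non-empty (or None for steady state)")
            if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
                raise ValueError("times must be strictly increasing")
            mats = [np.asarray(m) for m in counts]
            if len(mats) != len(times):
                raise ValueError("one count matrix per time required")
        clean = []
        for j, m in enumerate(mats):
            if m.ndim == 1:
                m = m[:, None]
            if m.size == 0:
                raise ValueError("empty count matrix")
            if not np.issubdtype(m.dtype, np.integer):
                if not np.allclose(m, np.round(m)):
                    raise ValueError(f"non-integer counts in snapshot {j}")
                m = np.round(m).astype(np.int64)
            else:
                m = m.astype(np.int64)
            if np.any(m < 0):
                raise ValueError(f"negative counts in snapshot {j}")
            clean.append(m)
        N = clean[0].shape[1]
        if any(m.shape[1] != N for m in clean):
            raise ValueError("all snapshots must share the species dimension")
        if species is None:
            species = tuple(f"species_{j}" for j in range(N)) if N > 1 else ("mRNA",)
        species = tuple(str(s) for s in species)
        if len(species) != N:
            raise ValueError("one species name per column required")
        self._mats = clean
        self.times = times
        self.species = species

    # -- basic queries ------------------------------------------------
    @property
    def is_steady(self) -> bool:
        return self.times is None

    @property
    def n_species(self) -> int:
        return self._mats[0].shape[1]

    @property
    def n_times(self) -> int:
        return 1 if self.is_steady else len(self.times)

    @property
    def n_cells(self) -> tuple:
        return tuple(m.shape[0] for m in self._mats)

    def at(self, j: int) -> np.ndarray:
        """Count matrix of the ``j``-th snapshot (the only one if steady)."""
        return self._mats[j]

    @property
    def steady_matrix(self) -> np.ndarray:
        if not self.is_steady:
            raise ValueError("dataset is time-resolved")
        return self._mats[0]

    def subset(self, cell_indices) -> "CountDataset":
        """Restrict to the given cells; ``cell_indices`` is one index
        array per snapshot (or a single array for steady data)."""
        if self.is_steady:
            idx = [np.asarray(cell_indices)]
        else:
            idx = [np.asarray(ix) for ix in cell_indices]
            if len(idx) != self.n_times:
                raise ValueError("one index array per snapshot required")
        mats = [m[ix] for m, ix in zip(self._mats, idx)]
        if self.is_steady:
            return CountDataset(mats[0], species=self.species)
        return CountDataset(mats, times=self.times, species=self.species)

    def map_counts(self, fn) -> "CountDataset":
        """Apply ``fn(matrix, snapshot_index) -> matrix`` to every snapshot."""
        mats = [fn(m.copy(), j) for j, m in enumerate(self._mats)]
        if self.is_steady:
            return CountDataset(mats[0], species=self.species)
        return CountDataset(mats, times=self.times, species=self.species)

    def __eq__(self, other):
        if not isinstance(other, CountDataset):
            return NotImplemented
        if self.is_steady != other.is_steady or self.species != other.species:
            return False
        if not self.is_steady and self.times != other.times:
            return False
        return all(np.array_equal(a, b) for a, b in zip(self._mats, other._mats))

    def __repr__(self):
        kind = "steady" if self.is_steady else f"{self.n_times} times"
        return f"CountDataset({kind}, n_cells={self.n_cells}, species={self.species})"


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    head = Path(path).read_text().splitlines()
    if not head:
        raise ValueError(f"{path}: empty file")
    return "\t" if "\t" in head[0] else ","


def read_counts(path, format: str = "long", gene=None) -> CountDataset:
    """Read a count table.

    ``format`` is ``"long"`` (time, cell_id, species columns; an empty
    time column marks steady-state data), ``"wide"`` (a single cells ×
    species matrix, steady state), or ``"mtx"`` (Matrix Market gene×cell
    matrix; ``gene`` selects the row, yielding a single-species
    steady-state dataset).
    """
    path = Path(path)
    if format == "mtx":
        if gene is None:
            raise ValueError("matrix-market input requires a gene selector")
        mat = scipy.io.mmread(str(path))
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        row = np.asarray(mat)[int(gene)]
        return CountDataset(row.astype(np.int64)[:, None], species=(f"gene_{gene}",))
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if format == "wide":
        return CountDataset(_validated_counts(df, path), species=tuple(df.columns))
    if format != "long":
        raise ValueError(f"unknown format {format!r}")
    required = {"time", "cell_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: long format needs columns {sorted(required)}")
    species = tuple(c for c in df.columns if c not in ("time", "cell_id"))
    if not species:
        raise ValueError(f"{path}: no species columns found")
    if df["time"].isna().all():
        counts = _validated_counts(df[list(species)], path)
        return CountDataset(counts, species=species)
    if df["time"].isna().any():
        raise ValueError(f"{path}: mixed steady and timed rows")
    times = sorted(df["time"].unique())
    mats = []
    for t in times:
        sub = df[df["time"] == t].sort_values("cell_id")
        mats.append(_validated_counts(sub[list(species)], path))
    return CountDataset(mats, times=times, species=species)


def _validated_counts(df: pd.DataFrame, path) -> np.ndarray:
    arr = df.to_numpy()
    for i, row in enumerate(arr):
        vals = np.asarray(row, dtype=float)
        if np.any(~np.isfinite(vals)) or np.any(vals < 0) or np.any(vals != np.round(vals)):
            raise ValueError(f"{path}: row {i} has negative or non-integer counts")
    return arr.astype(np.int64)


def write_counts(data: CountDataset, path, format: str = "long") -> None:
    """Write a dataset; the long format round-trips losslessly."""
    path = Path(path)
    if format == "long":
        frames = []
        for j in range(data.n_times):
            m = data.at(j)
            frame = pd.DataFrame(m, columns=list(data.species))
            frame.insert(0, "cell_id", np.arange(m.shape[0]))
            frame.insert(0, "time", np.nan if data.is_steady else data.times[j])
            frames.append(frame)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    elif format == "wide":
        if not data.is_steady:
            raise ValueError("wide format holds a single steady-state snapshot")
        pd.DataFrame(data.steady_matrix, columns=list(data.species)).to_csv(path, index=False)
    elif format == "mtx":
        if not data.is_steady or data.n_species != 1:
            raise ValueError("mtx export supports single-species steady data")
        mat = scipy.sparse.coo_matrix(data.steady_matrix.T)  # gene x cell
        scipy.io.mmwrite(str(path), mat)
    else:
        raise ValueError(f"unknown format {format!r}")


def write_pmf_table(pmf, path, label: str = "probability") -> None:
    """Write a probability mass function as a two-column delimited table
    (count, probability) — used by validation and plotting workflows."""
    arr = np.asarray(pmf, dtype=float)
    pd.DataFrame({"count": np.arange(arr.size), label: arr}).to_csv(path, index=False)
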