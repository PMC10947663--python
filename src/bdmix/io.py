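"""Reading and writing screens as tidy CSV.

A dataset file is a tidy table with columns time, dose, replicate, count —
one row per observation on the full factorial grid, including the t = 0
rows, which must all equal the known initial count n.  Counts are stored as
floating point (observation noise is additive Gaussian, so observed counts
are not integers); writing and re-reading a dataset is bitwise lossless for
the numeric payload.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import Dataset, ExperimentDesign

__all__ = ["read_dataset", "write_dataset", "dataset_to_frame"]

_COLUMNS = ["time", "dose", "replicate", "count"]


def dataset_to_frame(data: Dataset) -> pd.DataFrame:
    """Tidy (time, dose, replicate, count) view of a Dataset."""
    times = np.asarray(data.design.times)
    doses = np.asarray(data.design.doses)
    reps = np.arange(1, data.design.n_replicates + 1)
    t_idx, d_idx, r_idx = np.meshgrid(np.arange(times.size),
                                      np.arange(doses.size),
                                      np.arange(reps.size), indexing="ij")
    return pd.DataFrame({
        "time": times[t_idx.ravel()],
        "dose": doses[d_idx.ravel()],
        "replicate": reps[r_idx.ravel()],
        "count": data.counts.ravel(),
    })


def write_dataset(data: Dataset, path) -> None:
    """Write a Dataset as tidy CSV (full round-trip precision)."""
    dataset_to_frame(data).to_csv(path, index=False)


def read_dataset(path, expected_design: ExperimentDesign | None = None,
                 mode: str = "livecell") -> Dataset:
    """Read and validate a tidy dataset CSV.

    The file must contain the full factorial (time, dose, replicate) grid;
    any missing cell is a structured error naming the cell.  All t = 0
    counts must be identical — they define the known initial count n.  If
    expected_design is given, the file's grid must match it exactly (and its
    mode wins over the `mode` argument, which otherwise declares how the
    counts were acquired, since the file itself does not record this).
    """
    # the default (fast) float parser is not correctly rounded; round_trip
    # keeps read(write(x)) bitwise exact
    frame = pd.read_csv(path, float_precision="round_trip")
    missing_cols = [c for c in _COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"dataset file missing columns: {missing_cols}")
    for col in _COLUMNS:
        if not np.issubdtype(frame[col].dtype, np.number):
            raise ValueError(f"non-numeric entries in column {col!r}")
    if frame[_COLUMNS].isna().any().any():
        raise ValueError("dataset file contains empty cells")

    times = np.sort(frame["time"].unique())
    doses = np.sort(frame["dose"].unique())
    reps = np.sort(frame["replicate"].unique())
    pivot = frame.set_index(["time", "dose", "replicate"])["count"]
    if pivot.index.has_duplicates:
        dup = pivot.index[pivot.index.duplicated()][0]
        raise ValueError(f"duplicate rows for (time, dose, replicate) = {dup}")
    counts = np.empty((times.size, doses.size, reps.size))
    for i, t in enumerate(times):
        for j, d in enumerate(doses):
            for k, r in enumerate(reps):
                try:
                    counts[i, j, k] = pivot.loc[(t, d, r)]
                except KeyError:
                    raise ValueError(
                        f"missing grid cell (time={t}, dose={d}, replicate={r})"
                    ) from None

    zero = counts[0]
    if not np.all(zero == zero.flat[0]):
        raise ValueError("t = 0 counts differ across doses/replicates; the "
                         "initial count must be a single known value")
    n = zero.flat[0]
    if n != int(n) or n < 1:
        raise ValueError(f"initial count at t = 0 must be a positive integer, got {n}")

    if expected_design is not None:
        same = (np.array_equal(times, expected_design.times)
                and np.array_equal(doses, np.sort(expected_design.doses))
                and reps.size == expected_design.n_replicates)
        if not same:
            raise ValueError("dataset grid does not match the expected design")
        mode = expected_design.mode
    design = ExperimentDesign(times=times, doses=doses,
                              n_replicates=reps.size, mode=mode)
    return Dataset(counts=counts, design=design, n=int(n))
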