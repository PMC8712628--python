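"""Readers and writers for the pipeline's on-disk artifacts.

Signals live in an HDF5 container (one ``(n_roi, n_samples)`` dataset per
subject, with a sampling-rate attribute and ROI labels); cohort metadata and
all result tables are plain CSV with fixed, documented column schemas.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .preprocess import RoiTimeSeriesSet
from .stats import ParticipantRecord, records_to_frame

#: cohort metadata CSV columns, in order
METADATA_COLUMNS = [
    "subject_id", "group", "sex", "age_months", "mps", "ach",
    "srs_t", "srs_awa", "srs_cog", "srs_com", "srs_mot", "srs_man",
    "ados_sc", "epoch_count",
]


def write_signals(path: str | Path, signal_sets: list[RoiTimeSeriesSet]) -> None:
    """One HDF5 dataset per subject: ROI x sample, with fs and ROI labels."""
    with h5py.File(path, "w") as f:
        for ts in signal_sets:
            d = f.create_dataset(ts.subject_id, data=ts.data)
            d.attrs["fs"] = ts.fs
            d.attrs["roi_labels"] = np.array(ts.roi_labels, dtype="S")


def read_signals(path: str | Path) -> list[RoiTimeSeriesSet]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            d = f[name]
            labels = [s.decode() for s in d.attrs["roi_labels"]]
            out.append(RoiTimeSeriesSet(name, float(d.attrs["fs"]), labels, d[()]))
    return out


def write_metadata(path: str | Path, records: list[ParticipantRecord] | pd.DataFrame) -> None:
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df[METADATA_COLUMNS].to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_connectivity_csv(path: str | Path, matrix: ConnectivityMatrix,
                           roi_labels: list[str] | None = None) -> None:
    """Epoch-averaged PLI matrix as CSV with a ROI-label header."""
    n = matrix.n_roi
    labels = roi_labels or [f"roi_{k:02d}" for k in range(n)]
    pd.DataFrame(matrix.values, index=labels, columns=labels).to_csv(path)


def read_connectivity_csv(path: str | Path, subject_id: str, band: str) -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConnectivityMatrix(subject_id, band, df.to_numpy(float))
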