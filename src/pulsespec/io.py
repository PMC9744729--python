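"""Delimited-text readers and writers for recordings, R-R series and
tables.

Recording files are two-column CSV (time_s, amplitude) with a header
comment line carrying the sampling rate; R-R files hold one interval in
seconds per line; the subject table is a CSV with subject_id, group,
mets_status and file references.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .segmentation import Recording


def write_recording(path: str | Path, recording: Recording) -> None:
    path = Path(path)
    t = np.arange(recording.samples.size) / recording.sampling_rate
    with path.open("w") as fh:
        fh.write(f"# sampling_rate={recording.sampling_rate}\n")
        fh.write("time_s,amplitude\n")
        for ti, xi in zip(t, recording.samples):
            fh.write(f"{ti:.6f},{xi:.6f}\n")


def read_recording(path: str | Path, rr_path: str | Path | None = None) -> Recording:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
    if not header.startswith("# sampling_rate="):
        raise ValidationError(f"{path} lacks a sampling_rate header")
    rate = float(header.split("=", 1)[1])
    frame = pd.read_csv(path, comment="#")
    rr = read_rr(rr_path) if rr_path is not None else None
    return Recording(frame["amplitude"].to_numpy(dtype=float), rate, rr_intervals=rr)


def write_rr(path: str | Path, rr_intervals: np.ndarray) -> None:
    np.savetxt(path, np.asarray(rr_intervals, dtype=float), fmt="%.6f")


def read_rr(path: str | Path) -> np.ndarray:
    return np.atleast_1d(np.loadtxt(path, dtype=float))


def write_table(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
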