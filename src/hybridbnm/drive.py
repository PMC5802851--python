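"""Per-region injected drive ("source activity") container and I/O.

The drive holds the region-wise aggregated electrical source activity that
replaces stochastic input in the hybrid model: an N x T real matrix sampled
at 1 kHz, z-scored per region, interpreted as current once scaled by the
``w_BG`` weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class DriveTimeSeries:
    """N x T injected-current matrix with its sampling rate (Hz)."""

    values: np.ndarray
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(v)):
            raise ValueError("drive contains non-finite values")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.sample_rate

    def zscored(self) -> "DriveTimeSeries":
        """Return a per-region z-scored copy (mean 0, s.d. 1)."""
        v = self.values
        sd = v.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return DriveTimeSeries((v - v.mean(axis=1, keepdims=True)) / sd,
                               self.sample_rate)


def read_drive(path: str | Path, sample_rate: float | None = None,
               dataset: str = "drive") -> DriveTimeSeries:
    """Read an N x T drive matrix from CSV/TSV text or HDF5."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            v = np.asarray(f[dataset])
            rate = float(f[dataset].attrs.get("sample_rate", sample_rate or 1000.0))
    else:
        text = path.read_text()
        first = text.splitlines()[0]
        delim = "," if "," in first else ("\t" if "\t" in first else None)
        v = np.loadtxt(path, delimiter=delim)
        rate = sample_rate or 1000.0
    return DriveTimeSeries(np.atleast_2d(v), rate)


def write_drive(drive: DriveTimeSeries, path: str | Path,
                dataset: str = "drive") -> None:
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            d = f.create_dataset(dataset, data=drive.values)
            d.attrs["sample_rate"] = drive.sample_rate
    else:
        delim = "\t" if path.suffix.lower() == ".tsv" else ","
        np.savetxt(path, drive.values, delimiter=delim)
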