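"""Structural connectome container and plain-text / HDF5 I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class StructuralConnectome:
    """Nonnegative region-to-region white-matter coupling matrix C_ij.

    The matrix is max-normalized (largest entry 1) with a zero diagonal,
    mirroring how tractography-derived connectomes are prepared for
    whole-brain models.
    """

    weights: np.ndarray
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights contain non-finite entries")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        self.weights = w
        if not self.region_labels:
            self.region_labels = [f"region_{i}" for i in range(w.shape[0])]
        if len(self.region_labels) != w.shape[0]:
            raise ValueError("region_labels length does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def normalized(self) -> "StructuralConnectome":
        """Zero the diagonal and divide by the maximum entry."""
        w = self.weights.copy()
        np.fill_diagonal(w, 0.0)
        m = w.max()
        if m > 0:
            w = w / m
        return StructuralConnectome(w, list(self.region_labels))


def read_connectome(path: str | Path, normalize: bool = True,
                    dataset: str = "weights") -> StructuralConnectome:
    """Read an N x N matrix from whitespace/CSV text or HDF5.

    HDF5 is detected by suffix (``.h5``/``.hdf5``); anything else is parsed
    as a delimited text matrix (comma or whitespace).
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            w = np.asarray(f[dataset])
            labels = [
                s.decode() if isinstance(s, bytes) else str(s)
                for s in f.attrs.get("region_labels", [])
            ]
    else:
        text = path.read_text()
        delim = "," if "," in text.splitlines()[0] else None
        w = np.loadtxt(path, delimiter=delim)
        labels = []
    sc = StructuralConnectome(np.atleast_2d(w), labels)
    return sc.normalized() if normalize else sc


def write_connectome(sc: StructuralConnectome, path: str | Path,
                     dataset: str = "weights") -> None:
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset(dataset, data=sc.weights)
            f.attrs["region_labels"] = [s.encode() for s in sc.region_labels]
    else:
        np.savetxt(path, sc.weights, delimiter=",")
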