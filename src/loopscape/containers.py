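"""Core in-memory containers shared across the pipeline.

A :class:`Trajectory` holds Cartesian coordinates in Ångström together with
an mdtraj topology; a :class:`FeatureSeries` holds a frames × features matrix
of scalar collective variables (pair distances, dihedrals, TIC projections).
Both carry the physical time interval between consecutive frames so that
kinetic quantities downstream can be reported in physical units.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "FeatureSeries", "read_array_dialect", "write_array_dialect"]


@dataclass
class Trajectory:
    """Cartesian coordinates (frames × atoms × 3, Å) plus topology.

    Parameters
    ----------
    xyz : ndarray, shape (n_frames, n_atoms, 3)
        Coordinates in Ångström.
    frame_interval : float
        Physical time between consecutive frames (arbitrary units, > 0).
    topology : mdtraj.Topology
        Atom names, residue numbers and chain ids.
    """

    xyz: np.ndarray
    frame_interval: float
    topology: object  # mdtraj.Topology

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise ValueError(f"xyz must be (frames, atoms, 3); got {self.xyz.shape}")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates contain non-finite values")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.topology is not None and self.topology.n_atoms != self.xyz.shape[1]:
            raise ValueError(
                f"topology has {self.topology.n_atoms} atoms but coordinates "
                f"have {self.xyz.shape[1]}"
            )

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[1]


@dataclass
class FeatureSeries:
    """Per-trajectory frames × features matrix with one label per column."""

    values: np.ndarray
    labels: list[str]
    frame_interval: float = 1.0
    source_id: str = "traj-0"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.labels = list(self.labels)
        if self.values.shape[1] != len(self.labels):
            raise ValueError(
                f"{len(self.labels)} labels for {self.values.shape[1]} feature columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values contain NaN/inf")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy representation: frame index, source id, one column per feature."""
        df = pd.DataFrame(self.values, columns=self.labels)
        df.insert(0, "source_id", self.source_id)
        df.insert(0, "frame", np.arange(self.n_frames))
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, frame_interval: float = 1.0) -> "FeatureSeries":
        df = pd.read_csv(path)
        labels = [c for c in df.columns if c not in ("frame", "source_id")]
        source = str(df["source_id"].iloc[0]) if "source_id" in df else "traj-0"
        return cls(df[labels].to_numpy(), labels, frame_interval, source)


# ---------------------------------------------------------------------------
# Plain-text array dialect: a human-readable coordinate format used by the
# synthetic generator alongside DCD.  Layout:
#
#   # loopscape-array shape=(F,A,3) frame_interval=DT
#   x y z          <- one atom per line, frames concatenated row-major
# ---------------------------------------------------------------------------

_HEADER = "# loopscape-array shape=({},{},{}) frame_interval={}"


def write_array_dialect(path: str | Path, xyz: np.ndarray, frame_interval: float = 1.0) -> None:
    xyz = np.asarray(xyz, dtype=float)
    if xyz.ndim != 3 or xyz.shape[2] != 3:
        raise ValueError("expected (frames, atoms, 3) array")
    f, a, _ = xyz.shape
    buf = io.StringIO()
    buf.write(_HEADER.format(f, a, 3, repr(frame_interval)) + "\n")
    np.savetxt(buf, xyz.reshape(f * a, 3), fmt="%.8f")
    Path(path).write_text(buf.getvalue())


def read_array_dialect(path: str | Path) -> tuple[np.ndarray, float]:
    """Return (xyz, frame_interval) from the plain-text dialect."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# loopscape-array"):
            raise ValueError(f"{path}: not a loopscape array file")
        shape_part = header.split("shape=(")[1].split(")")[0]
        shape = tuple(int(s) for s in shape_part.split(","))
        dt = float(header.split("frame_interval=")[1])
        flat = np.loadtxt(fh)
    flat = np.atleast_2d(flat)
    expected = shape[0] * shape[1]
    if flat.shape[0] != expected:
        raise ValueError(
            f"{path}: truncated file — header promises {expected} atom rows, found {flat.shape[0]}"
        )
    return flat.reshape(shape), dt
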