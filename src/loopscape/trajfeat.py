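"""Trajectory reading and geometric featurization.

Computes the collective variables the kinetic analysis is built on: pairwise
distances between atoms or residue-group centroids, backbone φ/ψ dihedrals,
RMSD after optimal superposition, and per-atom RMSF.  File I/O (PDB topology,
DCD coordinates) goes through mdtraj; a plain-text array dialect is also
accepted so that synthetic fixtures remain human-readable.

Selections use 1-based residue numbering following PDB convention and are
written as ``chain/resSeq/atom_name`` triplets (e.g. ``"A/175/CA"``); a
``chain/resSeq`` pair selects all atoms of the residue, whose centroid is
then used for distances.  No periodic-boundary imaging is performed: inputs
are assumed to be whole-molecule, as is typical for post-processed protein
trajectories.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .containers import FeatureSeries, Trajectory, read_array_dialect, write_array_dialect

__all__ = [
    "AtomPairSpec",
    "read_trajectory",
    "write_trajectory",
    "resolve_selection",
    "pairwise_distances",
    "backbone_dihedrals",
    "dihedral_angle",
    "superpose_rmsd",
    "atomic_fluctuations",
]

_NM_TO_ANG = 10.0


def read_trajectory(topology_path: str | Path, coords_path: str | Path, frame_interval: float = 1.0) -> Trajectory:
    """Load a trajectory from a PDB topology plus DCD or plain-array coordinates.

    Coordinates are returned in Ångström regardless of on-disk units.
    Raises ``ValueError`` on an atom-count mismatch or truncated file.
    """
    import mdtraj as md

    topology_path, coords_path = Path(topology_path), Path(coords_path)
    for p in (topology_path, coords_path):
        if not p.exists():
            raise FileNotFoundError(p)
    top = md.load_topology(str(topology_path))
    suffix = coords_path.suffix.lower()
    if suffix == ".dcd":
        with md.formats.DCDTrajectoryFile(str(coords_path)) as fh:
            xyz_ang, _, _ = fh.read()  # DCD stores Å natively
        xyz = np.asarray(xyz_ang, dtype=float)
        dt = frame_interval
    elif suffix in (".txt", ".arr"):
        xyz, dt = read_array_dialect(coords_path)
    elif suffix == ".pdb":
        t = md.load(str(coords_path))
        xyz = t.xyz * _NM_TO_ANG
        dt = frame_interval
    else:
        raise ValueError(f"unrecognized coordinate format: {coords_path.suffix}")
    if xyz.shape[1] != top.n_atoms:
        raise ValueError(
            f"atom-count mismatch: topology {topology_path.name} has {top.n_atoms} atoms, "
            f"coordinates {coords_path.name} have {xyz.shape[1]}"
        )
    return Trajectory(xyz, dt, top)


def write_trajectory(traj: Trajectory, topology_path: str | Path, coords_path: str | Path) -> None:
    """Write topology as PDB and coordinates as DCD or plain-text array."""
    import mdtraj as md

    if traj.topology is None:
        raise ValueError("trajectory carries no topology; cannot write PDB")
    mt = md.Trajectory(traj.xyz[:1] / _NM_TO_ANG, traj.topology)
    mt.save_pdb(str(topology_path))
    suffix = Path(coords_path).suffix.lower()
    if suffix == ".dcd":
        with md.formats.DCDTrajectoryFile(str(coords_path), "w") as fh:
            fh.write(traj.xyz)
    elif suffix in (".txt", ".arr"):
        write_array_dialect(coords_path, traj.xyz, traj.frame_interval)
    else:
        raise ValueError(f"unrecognized coordinate format: {suffix}")


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def resolve_selection(topology, sel: str | Sequence) -> np.ndarray:
    """Resolve ``chain/resSeq[/atom_name]`` to atom indices.

    Returns a nonempty integer array; raises ``ValueError`` if nothing (or,
    for an atom-level selection, more than one atom) matches.
    """
    if isinstance(sel, (list, tuple)) and not isinstance(sel, str):
        parts = [str(p) for p in sel]
    else:
        parts = str(sel).split("/")
    if len(parts) not in (2, 3):
        raise ValueError(f"selection {sel!r}: expected chain/resSeq or chain/resSeq/atom")
    chain_id, resseq = parts[0], int(parts[1])
    atom_name = parts[2] if len(parts) == 3 else None
    idx = []
    for atom in topology.atoms:
        ch = atom.residue.chain
        cid = getattr(ch, "chain_id", None) or chr(ord("A") + ch.index)
        if cid != chain_id or atom.residue.resSeq != resseq:
            continue
        if atom_name is None or atom.name == atom_name:
            idx.append(atom.index)
    if not idx:
        raise ValueError(f"selection {sel!r} matches no atoms")
    if atom_name is not None and len(idx) > 1:
        raise ValueError(f"selection {sel!r} is ambiguous ({len(idx)} atoms)")
    return np.asarray(idx, dtype=int)


@dataclass
class AtomPairSpec:
    """Pairs of selections; multi-atom selections are reduced to centroids."""

    pairs: list[tuple[str, str]]

    def resolve(self, topology) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(resolve_selection(topology, a), resolve_selection(topology, b)) for a, b in self.pairs]

    def labels(self) -> list[str]:
        return [f"d({a}|{b})" for a, b in self.pairs]


def _centroid(xyz: np.ndarray, idx: np.ndarray) -> np.ndarray:
    return xyz[:, idx, :].mean(axis=1)


def pairwise_distances(traj: Trajectory, spec: AtomPairSpec) -> FeatureSeries:
    """Euclidean distance per frame for each selection pair, in Å."""
    resolved = spec.resolve(traj.topology)
    cols = []
    for ia, ib in resolved:
        d = np.linalg.norm(_centroid(traj.xyz, ia) - _centroid(traj.xyz, ib), axis=1)
        cols.append(d)
    return FeatureSeries(np.column_stack(cols), spec.labels(), traj.frame_interval, "distances")


# ---------------------------------------------------------------------------
# Dihedrals
# ---------------------------------------------------------------------------

def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Signed dihedral (degrees, IUPAC convention) for frames × 3 points.

    Zero for a cis (eclipsed) arrangement, ±180° for trans; positive for a
    right-handed (clockwise looking 1→2) rotation of the far bond.  Output
    mapped into (−180°, 180°].
    """
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # arctan2 returns [-180, 180]; fold the closed lower edge onto +180
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    return ang


def backbone_dihedrals(traj: Trajectory, chain_id: str, resseq: int) -> FeatureSeries:
    """φ and ψ (degrees) of one residue.

    φ = C(i−1)–N(i)–Cα(i)–C(i);  ψ = N(i)–Cα(i)–C(i)–N(i+1).
    Requires the residue's neighbours to carry the defining backbone atoms.
    """
    top = traj.topology

    def atom(rs: int, name: str) -> int:
        try:
            return int(resolve_selection(top, f"{chain_id}/{rs}/{name}")[0])
        except ValueError as e:
            raise ValueError(f"missing backbone atom {name} in residue {rs}: {e}") from e

    c_prev = atom(resseq - 1, "C")
    n_i, ca_i, c_i = atom(resseq, "N"), atom(resseq, "CA"), atom(resseq, "C")
    n_next = atom(resseq + 1, "N")
    xyz = traj.xyz
    phi = dihedral_angle(xyz[:, c_prev], xyz[:, n_i], xyz[:, ca_i], xyz[:, c_i])
    psi = dihedral_angle(xyz[:, n_i], xyz[:, ca_i], xyz[:, c_i], xyz[:, n_next])
    return FeatureSeries(
        np.column_stack([phi, psi]),
        [f"phi_{chain_id}{resseq}", f"psi_{chain_id}{resseq}"],
        traj.frame_interval,
        "dihedrals",
    )


# ---------------------------------------------------------------------------
# Superposition, RMSD, RMSF
# ---------------------------------------------------------------------------

def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation R and translations aligning mobile P onto fixed Q.

    Returns (R, p_mean, q_mean) with aligned = (P − p_mean) @ R + q_mean.
    """
    pm, qm = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pm).T @ (Q - qm)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    return R, pm, qm


def superpose(traj: Trajectory, reference_frame: int = 0, selection: Sequence[int] | None = None) -> Trajectory:
    """Least-squares (Kabsch) superposition of every frame onto a reference.

    The rotation is fit on ``selection`` (all atoms by default, ≥ 3 atoms)
    and applied to all atoms.
    """
    idx = np.arange(traj.n_atoms) if selection is None else np.asarray(selection, dtype=int)
    if idx.size < 3:
        raise ValueError("superposition needs at least 3 atoms (rotation underdetermined)")
    ref = traj.xyz[reference_frame][idx]
    out = np.empty_like(traj.xyz)
    for t in range(traj.n_frames):
        R, pm, qm = _kabsch(traj.xyz[t][idx], ref)
        out[t] = (traj.xyz[t] - pm) @ R + qm
    return Trajectory(out, traj.frame_interval, traj.topology)


def superpose_rmsd(traj: Trajectory, reference_frame: int = 0, selection: Sequence[int] | None = None) -> np.ndarray:
    """Per-frame RMSD (Å) to a reference frame after optimal superposition."""
    idx = np.arange(traj.n_atoms) if selection is None else np.asarray(selection, dtype=int)
    if idx.size < 3:
        raise ValueError("RMSD needs at least 3 atoms (rotation underdetermined)")
    ref = traj.xyz[reference_frame][idx]
    rmsd = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        mob = traj.xyz[t][idx]
        R, pm, qm = _kabsch(mob, ref)
        aligned = (mob - pm) @ R + qm
        rmsd[t] = np.sqrt(np.mean(np.sum((aligned - ref) ** 2, axis=1)))
    return rmsd


def atomic_fluctuations(
    traj: Trajectory,
    selection: Sequence[int] | None = None,
    presuperpose: bool = True,
) -> np.ndarray:
    """Per-atom RMSF (Å): sqrt of time-mean squared displacement from the
    time-mean position, after superposing onto the first frame by default.

    Raises on single-frame input (fluctuation undefined).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF undefined for a single-frame trajectory")
    idx = np.arange(traj.n_atoms) if selection is None else np.asarray(selection, dtype=int)
    work = superpose(traj, 0, idx if idx.size >= 3 else None) if presuperpose else traj
    xyz = work.xyz[:, idx, :]
    mean = xyz.mean(axis=0)
    return np.sqrt(np.mean(np.sum((xyz - mean) ** 2, axis=2), axis=0))
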