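"""Downstream landscape analyses.

Free-energy surfaces on the slow (TIC) coordinates, representative
conformations for each metastable basin, the dihedral-sign vs loop-state
association analysis, distance-based contact histograms, and 3-d voxel
occupancy maps of selected atoms.

The free-energy surface supports two weighting modes: a raw 2-d histogram,
or MSM reweighting in which each frame carries weight π(microstate) /
count(microstate), correcting for non-equilibrium sampling across the
trajectory ensemble.  Energies are in units of kT with the global minimum
shifted to zero; empty bins are masked rather than carrying −∞/NaN.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats

from .containers import FeatureSeries, Trajectory
from .msmcore import MarkovModel, MetastableDecomposition, MicrostateAssignment
from . import trajfeat

__all__ = [
    "FreeEnergySurface",
    "ContactHistogram",
    "OccupancyGrid",
    "CorrelationReport",
    "msm_frame_weights",
    "free_energy_surface",
    "bin_basin_masks",
    "cramers_v",
    "representative_conformations",
    "export_representatives",
    "dihedral_state_correlation",
    "contact_histograms",
    "occupancy_grid",
]


@dataclass
class FreeEnergySurface:
    x_edges: np.ndarray
    y_edges: np.ndarray
    F: np.ndarray          # masked entries are NaN in storage but flagged by .mask
    mask: np.ndarray       # True where the bin is empty
    kT: float = 1.0

    def integrated_basin_energy(self, bin_mask: np.ndarray) -> float:
        """−kT·ln Σ exp(−F/kT) over the (occupied) bins selected by bin_mask.

        The integrated basin energy differs from the basin's minimum: basin
        *differences* of this quantity reproduce −kT·ln of the ratio of
        probability masses, so they are directly comparable to equilibrium
        population ratios from the kinetic model.
        """
        sel = bin_mask & ~self.mask
        if not sel.any():
            raise ValueError("basin contains no occupied bins")
        return float(-self.kT * scipy.special.logsumexp(-self.F[sel] / self.kT))

    def basin_minimum(self, x_range: tuple[float, float], y_range: tuple[float, float]) -> float:
        """Minimum free energy inside a rectangular region of TIC space."""
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        sel = np.ix_((xc >= x_range[0]) & (xc <= x_range[1]),
                     (yc >= y_range[0]) & (yc <= y_range[1]))
        block = np.where(self.mask[sel], np.inf, self.F[sel])
        if not np.isfinite(block).any():
            raise ValueError("region contains no occupied bins")
        return float(np.min(block))

    def to_csv(self, path: str | Path) -> None:
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        xi, yi = np.meshgrid(np.arange(xc.size), np.arange(yc.size), indexing="ij")
        df = pd.DataFrame({
            "tic1": xc[xi.ravel()], "tic2": yc[yi.ravel()],
            "free_energy_kT": np.where(self.mask, np.nan, self.F).ravel(),
        })
        df.to_csv(path, index=False)


@dataclass
class ContactHistogram:
    pair_label: str
    bin_edges: np.ndarray
    frequency: np.ndarray        # normalized to sum 1
    cutoff: float
    cutoff_fraction: float


@dataclass
class OccupancyGrid:
    origin: np.ndarray
    voxel_size: float
    counts: np.ndarray           # 3-d visit counts
    normalization: int           # frames × atoms selected

    @property
    def density(self) -> np.ndarray:
        return self.counts / self.normalization

    def to_dx(self, path: str | Path) -> None:
        """OpenDX-style scalar field of the occupancy density."""
        nx, ny, nz = self.counts.shape
        lines = [
            f"object 1 class gridpositions counts {nx} {ny} {nz}",
            "origin {:.4f} {:.4f} {:.4f}".format(*self.origin),
            f"delta {self.voxel_size:.4f} 0 0",
            f"delta 0 {self.voxel_size:.4f} 0",
            f"delta 0 0 {self.voxel_size:.4f}",
            f"object 2 class gridconnections counts {nx} {ny} {nz}",
            f"object 3 class array type double rank 0 items {nx*ny*nz} data follows",
        ]
        flat = self.density.ravel(order="C")
        for i in range(0, flat.size, 3):
            lines.append(" ".join(f"{v:.6e}" for v in flat[i:i + 3]))
        lines.append('attribute "dep" string "positions"')
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class CorrelationReport:
    contingency: np.ndarray      # 2 × m integer table (dihedral sign × state)
    score: float                 # Cramér's V in [0, 1]
    permutation_p: float
    n_perm: int


# ---------------------------------------------------------------------------
# Free-energy surface
# ---------------------------------------------------------------------------

def msm_frame_weights(model: MarkovModel, assignment: MicrostateAssignment) -> list[np.ndarray]:
    """Per-frame equilibrium weights π(microstate)/count(microstate).

    Frames whose microstate fell outside the model's active set get weight 0.
    """
    pi_full = np.zeros(assignment.k)
    pi_full[model.active_set] = model.pi
    counts = np.bincount(np.concatenate(assignment.labels), minlength=assignment.k)
    per_state = np.where(counts > 0, pi_full / np.maximum(counts, 1), 0.0)
    return [per_state[l] for l in assignment.labels]


def free_energy_surface(
    tics: Sequence[FeatureSeries] | FeatureSeries,
    weights: Sequence[np.ndarray] | np.ndarray | None = None,
    bins: int | tuple[int, int] = 80,
    kT: float = 1.0,
    extent_percentiles: tuple[float, float] = (1.0, 99.0),
) -> FreeEnergySurface:
    """F = −kT·ln(weighted 2-d histogram / max), shifted so the minimum is 0.

    Uses the first two columns (TIC 1 / TIC 2) of the projected series.
    Default binning: 80×80 over the 1st–99th percentile range of the data.
    """
    if isinstance(tics, FeatureSeries):
        tics = [tics]
    X = np.vstack([s.values[:, :2] for s in tics])
    if weights is None:
        w = np.ones(X.shape[0])
    elif isinstance(weights, np.ndarray) and weights.ndim == 1:
        w = np.asarray(weights, dtype=float)
    else:
        w = np.concatenate([np.asarray(wi, dtype=float) for wi in weights])
    if w.shape[0] != X.shape[0]:
        raise ValueError("one weight per frame required")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if isinstance(bins, int):
        bins = (bins, bins)
    if min(bins) < 2:
        raise ValueError("at least 2 bins per axis")
    lo, hi = extent_percentiles
    xr = np.percentile(X[:, 0], [lo, hi])
    yr = np.percentile(X[:, 1], [lo, hi])
    H, xe, ye = np.histogram2d(X[:, 0], X[:, 1], bins=bins, range=[xr, yr], weights=w)
    if H.max() <= 0:
        raise ValueError("all histogram bins are empty")
    mask = H <= 0
    with np.errstate(divide="ignore"):
        F = -kT * np.log(H / H.max())
    F = np.where(mask, np.nan, F)
    return FreeEnergySurface(xe, ye, F, mask, kT)


def bin_basin_masks(
    fes: FreeEnergySurface,
    tics: Sequence[FeatureSeries] | FeatureSeries,
    frame_basin: np.ndarray,
    n_basins: int,
) -> list[np.ndarray]:
    """Assign each occupied surface bin to the basin contributing the most
    frames to it; returns one boolean bin mask per basin."""
    if isinstance(tics, FeatureSeries):
        tics = [tics]
    X = np.vstack([s.values[:, :2] for s in tics])
    frame_basin = np.asarray(frame_basin, dtype=int)
    ix = np.clip(np.digitize(X[:, 0], fes.x_edges) - 1, 0, fes.x_edges.size - 2)
    iy = np.clip(np.digitize(X[:, 1], fes.y_edges) - 1, 0, fes.y_edges.size - 2)
    votes = np.zeros((fes.x_edges.size - 1, fes.y_edges.size - 1, n_basins))
    np.add.at(votes, (ix, iy, frame_basin), 1)
    winner = np.argmax(votes, axis=2)
    occupied = votes.sum(axis=2) > 0
    return [(winner == a) & occupied for a in range(n_basins)]


# ---------------------------------------------------------------------------
# Representatives
# ---------------------------------------------------------------------------

def representative_conformations(
    decomposition: MetastableDecomposition,
    assignment: MicrostateAssignment,
    tics: Sequence[FeatureSeries] | FeatureSeries,
) -> list[tuple[int, int]]:
    """Frame nearest (Euclidean, TIC space) to the membership-weighted
    centroid of each metastable state.

    Returns one (trajectory index, frame index) pair per metastable state;
    deterministic (ties broken by the earliest frame).
    """
    if isinstance(tics, FeatureSeries):
        tics = [tics]
    X = np.vstack([s.values for s in tics])
    labels = np.concatenate(assignment.labels)
    lengths = [s.n_frames for s in tics]
    if labels.size != X.shape[0]:
        raise ValueError("assignment and TIC series cover different frame counts")
    frame_memb = decomposition.memberships[labels]  # frames × m
    out = []
    offsets = np.cumsum([0] + lengths)
    for a in range(decomposition.m):
        w = frame_memb[:, a]
        if w.sum() <= 0:
            raise ValueError(f"metastable state {a} has no supporting frames")
        centroid = (w[:, None] * X).sum(axis=0) / w.sum()
        crisp_frames = np.flatnonzero(decomposition.crisp[labels] == a)
        if crisp_frames.size == 0:
            crisp_frames = np.arange(X.shape[0])
        d = np.linalg.norm(X[crisp_frames] - centroid, axis=1)
        g = int(crisp_frames[int(np.argmin(d))])
        ti = int(np.searchsorted(offsets, g, side="right") - 1)
        out.append((ti, g - int(offsets[ti])))
    return out


def export_representatives(
    trajs: Sequence[Trajectory],
    representatives: Sequence[tuple[int, int]],
    outdir: str | Path,
    prefix: str = "metastable",
) -> list[Path]:
    """Write each representative frame as a single-model PDB file."""
    import mdtraj as md

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for a, (ti, fi) in enumerate(representatives):
        traj = trajs[ti]
        if traj.topology is None:
            raise ValueError("trajectory carries no topology; cannot write PDB")
        frame = md.Trajectory(traj.xyz[fi:fi + 1] / 10.0, traj.topology)  # Å → nm
        path = outdir / f"{prefix}_{a}.pdb"
        frame.save_pdb(str(path))
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# Dihedral-sign vs metastable-state association
# ---------------------------------------------------------------------------

def cramers_v(table: np.ndarray) -> float:
    """Cramér's V = sqrt(χ² / (N·(min(r,c)−1))) for an r × c table."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n == 0:
        return 0.0
    chi2 = scipy.stats.chi2_contingency(table, correction=False)[0]
    k = min(table.shape) - 1
    if k == 0:
        return 0.0
    return float(np.sqrt(chi2 / (n * k)))


def dihedral_state_correlation(
    phi: np.ndarray | FeatureSeries,
    state_labels: np.ndarray,
    threshold: float = 0.0,
    n_perm: int = 500,
    block_length: int = 1,
    seed: int = 0,
) -> CorrelationReport:
    """Association between the sign of a backbone dihedral and the
    metastable state, as a 2 × m contingency table scored by Cramér's V.

    The permutation null shuffles contiguous blocks of ``block_length``
    frames (set it to the model lag) so that the p-value respects the
    autocorrelation of the input rather than assuming independent frames.
    """
    if isinstance(phi, FeatureSeries):
        phi = phi.values[:, 0]
    phi = np.asarray(phi, dtype=float).ravel()
    state_labels = np.asarray(state_labels, dtype=int).ravel()
    if phi.size != state_labels.size:
        raise ValueError("phi and state labels must have equal frame counts")
    m = int(state_labels.max()) + 1
    sign = (phi >= threshold).astype(int)  # 0: φ < threshold, 1: φ ≥ threshold

    def table(sig, lab):
        t = np.zeros((2, m), dtype=int)
        np.add.at(t, (sig, lab), 1)
        return t

    obs = table(sign, state_labels)
    if obs.sum(axis=1).min() == 0:
        warnings.warn("one dihedral sign class is empty; association undefined, score 0",
                      RuntimeWarning)
        return CorrelationReport(obs, 0.0, 1.0, 0)
    v_obs = cramers_v(obs)
    rng = np.random.default_rng(seed)
    nb = int(np.ceil(phi.size / max(block_length, 1)))
    block_ids = np.repeat(np.arange(nb), block_length)[: phi.size]
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(nb)
        order = np.argsort(perm[block_ids], kind="stable")
        v = cramers_v(table(sign[order], state_labels))
        if v >= v_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return CorrelationReport(obs, v_obs, float(p), n_perm)


# ---------------------------------------------------------------------------
# Contact histograms and occupancy grids
# ---------------------------------------------------------------------------

def contact_histograms(
    traj: Trajectory,
    spec: trajfeat.AtomPairSpec,
    bin_width: float = 0.25,
    cutoff: float = 4.0,
) -> list[ContactHistogram]:
    """Normalized distance histograms per pair plus the fraction of frames
    at or below the contact cutoff (Å)."""
    series = trajfeat.pairwise_distances(traj, spec)
    out = []
    for j, label in enumerate(series.labels):
        d = series.values[:, j]
        lo = np.floor(d.min() / bin_width) * bin_width
        hi = np.ceil(d.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
        edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
        h, edges = np.histogram(d, bins=edges)
        freq = h / h.sum()
        out.append(ContactHistogram(label, edges, freq, cutoff, float(np.mean(d <= cutoff))))
    return out


def occupancy_grid(
    traj: Trajectory,
    selection: Sequence[int],
    voxel_size: float = 1.0,
    superpose_first: bool = True,
    reference_frame: int = 0,
) -> OccupancyGrid:
    """Per-voxel visit counts of the selected atoms over all frames.

    The trajectory is superposed onto a reference frame first (all atoms)
    so the grid lives in a common molecular frame.  The grid origin sits on
    a voxel boundary at the floor of the selected atoms' extent.
    """
    idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise ValueError("empty atom selection")
    work = trajfeat.superpose(traj, reference_frame) if superpose_first and traj.n_atoms >= 3 else traj
    pts = work.xyz[:, idx, :].reshape(-1, 3)
    origin = np.floor(pts.min(axis=0) / voxel_size) * voxel_size
    ijk = np.floor((pts - origin) / voxel_size).astype(int)
    shape = ijk.max(axis=0) + 1
    counts = np.zeros(shape, dtype=np.int64)
    np.add.at(counts, (ijk[:, 0], ijk[:, 1], ijk[:, 2]), 1)
    return OccupancyGrid(origin, float(voxel_size), counts, int(pts.shape[0]))
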