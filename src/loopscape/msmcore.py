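"""Markov state model estimation and metastable kinetics.

The sequence implemented here is the standard trajectory-to-kinetics chain:
k-means discretization of the slow coordinates into microstates, sliding-
window transition counting at a lag time, ergodic trimming to the largest
strongly connected set, maximum-likelihood estimation of a reversible
(detailed-balance) transition matrix, spectral validation (implied
timescales, Chapman–Kolmogorov test), PCCA+ coarse-graining into a few
metastable states, and finally equilibrium populations and mean first
passage times between the metastable states.

Numerical conventions
---------------------
* Reversible MLE: fixed-point iteration on the symmetric variables
  x_ij = (c_ij + c_ji) / (c_i/x_i + c_j/x_j), which increases the likelihood
  monotonically; converged when the max relative change < ``tol``.
* MFPTs solve the first-step linear system h_i = τ + Σ_j T_ij h_j with
  h = 0 on the target and are averaged over the source weighted by the
  stationary distribution restricted to the source; reported in physical
  time via the frame interval.
* Populations of metastable states use crisp (argmax) assignments by
  default; membership-weighted populations are available as an option.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .containers import FeatureSeries

__all__ = [
    "MicrostateAssignment",
    "CountMatrix",
    "MarkovModel",
    "MetastableDecomposition",
    "KineticsResult",
    "cluster_microstates",
    "count_transitions",
    "largest_connected_set",
    "estimate_reversible_T",
    "stationary_distribution",
    "implied_timescales",
    "ck_test",
    "pcca",
    "metastable_populations",
    "mfpt",
    "compute_kinetics",
    "estimate_msm",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class MicrostateAssignment:
    """Per-frame microstate labels (one array per trajectory) + k-means centers."""

    labels: list[np.ndarray]
    centers: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.labels = [np.asarray(l, dtype=int) for l in self.labels]
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        k = self.centers.shape[0]
        for l in self.labels:
            if l.size and (l.min() < 0 or l.max() >= k):
                raise ValueError("labels outside [0, k)")

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    @property
    def n_frames(self) -> int:
        return sum(l.size for l in self.labels)


@dataclass
class CountMatrix:
    counts: np.ndarray
    lag: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("negative transition counts")


@dataclass
class MarkovModel:
    """Reversible transition matrix on the active microstate set."""

    T: np.ndarray
    pi: np.ndarray
    lag: int
    frame_interval: float = 1.0
    active_set: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        rows = self.T.sum(axis=1)
        if np.max(np.abs(rows - 1.0)) > 1e-10:
            raise ValueError("transition-matrix rows must sum to 1 within 1e-10")
        if abs(self.pi.sum() - 1.0) > 1e-10 or np.any(self.pi < -1e-15):
            raise ValueError("pi must be a probability vector")
        if self.active_set is None:
            self.active_set = np.arange(self.T.shape[0])
        self.active_set = np.asarray(self.active_set, dtype=int)

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    @property
    def lag_time(self) -> float:
        return self.lag * self.frame_interval

    def detailed_balance_residual(self) -> float:
        F = self.pi[:, None] * self.T
        return float(np.max(np.abs(F - F.T)))

    def eigenvalues(self, k: int | None = None) -> np.ndarray:
        """Real eigenvalue spectrum, sorted descending (reversible T)."""
        ev = np.linalg.eigvals(self.T)
        ev = np.real(ev[np.abs(np.imag(ev)) < 1e-10])
        ev = np.sort(ev)[::-1]
        return ev if k is None else ev[:k]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "T": self.T.tolist(),
            "pi": self.pi.tolist(),
            "lag": int(self.lag),
            "frame_interval": float(self.frame_interval),
            "active_set": self.active_set.tolist(),
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "MarkovModel":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["T"]), np.asarray(d["pi"]), d["lag"],
                   d["frame_interval"], np.asarray(d["active_set"]))


@dataclass
class MetastableDecomposition:
    """Fuzzy memberships of microstates into m metastable states."""

    memberships: np.ndarray

    def __post_init__(self) -> None:
        self.memberships = np.atleast_2d(np.asarray(self.memberships, dtype=float))
        if np.any(self.memberships < -1e-10):
            raise ValueError("memberships must be nonnegative")
        rows = self.memberships.sum(axis=1)
        if np.max(np.abs(rows - 1.0)) > 1e-10:
            raise ValueError("membership rows must sum to 1")

    @property
    def m(self) -> int:
        return self.memberships.shape[1]

    @property
    def crisp(self) -> np.ndarray:
        return np.argmax(self.memberships, axis=1)

    def sets(self) -> list[np.ndarray]:
        c = self.crisp
        return [np.flatnonzero(c == a) for a in range(self.m)]


@dataclass
class KineticsResult:
    populations: np.ndarray
    mfpt: np.ndarray  # m × m, physical time units
    lag: int
    frame_interval: float

    def __post_init__(self) -> None:
        self.populations = np.asarray(self.populations, dtype=float)
        self.mfpt = np.asarray(self.mfpt, dtype=float)
        if abs(self.populations.sum() - 1.0) > 1e-10:
            raise ValueError("populations must sum to 1")
        if np.any(np.abs(np.diag(self.mfpt)) > 0):
            raise ValueError("MFPT diagonal must be 0")

    def to_csv(self, path: str | Path) -> None:
        m = self.populations.size
        rows = []
        for a in range(m):
            row = {"state": a, "population": self.populations[a]}
            for b in range(m):
                row[f"mfpt_to_{b}"] = self.mfpt[a, b]
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Discretization and counting
# ---------------------------------------------------------------------------

def cluster_microstates(
    tics: Sequence[FeatureSeries] | FeatureSeries,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 500,
) -> MicrostateAssignment:
    """k-means (k-means++ init, fixed seed) over the pooled frames."""
    from sklearn.cluster import KMeans

    if isinstance(tics, FeatureSeries):
        tics = [tics]
    X = np.vstack([s.values for s in tics])
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds total frame count {X.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, max_iter=max_iter,
                random_state=int(seed) % (2**32))
    flat = km.fit_predict(X)
    labels, start = [], 0
    for s in tics:
        labels.append(flat[start:start + s.n_frames])
        start += s.n_frames
    return MicrostateAssignment(labels, km.cluster_centers_, int(seed))


def count_transitions(assignment: MicrostateAssignment | Sequence[np.ndarray], lag: int,
                      n_states: int | None = None) -> CountMatrix:
    """Sliding-window transition counts at the given lag, never crossing
    trajectory boundaries."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if isinstance(assignment, MicrostateAssignment):
        paths, k = assignment.labels, assignment.k
    else:
        paths = [np.asarray(p, dtype=int) for p in assignment]
        k = n_states if n_states is not None else max(int(p.max()) for p in paths) + 1
    if all(p.size <= lag for p in paths):
        raise ValueError(f"lag {lag} is >= every trajectory length")
    C = np.zeros((k, k), dtype=np.int64)
    for p in paths:
        if p.size <= lag:
            continue
        np.add.at(C, (p[:-lag], p[lag:]), 1)
    return CountMatrix(C, lag)


def largest_connected_set(counts: CountMatrix | np.ndarray) -> np.ndarray:
    """Largest strongly connected component of the directed count graph.

    Ties broken by larger total counts within the component, then by lowest
    state index.
    """
    C = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    G = nx.DiGraph()
    G.add_nodes_from(range(C.shape[0]))
    for i, j in zip(*np.nonzero(C)):
        G.add_edge(int(i), int(j))
    best = None
    for comp in nx.strongly_connected_components(G):
        nodes = sorted(comp)
        tot = int(C[np.ix_(nodes, nodes)].sum())
        key = (len(nodes), tot, -min(nodes))
        if best is None or key > best[0]:
            best = (key, nodes)
    return np.asarray(best[1], dtype=int)


# ---------------------------------------------------------------------------
# Reversible estimation
# ---------------------------------------------------------------------------

def estimate_reversible_T(
    counts: CountMatrix | np.ndarray,
    lag: int | None = None,
    frame_interval: float = 1.0,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    active_set: np.ndarray | None = None,
) -> MarkovModel:
    """Maximum-likelihood reversible transition matrix from transition counts.

    Fixed-point iteration on the symmetric variables x_ij; the stationary
    distribution falls out as the normalized row sums of x.  The count
    matrix must be restricted to (or restrictable to) a strongly connected
    active set.
    """
    if isinstance(counts, CountMatrix):
        C_full = np.asarray(counts.counts, dtype=float)
        lag = counts.lag if lag is None else lag
    else:
        C_full = np.asarray(counts, dtype=float)
        if lag is None:
            lag = 1
    if active_set is None:
        active_set = largest_connected_set(C_full)
    C = C_full[np.ix_(active_set, active_set)]
    n = C.shape[0]
    if n == 1:
        return MarkovModel(np.ones((1, 1)), np.ones(1), lag, frame_interval, active_set)

    Csym = C + C.T
    c_i = C.sum(axis=1)
    if np.any(c_i == 0):
        raise ValueError("active set not strongly connected: a state has no outgoing counts")
    x = Csym / Csym.sum()
    mask = Csym > 0
    for it in range(max_iter):
        x_i = x.sum(axis=1)
        denom = c_i[:, None] / x_i[:, None] + c_i[None, :] / x_i[None, :]
        x_new = np.where(mask, Csym / np.where(denom > 0, denom, 1.0), 0.0)
        x_new /= x_new.sum()
        delta = np.max(np.abs(x_new - x)[mask] / np.maximum(x_new[mask], 1e-300))
        x = x_new
        if delta < tol:
            break
    else:
        warnings.warn(
            f"reversible MLE did not converge in {max_iter} iterations "
            f"(residual {delta:.3g})", RuntimeWarning)
    x_i = x.sum(axis=1)
    T = x / x_i[:, None]
    T /= T.sum(axis=1, keepdims=True)  # squash last-ulp row-sum drift
    pi = x_i / x_i.sum()
    return MarkovModel(T, pi, lag, frame_interval, active_set)


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Left eigenvector of eigenvalue 1, normalized to sum 1.

    Raises ``ValueError`` on a reducible chain (degenerate unit eigenvalue).
    """
    T = np.asarray(T, dtype=float)
    vals, vecs = np.linalg.eig(T.T)
    near_one = np.abs(vals - 1.0) < 1e-8
    if near_one.sum() > 1:
        raise ValueError("reducible transition matrix: unit eigenvalue is degenerate")
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    if np.all(pi <= 0):
        pi = -pi
    if np.any(pi < -1e-10):
        raise ValueError("stationary eigenvector has mixed signs; chain may be reducible")
    pi = np.clip(pi, 0, None)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def implied_timescales(
    models: Sequence[MarkovModel],
    n_timescales: int = 3,
) -> pd.DataFrame:
    """t_i(τ) = −τ·Δt / ln λ_i(τ) for the top non-stationary eigenvalues.

    Nonpositive eigenvalues are discarded (with a warning) — they carry no
    timescale; the stationary eigenvalue λ=1 is excluded.  A lag-independent
    (flat) profile indicates Markovian behaviour at those lags.
    """
    rows = []
    for m in models:
        ev = m.eigenvalues()
        ev = ev[~np.isclose(ev, 1.0, atol=1e-12)]
        kept = ev[ev > 0][:n_timescales]
        if (ev[:n_timescales] <= 0).any():
            warnings.warn(f"lag {m.lag}: discarding nonpositive eigenvalues", RuntimeWarning)
        row = {"lag": m.lag, "lag_time": m.lag_time}
        for i, lam in enumerate(kept):
            row[f"t{i+2}"] = -m.lag * m.frame_interval / np.log(lam)
        rows.append(row)
    return pd.DataFrame(rows)


def ck_test(
    model: MarkovModel,
    assignment: MicrostateAssignment | Sequence[np.ndarray],
    factors: Sequence[int],
    decomposition: MetastableDecomposition | None = None,
    n_metastable: int = 2,
) -> pd.DataFrame:
    """Chapman–Kolmogorov test on metastable-set persistence probabilities.

    For each factor k, compares the model prediction  P_pred = persistence
    of set A under T(τ)^k  with  P_est from a model re-estimated at lag kτ,
    and reports a 3× binomial standard error band for the re-estimate.
    Columns: set, factor, p_pred, p_est, deviation, band.
    """
    if decomposition is None:
        decomposition = pcca(model, n_metastable)
    paths = assignment.labels if isinstance(assignment, MicrostateAssignment) else list(assignment)
    n_full = (assignment.k if isinstance(assignment, MicrostateAssignment)
              else max(int(p.max()) for p in paths) + 1)
    sets_active = decomposition.sets()  # indices into the active set
    rows = []
    for k in sorted(set(int(f) for f in factors)):
        if k < 1:
            raise ValueError("factors must be >= 1")
        lag_k = k * model.lag
        if all(p.size <= lag_k for p in paths):
            raise ValueError(f"insufficient data at lag {lag_k}")
        Ck = count_transitions(paths, lag_k, n_states=n_full)
        model_k = estimate_reversible_T(Ck, frame_interval=model.frame_interval)
        Tk_pred = np.linalg.matrix_power(model.T, k)
        # map active sets of the two models onto common microstate labels
        pos_k = {s: i for i, s in enumerate(model_k.active_set)}
        for a, A in enumerate(sets_active):
            micro_A = model.active_set[A]
            w = model.pi[A] / model.pi[A].sum()
            p_pred = float(w @ Tk_pred[np.ix_(A, A)].sum(axis=1))
            A_k = [pos_k[s] for s in micro_A if s in pos_k]
            if not A_k:
                continue
            pi_k = model_k.pi[A_k] / model_k.pi[A_k].sum()
            p_est = float(pi_k @ model_k.T[np.ix_(A_k, A_k)].sum(axis=1))
            # effective count divides by the factor: sliding windows at lag kτ
            # overlap k-fold relative to the estimation lag, so raw counts
            # overstate the number of independent observations
            n_eff = float(Ck.counts[np.ix_(micro_A, np.arange(n_full))].sum()) / k
            band = 3.0 * np.sqrt(max(p_est * (1 - p_est), 1e-12) / max(n_eff, 1.0))
            rows.append({"set": a, "factor": k, "p_pred": p_pred, "p_est": p_est,
                         "deviation": abs(p_pred - p_est), "band": band})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Metastable decomposition and kinetics
# ---------------------------------------------------------------------------

def pcca(model: MarkovModel, m: int) -> MetastableDecomposition:
    """PCCA+ fuzzy memberships from the top-m eigenvectors (simplex vertex
    search).

    The m dominant right eigenvectors span a simplex whose vertices are the
    signatures of the metastable states; the inner-simplex algorithm picks
    the m most extreme microstates as vertices and expresses every other
    state as a convex combination.  Memberships are clipped to [0, 1] and
    row-renormalized; the crisp map is the row argmax.
    """
    n = model.n_states
    if m < 2:
        raise ValueError("m must be >= 2")
    if m > n:
        raise ValueError(f"m={m} exceeds number of microstates {n}")
    if m == n:
        return MetastableDecomposition(np.eye(n))
    # right eigenvectors of the reversible T via the symmetric conjugate
    sqrt_pi = np.sqrt(np.maximum(model.pi, 1e-300))
    S = (sqrt_pi[:, None] * model.T) / sqrt_pi[None, :]
    S = 0.5 * (S + S.T)
    evals, V = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, V = evals[order], V[:, order]
    gap_window = evals[: min(m + 1, n)]
    if m < n and abs(gap_window[m - 1] - gap_window[min(m, n - 1)]) < 1e-12:
        warnings.warn(f"spectral degeneracy at the m={m} cut: eigenvalues "
                      f"{gap_window[m-1]:.6f} ≈ {gap_window[min(m, n-1)]:.6f}", RuntimeWarning)
    psi = V[:, :m] / sqrt_pi[:, None]  # right eigenvectors of T
    psi = psi / np.abs(psi[:, 0:1])    # first column = 1

    # inner-simplex vertex search
    verts = [int(np.argmax(np.linalg.norm(psi - psi.mean(axis=0), axis=1)))]
    basis = psi - psi[verts[0]]
    for _ in range(1, m):
        # farthest state from the affine span of the vertices chosen so far
        if len(verts) > 1:
            Q, _ = np.linalg.qr(basis[verts[1:]].T)
        else:
            Q = np.zeros((m, 0))
        resid = basis - basis @ Q @ Q.T
        verts.append(int(np.argmax(np.linalg.norm(resid, axis=1))))
    A = np.linalg.pinv(psi[verts])
    chi = psi @ A
    chi = np.clip(chi, 0.0, None)
    chi = chi / chi.sum(axis=1, keepdims=True)
    return MetastableDecomposition(chi)


def metastable_populations(
    model: MarkovModel,
    decomposition: MetastableDecomposition,
    weighted: bool = False,
) -> np.ndarray:
    """Equilibrium population of each metastable state.

    Crisp (default): sum of π over microstates assigned by argmax.
    ``weighted=True`` uses membership-weighted sums instead.
    """
    if decomposition.memberships.shape[0] != model.n_states:
        raise ValueError("decomposition does not match model dimension")
    if weighted:
        return model.pi @ decomposition.memberships
    pops = np.zeros(decomposition.m)
    for a, A in enumerate(decomposition.sets()):
        pops[a] = model.pi[A].sum()
    return pops


def mfpt(model: MarkovModel, source: Sequence[int], target: Sequence[int]) -> float:
    """Mean first passage time from a source set to a target set, in the
    model's physical time units.

    First-step analysis: h = 0 on the target, h_i = τΔt + Σ_j T_ij h_j
    elsewhere; the result is the π-weighted average of h over the source.
    MFPT of a set to itself is 0 by convention.
    """
    source = np.asarray(sorted(set(int(s) for s in source)), dtype=int)
    target = np.asarray(sorted(set(int(t) for t in target)), dtype=int)
    if source.size == 0 or target.size == 0:
        raise ValueError("source and target must be nonempty")
    if np.array_equal(source, target):
        return 0.0
    if np.intersect1d(source, target).size:
        raise ValueError("source and target must be disjoint")
    n = model.n_states
    free = np.setdiff1d(np.arange(n), target)
    A = np.eye(free.size) - model.T[np.ix_(free, free)]
    try:
        h_free = np.linalg.solve(A, np.full(free.size, model.lag_time))
    except np.linalg.LinAlgError as e:
        raise ValueError(f"target unreachable from source (singular first-step system): {e}") from e
    h = np.zeros(n)
    h[free] = h_free
    w = model.pi[source] / model.pi[source].sum()
    return float(w @ h[source])


def compute_kinetics(model: MarkovModel, decomposition: MetastableDecomposition) -> KineticsResult:
    """Populations and the full m × m MFPT matrix between metastable states."""
    pops = metastable_populations(model, decomposition)
    sets = decomposition.sets()
    m = decomposition.m
    for a, A in enumerate(sets):
        if A.size == 0:
            raise ValueError(f"metastable state {a} is empty under crisp assignment")
    M = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            if a != b:
                M[a, b] = mfpt(model, sets[a], sets[b])
    return KineticsResult(pops, M, model.lag, model.frame_interval)


def estimate_msm(
    assignment: MicrostateAssignment,
    lag: int,
    frame_interval: float = 1.0,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> MarkovModel:
    """Convenience: counts → largest connected set → reversible MLE."""
    C = count_transitions(assignment, lag)
    return estimate_reversible_T(C, frame_interval=frame_interval, tol=tol, max_iter=max_iter)
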