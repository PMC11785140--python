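"""Time-lagged independent component analysis (tICA).

tICA finds linear combinations of input features that maximize the
autocorrelation at a chosen lag time — the slowest collective coordinates
of the dynamics.  For trajectory data generated by a reversible Markov
process, the leading tICA eigenvalue at lag τ approaches the second
transition-matrix eigenvalue raised to the power τ, which is how the
estimator is validated here against synthetic chains with known spectra.

The estimator is the symmetrized (reversible) one: instantaneous and
time-lagged covariances are averaged over forward and backward time, pooled
over trajectories after removing the pooled mean, and the generalized
symmetric eigenproblem  C_τ v = λ (C_0 + εI) v  is solved with a small
shrinkage ε to guard against rank deficiency.  Components are normalized to
unit (C_0 + εI)-weighted variance and ordered by eigenvalue (kinetic order).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg

from .containers import FeatureSeries

__all__ = ["TicaModel", "estimate_tica", "project"]


@dataclass
class TicaModel:
    """Fitted tICA transform.

    ``eigenvalues`` are lag-τ autocorrelations of the components, sorted
    descending; ``components`` is (n_features, n_components) with columns
    normalized so vᵀ(C0+εI)v = 1.
    """

    lag: int
    mean: np.ndarray
    C0: np.ndarray
    Ctau: np.ndarray
    eigenvalues: np.ndarray
    components: np.ndarray
    regularization: float
    labels: list[str] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.mean.shape[0]

    def kinetic_variance_dim(self, threshold: float = 0.95) -> int:
        """Smallest n with cumulative kinetic variance Σλ² ≥ threshold."""
        kv = np.cumsum(self.eigenvalues**2)
        if kv[-1] <= 0:
            return 1
        kv = kv / kv[-1]
        return int(np.searchsorted(kv, threshold) + 1)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "lag": int(self.lag),
            "mean": self.mean.tolist(),
            "C0": self.C0.tolist(),
            "Ctau": self.Ctau.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "components": self.components.tolist(),
            "regularization": float(self.regularization),
            "labels": self.labels,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "TicaModel":
        d = json.loads(Path(path).read_text())
        return cls(
            lag=d["lag"],
            mean=np.asarray(d["mean"]),
            C0=np.asarray(d["C0"]),
            Ctau=np.asarray(d["Ctau"]),
            eigenvalues=np.asarray(d["eigenvalues"]),
            components=np.asarray(d["components"]),
            regularization=d["regularization"],
            labels=list(d.get("labels", [])),
        )


def _as_series_list(series) -> list[FeatureSeries]:
    if isinstance(series, FeatureSeries):
        return [series]
    return list(series)


def estimate_tica(
    series: Sequence[FeatureSeries] | FeatureSeries,
    lag: int,
    regularization: float | None = None,
) -> TicaModel:
    """Fit tICA on one or more feature series at the given lag (frames).

    ``regularization`` defaults to 1e-6 · trace(C0)/dim; pass 0 to disable
    (a singular C0 then raises).
    """
    series = _as_series_list(series)
    if not series:
        raise ValueError("no input series")
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    labels = series[0].labels
    for s in series:
        if s.labels != labels:
            raise ValueError("all series must share feature labels")
        if s.n_frames <= lag:
            raise ValueError(f"series {s.source_id!r} has {s.n_frames} frames <= lag {lag}")
    dim = len(labels)

    # pooled symmetric mean over heads (0..T-lag) and tails (lag..T)
    total = 0
    ssum = np.zeros(dim)
    for s in series:
        X0, Xt = s.values[:-lag], s.values[lag:]
        ssum += X0.sum(axis=0) + Xt.sum(axis=0)
        total += 2 * X0.shape[0]
    mean = ssum / total

    C0 = np.zeros((dim, dim))
    Ct = np.zeros((dim, dim))
    for s in series:
        X0 = s.values[:-lag] - mean
        Xt = s.values[lag:] - mean
        C0 += X0.T @ X0 + Xt.T @ Xt
        Ct += X0.T @ Xt
    C0 /= total
    Ct /= total / 2.0
    Ct = 0.5 * (Ct + Ct.T)  # enforce reversibility of the estimate

    if regularization is None:
        regularization = 1e-6 * np.trace(C0) / dim
    C0r = C0 + regularization * np.eye(dim)
    try:
        evals, evecs = scipy.linalg.eigh(Ct, C0r)
    except scipy.linalg.LinAlgError as e:
        raise ValueError(f"singular C0 (try regularization > 0): {e}") from e
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if np.any(evals > 1.0 + 1e-9):
        warnings.warn(
            f"tICA eigenvalue {evals.max():.4f} > 1: input may be far from equilibrium "
            "or undersampled at this lag",
            RuntimeWarning,
        )
    return TicaModel(
        lag=lag,
        mean=mean,
        C0=C0,
        Ctau=Ct,
        eigenvalues=evals,
        components=evecs,
        regularization=float(regularization),
        labels=labels,
    )


def project(model: TicaModel, series: FeatureSeries, n_components: int | None = None) -> FeatureSeries:
    """Map a feature series onto the leading TICs: (x − mean) @ components."""
    if series.labels != model.labels:
        raise ValueError("feature labels do not match the tICA training labels")
    n = model.components.shape[1] if n_components is None else int(n_components)
    if n > model.components.shape[1]:
        raise ValueError(f"requested {n} components, model has {model.components.shape[1]}")
    Y = (series.values - model.mean) @ model.components[:, :n]
    return FeatureSeries(Y, [f"TIC {i+1}" for i in range(n)], series.frame_interval, series.source_id)
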