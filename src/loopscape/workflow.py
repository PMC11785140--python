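"""High-level convenience: run the full feature → tICA → MSM → kinetics chain
in memory and relate recovered metastable states to reference labels."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import msmcore, tica as tica_mod
from .containers import FeatureSeries

__all__ = ["EnsembleResult", "analyze_ensemble", "match_states"]


@dataclass
class EnsembleResult:
    tica_model: tica_mod.TicaModel
    projections: list[FeatureSeries]
    assignment: msmcore.MicrostateAssignment
    model: msmcore.MarkovModel
    decomposition: msmcore.MetastableDecomposition
    kinetics: msmcore.KineticsResult

    def frame_metastable_labels(self) -> np.ndarray:
        """Crisp metastable label per pooled frame (−1 outside the active set)."""
        labels = np.concatenate(self.assignment.labels)
        pos = -np.ones(self.assignment.k, dtype=int)
        pos[self.model.active_set] = np.arange(self.model.active_set.size)
        out = -np.ones(labels.size, dtype=int)
        ok = pos[labels] >= 0
        out[ok] = self.decomposition.crisp[pos[labels[ok]]]
        return out


def analyze_ensemble(
    series: Sequence[FeatureSeries],
    tica_lag: int = 5,
    n_components: int | None = None,
    k: int = 9,
    msm_lag: int = 5,
    m: int = 3,
    seed: int = 0,
    frame_interval: float | None = None,
) -> EnsembleResult:
    """tICA → k-means microstates → reversible MSM → PCCA+ → kinetics."""
    tm = tica_mod.estimate_tica(series, tica_lag)
    n = n_components or max(2, tm.kinetic_variance_dim(0.95))
    proj = [tica_mod.project(tm, s, n) for s in series]
    assign = msmcore.cluster_microstates(proj, k, seed=seed)
    dt = frame_interval if frame_interval is not None else series[0].frame_interval
    model = msmcore.estimate_msm(assign, msm_lag, frame_interval=dt)
    dec = msmcore.pcca(model, m)
    kin = msmcore.compute_kinetics(model, dec)
    return EnsembleResult(tm, proj, assign, model, dec, kin)


def match_states(recovered: np.ndarray, reference: np.ndarray, m: int) -> np.ndarray:
    """Permutation p with p[recovered_state] = reference_state by majority vote.

    Frames labelled −1 on either side are ignored.  Raises if the vote does
    not produce a bijection (recovered states fail to separate the
    reference partition).
    """
    recovered = np.asarray(recovered)
    reference = np.asarray(reference)
    ok = (recovered >= 0) & (reference >= 0)
    votes = np.zeros((m, m))
    np.add.at(votes, (recovered[ok], reference[ok]), 1)
    p = np.argmax(votes, axis=1)
    if len(set(p.tolist())) != m:
        raise ValueError(f"recovered states do not map 1:1 onto reference blocks (votes:\n{votes})")
    return p
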