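"""Shared fixtures: ground-truth chains and (expensive) pipeline runs.

The full-scale recovery runs (10 trajectories × 50 000 steps) are session-
scoped so the end-to-end, directionality and surface-consistency checks all
reuse the same two computations.
"""
from __future__ import annotations

import numpy as np
import pytest

from loopscape import synthdyn, workflow


TWO_STATE_T = np.array([[0.9, 0.1], [0.2, 0.8]])


@pytest.fixture(scope="session")
def fixture_chain():
    """Default 9-microstate, 3-block ground-truth chain."""
    return synthdyn.default_fixture_chain(seed=7)


@pytest.fixture(scope="session")
def block_sets(fixture_chain):
    b = fixture_chain.block_labels
    return [np.flatnonzero(b == i) for i in range(3)]


def run_recovery(chain, n_steps=50_000, n_traj=10, seed=7):
    """Full pipeline on a ground-truth chain; returns (paths, result)."""
    paths, series = synthdyn.make_hidden_chain(chain, n_steps, n_traj)
    result = workflow.analyze_ensemble(
        series, tica_lag=5, n_components=4, k=9, msm_lag=5, m=3, seed=seed)
    return paths, result


@pytest.fixture(scope="session")
def recovery_wt(fixture_chain):
    """Recovery run at the reference exchange rates."""
    return run_recovery(fixture_chain)


@pytest.fixture(scope="session")
def recovery_fast():
    """Recovery run with block-exchange couplings scaled by 2.5."""
    chain = synthdyn.default_fixture_chain(exchange_scale=2.5, seed=7)
    return chain, run_recovery(chain)


def match_to_blocks(chain, paths, result):
    """Permutation mapping recovered metastable states onto true blocks."""
    true_blocks = chain.block_labels[np.concatenate(paths)]
    return workflow.match_states(result.frame_metastable_labels(), true_blocks, 3)
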