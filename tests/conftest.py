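"""Shared fixtures: simulated cohorts under the default study conditions.

The 20-cell FS and non-FS cohorts (seed 1) and the 300-sweep baseline
connection are the reference conditions for the calibrated-recovery checks,
so they are simulated once per session and shared.
"""

from __future__ import annotations

import numpy as np
import pytest

from pairclamp import (
    FS_SYNAPSE,
    ModulationScenario,
    PairProtocol,
    build_feature_matrix,
    extract_features,
    measure_connection,
    simulate_paired_recording,
    simulate_step_cohort,
)

COHORT_N = 20
COHORT_SEED = 1

#: per-connection modulation categories transcribed from the published
#: cohorts (human FS, rat FS, human non-FS): counts of connections whose
#: EPSC amplitude significantly increased / decreased / did not change.
PRINTED_COHORTS = {
    "human_fs": {"increase": 6, "decrease": 2, "no_change": 3, "printed_increase_pct": 54},
    "rat_fs": {"increase": 5, "decrease": 1, "no_change": 8, "printed_increase_pct": 36},
    "human_nonfs": {"increase": 2, "decrease": 1, "no_change": 10, "printed_increase_pct": 15},
}


@pytest.fixture(scope="session")
def fs_cohort():
    recs, params = simulate_step_cohort(COHORT_N, "FS", seed=COHORT_SEED)
    return recs, params


@pytest.fixture(scope="session")
def nonfs_cohort():
    recs, params = simulate_step_cohort(COHORT_N, "nonFS", seed=COHORT_SEED + 1)
    return recs, params


@pytest.fixture(scope="session")
def fs_features(fs_cohort):
    recs, _ = fs_cohort
    return {r.cell_id: extract_features(r) for r in recs}


@pytest.fixture(scope="session")
def nonfs_features(nonfs_cohort):
    recs, _ = nonfs_cohort
    return {r.cell_id: extract_features(r) for r in recs}


@pytest.fixture(scope="session")
def cohort_matrix(fs_features, nonfs_features):
    """40-cell feature matrix plus ground-truth class labels."""
    feats = {**fs_features, **nonfs_features}
    truth = {cid: ("FS" if cid.startswith("FS") else "nonFS") for cid in feats}
    return build_feature_matrix(feats), truth


@pytest.fixture(scope="session")
def baseline_connection():
    """300 baseline sweeps of the default FS-targeting connection, seed 1."""
    protocol = PairProtocol(n_sweeps_baseline=300, n_sweeps_agonist=0)
    rec, truth = simulate_paired_recording(
        FS_SYNAPSE, ModulationScenario(), protocol, seed=COHORT_SEED
    )
    return rec, truth


@pytest.fixture(scope="session")
def baseline_events(baseline_connection):
    rec, _ = baseline_connection
    return measure_connection(rec)
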