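"""Shared fixtures: small noise-free synthetic sessions, computed once."""

from __future__ import annotations

import numpy as np
import pytest

from strideforge.pipeline import process_session
from strideforge.simulate import NoiseSpec, SyntheticScenario, simulate_session


@pytest.fixture(scope="session")
def clean_session():
    """Noise-free constant-speed (3 m/s) flat session, 30 s of running."""
    scenario = SyntheticScenario(
        duration=30.0, speed_profile=3.0, slope_profile=0.0,
        noise=NoiseSpec.silent(), seed=1,
    )
    recs, gnss, truth = simulate_session(scenario)
    return scenario, recs, gnss, truth


@pytest.fixture(scope="session")
def processed_clean(clean_session):
    scenario, recs, gnss, truth = clean_session
    return process_session(recs, gnss, scenario.subject)


@pytest.fixture(scope="session")
def sloped_session():
    """Noise-free 10 % uphill session at 3 m/s."""
    scenario = SyntheticScenario(
        duration=25.0, speed_profile=3.0, slope_profile=0.10,
        noise=NoiseSpec.silent(), seed=3,
    )
    recs, gnss, truth = simulate_session(scenario)
    return scenario, recs, gnss, truth


def match_events(detected_s: np.ndarray, truth_s: np.ndarray, tol_s: float):
    """Greedy 1-1 matching of detected events to ground-truth times.

    Returns (n_matched, n_detected, n_truth_in_range).  Truth events
    outside the detected coverage (first/last, where a detector cannot see
    a full cycle) are not counted as misses.
    """
    if detected_s.size == 0:
        return 0, 0, truth_s.size
    lo, hi = detected_s.min() - tol_s, detected_s.max() + tol_s
    truth_in = truth_s[(truth_s >= lo) & (truth_s <= hi)]
    used = np.zeros(truth_in.size, dtype=bool)
    matched = 0
    for d in detected_s:
        err = np.abs(truth_in - d)
        err[used] = np.inf
        j = int(np.argmin(err)) if truth_in.size else 0
        if truth_in.size and err[j] <= tol_s:
            used[j] = True
            matched += 1
    return matched, detected_s.size, truth_in.size
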