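import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from foragedive.segmentation import segment_dives
from foragedive.synthetic import SimConfig, simulate_trip


@pytest.fixture(scope="session")
def small_trip():
    """One simulated individual, 2 nights, standard noise/drift."""
    cfg = SimConfig(n_individuals=1, n_nights=2, seed=101)
    depth, accel, truth = simulate_trip(cfg, "ID001")
    return cfg, depth, accel, truth


@pytest.fixture(scope="session")
def clean_trip():
    """Noise- and drift-free trip: segmentation should be exact."""
    cfg = SimConfig(n_individuals=1, n_nights=1, seed=202,
                    depth_noise_sd=0.0, drift_amplitude_m=0.0)
    depth, accel, truth = simulate_trip(cfg, "ID001")
    return cfg, depth, accel, truth


def match_truth(dives: pd.DataFrame, truth_dives: pd.DataFrame,
                tol: float = 5.0) -> pd.DataFrame:
    """Align detected dives with generator truth by nearest start time."""
    a = dives.sort_values("start_s").copy()
    b = truth_dives.sort_values("start_s").copy()
    a["start_s"] = a["start_s"].astype(float)
    b["start_s"] = b["start_s"].astype(float)
    return pd.merge_asof(a, b, on="start_s", direction="nearest",
                         tolerance=float(tol), suffixes=("", "_t"))


@pytest.fixture(scope="session")
def clean_segmented(clean_trip):
    _, depth, _, truth = clean_trip
    dives = segment_dives(depth)
    return depth, dives, match_truth(dives, truth.dives)
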