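import numpy as np
import pytest

from polysweep.pipeline import _scan_replicate, _subset
from polysweep.scenario import simulate_null_replicate
from polysweep.sweepstats import ScanConfig


@pytest.fixture(scope="session")
def null_scan_suite():
    """Ten neutral desk replicates with all four statistic tracks each.

    This is the expensive shared resource of the suite (~1-2 min): it backs
    the threshold-calibration check, the standardization and score-uniformity
    properties, and provides realistic score tracks for smaller tests.
    """
    cfg = ScanConfig(seed=0)
    suite = []
    for r in range(10):
        hs = simulate_null_replicate(seed=1009 * (r + 1))
        tracks = _scan_replicate(hs, cfg, np.random.default_rng(r))
        suite.append({"tracks": tracks, "hs": hs})
    return suite


@pytest.fixture(scope="session")
def desk_dataset():
    """One full desk-profile scenario run (taxon schedule end to end)."""
    from polysweep.scenario import DemographyScript, run_wheat_scenario

    return run_wheat_scenario(DemographyScript.desk_profile(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
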