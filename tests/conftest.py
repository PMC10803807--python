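import pandas as pd
import pytest

from wisentpanel import panel_io as pio
from wisentpanel import simulate as sim


@pytest.fixture(scope="session")
def panel():
    return pio.default_panel()


@pytest.fixture(scope="session")
def small_truth():
    """A compact simulated population shared across read-only tests."""
    cfg = sim.SimConfig(seed=11, n_generations=3, offspring_per_pair=2.5)
    return sim.simulate_population(cfg)


@pytest.fixture(scope="session")
def small_observed(small_truth):
    rcs, log = sim.observe_replicates(small_truth)
    return rcs, log


def make_replicates(marker, calls, sample_id="S1", extra_markers=(), sample_type="noninvasive"):
    """ReplicateCalls with the given calls at one marker (NoCall elsewhere)."""
    cols = [marker.marker_id] + [m.marker_id for m in extra_markers]
    rows = {}
    for i, c in enumerate(calls, start=1):
        rows[f"rep{i}"] = [c] + [pio.NO_CALL] * len(extra_markers)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    return pio.ReplicateCalls(sample_id, df, sample_type=sample_type)
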