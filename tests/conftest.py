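import io
import textwrap

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import gazedpa as g

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


TINY_CSV = textwrap.dedent("""\
    participant,item,condition,trial,t_ms,aoi,correct
    p1,i1,negative,neg-i1,4100,factual,true
    p1,i1,negative,neg-i1,4150,illusory,true
    p1,i1,negative,neg-i1,4200,elsewhere,true
    """)


@pytest.fixture
def tiny_trialset() -> g.TrialSet:
    return g.read_trials(io.StringIO(TINY_CSV))


def make_trialset(rows, window_config=None) -> g.TrialSet:
    """Build a TrialSet from (participant, item, condition, trial, t_ms, aoi, correct) tuples."""
    df = pd.DataFrame(rows, columns=list(g.core.SAMPLE_COLUMNS))
    return g.TrialSet(samples=df, window_config=window_config or g.WindowConfig())


@pytest.fixture(scope="session")
def small_simulated():
    """One small simulated experiment shared by integration-level tests."""
    cfg = g.SimConfig(seed=42, n_participants=10, n_items=8)
    ts, gt = g.simulate_dataset(cfg)
    ts = g.assign_windows(ts)
    ts, _ = g.filter_correct(ts)
    binned = g.bin_fixations(ts)
    return cfg, ts, gt, binned
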