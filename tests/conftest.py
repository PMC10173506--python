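import pandas as pd
import pytest

from nichewebs import FeatureTable, ScenarioConfig, generate
from nichewebs.pipeline import RunConfig, run_all


@pytest.fixture
def tiny_table():
    """3 ASVs x 4 samples with hand-checkable counts."""
    counts = pd.DataFrame(
        [[2, 0, 1, 5], [2, 0, 3, 5], [0, 4, 0, 10]],
        index=["a1", "a2", "a3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return FeatureTable(counts)


@pytest.fixture(scope="session")
def default_community():
    """One default synthetic community, shared across read-only tests."""
    return generate(ScenarioConfig(), seed=1)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """A full pipeline run on the default scenario (reduced null reps to
    keep the suite quick; the null mean is stable well below 100 reps)."""
    out = tmp_path_factory.mktemp("run")
    cfg = RunConfig(scenario=ScenarioConfig(), seed=1, outdir=str(out), null_reps=15)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_all(cfg)
    return res
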