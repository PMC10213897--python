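import pytest

import chewsim as cs


@pytest.fixture(scope="session")
def model():
    """Calibrated default anatomy, right side working."""
    return cs.build_default("right")


@pytest.fixture(scope="session")
def all_runs(model):
    """Full pipeline results for the five catalogued foods at the default
    resolution (200 steps)."""
    results, summary = cs.run_foods(model, cs.fixtures.FOOD_IDS, n_steps=200)
    return results


@pytest.fixture(scope="session")
def chocolate_run(all_runs):
    return all_runs["d"]


@pytest.fixture(scope="session")
def summary_table(all_runs):
    import pandas as pd

    return pd.concat([r.summary for r in all_runs.values()], ignore_index=True)
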