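import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """A compact two-plot synthetic study shared across test modules."""
    from rametdemog import pipeline, synthetic

    truth = pipeline.demo_truth(dry=True)
    weather = synthetic.gen_weather("demo", 1950, 2009, truth, 11)
    records, truth_log = synthetic.gen_population(
        "demo", ["P1", "P2"], 1990, 2009, truth, weather, 12)
    return {"truth": truth, "weather": weather, "records": records,
            "truth_log": truth_log}


@pytest.fixture(scope="session")
def resolved_study(small_study):
    from rametdemog import census

    resolved = census.resolve_fates(small_study["records"])
    table = census.tabulate_transitions(resolved, "demo")
    return {"resolved": resolved, "table": table, **small_study}


def make_records(rows):
    """Census-record helper: rows of (plot, tag, year, stage)."""
    return pd.DataFrame(
        [("s", p, t, y, st, np.nan, False) for p, t, y, st in rows],
        columns=["site", "plot", "tag_id", "year", "stage",
                 "dist_cm", "cotyledons"])
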