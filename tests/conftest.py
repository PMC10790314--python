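import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from nodoscope import synth
from nodoscope.responders import build_feature_table, classify_responders
from nodoscope.transients import detect_and_featurize


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def class_tables():
    """Responder feature tables for the three calibrated agonist classes
    at their emulated sample sizes (n = 200 / 102 / 51), produced by the
    full trace -> detect -> featurize -> responder pipeline."""
    import pandas as pd

    tables = {}
    for ci, (name, preset) in enumerate(synth.CLASS_PRESETS.items()):
        traces, schedule, truth = synth.make_class_traces(preset, seed=123 + ci)
        events = detect_and_featurize(traces, schedule.fps)
        res = classify_responders(
            events, schedule.events[0], traces=traces, fps=schedule.fps
        )
        tab = build_feature_table(res)
        tab["event_label"] = name
        tables[name] = tab
    return tables


@pytest.fixture(scope="session")
def combined_table(class_tables):
    import pandas as pd

    return pd.concat(class_tables.values(), ignore_index=True)


@pytest.fixture(scope="session")
def movie_fixture():
    """Default synthetic movie with ground truth (10 neurons, jitter,
    breathing artifacts, diffuse background)."""
    movie, truth, schedule = synth.make_movie_fixture(seed=77, duration_s=60.0)
    return movie, truth, schedule
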