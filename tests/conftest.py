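import numpy as np
import pandas as pd
import pytest

from lagkit import SimScenario, generate_cell_traces
from lagkit.single_cell import analyze_traces


@pytest.fixture(scope="session")
def default_scenario():
    return SimScenario(seed=11)


@pytest.fixture(scope="session")
def cohort(default_scenario):
    """A 200-lineage synthetic switch cohort with ground truth."""
    traces, truth = generate_cell_traces(default_scenario, 200)
    return traces, truth


@pytest.fixture(scope="session")
def cohort_lags(default_scenario, cohort):
    """Estimated lag table for the cohort, merged with ground truth."""
    traces, truth = cohort
    table = analyze_traces(traces, default_scenario.switch_time,
                           focal_ids=truth["focal_cell_id"].tolist())
    return table.merge(truth, left_on="cell_id", right_on="focal_cell_id")


def make_trace(times, lengths, fluorescence, cell_id="c1", parent=None,
               divides_at_end=False):
    from lagkit.types import CellTrace
    times = np.asarray(times, float)
    flags = np.zeros(len(times), bool)
    flags[-1] = divides_at_end
    return CellTrace(cell_id=cell_id, parent_id=parent, experiment_id="e1",
                     condition="test", times=times,
                     lengths=np.asarray(lengths, float),
                     fluorescence=np.asarray(fluorescence, float),
                     division_flag=flags)
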