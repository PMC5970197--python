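import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import accesstf as a

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_scenario():
    return a.SimulationScenario(
        n_motifs=2000, n_genes=300, genome_length=3_000_000, seed=11
    )


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_scenario):
    """A simulated pseudo-genome written once per session."""
    out = tmp_path_factory.mktemp("fixture")
    result = a.simulate_genome_fixture(small_scenario, out)
    result["dir"] = out
    return result


def expression_from_grid(genes, values, expressed=None):
    """Build an ExpressionMatrix from a dict {(time, rep): column}."""
    cols = pd.MultiIndex.from_tuples(sorted(values), names=["time", "rep"])
    frame = pd.DataFrame(
        {tr: values[tr] for tr in cols}, index=pd.Index(genes, name="gene")
    )
    frame.columns = cols
    flags = pd.Series(True if expressed is None else expressed, index=frame.index)
    return a.ExpressionMatrix(frame, flags)
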