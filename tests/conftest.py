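import numpy as np
import pandas as pd
import pytest

from pathpanel.panel_core import (
    CountsExperiment, Panel, Probe, ProbeClass,
)
from pathpanel.synthetic import SimulationConfig


@pytest.fixture
def tiny_panel() -> Panel:
    """3 genes + 1 housekeeping + 2 positive + 1 negative control."""
    return Panel(probes=[
        Probe("GENEA", ProbeClass.ENDOGENOUS),
        Probe("GENEB", ProbeClass.ENDOGENOUS),
        Probe("GENEC", ProbeClass.ENDOGENOUS),
        Probe("ACTB", ProbeClass.HOUSEKEEPING),
        Probe("POS_A", ProbeClass.POSITIVE_CTRL, 128.0),
        Probe("POS_B", ProbeClass.POSITIVE_CTRL, 32.0),
        Probe("NEG_A", ProbeClass.NEGATIVE_CTRL),
    ], name="tiny")


def make_experiment(panel: Panel, counts: np.ndarray,
                    groups: list[str] | None = None) -> CountsExperiment:
    n = counts.shape[0]
    ids = [f"L{i+1}" for i in range(n)]
    lanes = pd.DataFrame({
        "sample_id": ids,
        "group": groups if groups is not None else ["g"] * n,
    })
    df = pd.DataFrame(np.asarray(counts, dtype=np.int64),
                      index=pd.Index(ids, name="sample_id"),
                      columns=panel.probe_names)
    return CountsExperiment(panel=panel, lanes=lanes, counts=df)


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(n_endogenous=30, n_housekeeping=4,
                            neg_ctrl_count=4, seed=11)
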