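import numpy as np
import pytest

from cipasim import biomarkers as bm
from cipasim import cardiac_sim as cs
from cipasim import pipeline as pl


@pytest.fixture(scope="session")
def cell_config():
    return cs.CellModelConfig()


@pytest.fixture(scope="session")
def control_bundle(cell_config):
    """Drug-free reference: steady state, capture amplitude, a short paced run
    from the steady state, the representative beat and its features."""
    state, amp = cs.steady_state_control(cell_config, cs.PacingProtocol())
    proto = cs.desk_protocol()
    traces = cs.run_paced(cell_config, cs.NO_BLOCK, proto,
                          initial_state=state, stim_amplitude=amp)
    idx = bm.select_ap(traces)
    beat = traces[idx]
    control_auc = (beat.auc_inal, beat.auc_ical)
    features = bm.compute_features(beat, control_auc, proto.bcl)
    return {
        "config": cell_config,
        "state": state,
        "amp": amp,
        "protocol": proto,
        "traces": traces,
        "beat": beat,
        "control_auc": control_auc,
        "features": features,
    }


def single_channel_block(channel: str, factor: float) -> cs.DrugBlockVector:
    factors = {c: 1.0 for c in cs.CHANNELS}
    factors[channel] = factor
    return cs.DrugBlockVector(factors)


@pytest.fixture(scope="session")
def desk_run(tmp_path_factory):
    """One full desk-scale synthetic-panel pipeline run (12 train + 16 test
    drugs), shared by the end-to-end tests."""
    out_dir = tmp_path_factory.mktemp("desk_run")
    config = pl.RunConfig(out_dir=str(out_dir), scale="desk", master_seed=1)
    return config, pl.run_all(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
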