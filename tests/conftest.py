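import numpy as np
import pytest

import microtunnel as mt


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def rendered_trace():
    """100 well-separated 10-S.D. spikes on a 25 kHz noise trace, with truth."""
    g = np.random.default_rng(5)
    times = np.sort(g.uniform(0.05, 4.95, 200))
    times = times[np.concatenate([[True], np.diff(times) > 0.004])][:100]
    trace = mt.render_voltage_trace(times, amplitude=10.0, noise_sd=1e-5,
                                    duration=5.0, seed=6)
    return times, trace


@pytest.fixture(scope="session")
def valid_ff_axon():
    return mt.GroundTruthAxon(
        axon_id="ax_ff", region_pair=("EC", "DG"), direction="feed_forward",
        conduction_delay=0.0006, detect_prob=0.9, jitter_sd=5e-5,
    )


@pytest.fixture(scope="session")
def five_tunnel_dataset():
    layout = mt.five_tunnel_layout()
    return layout, mt.generate_dataset(layout, duration=60.0, seed=4)
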