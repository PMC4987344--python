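import numpy as np
import pytest

from apcphys import features, synth
from apcphys.recordings import subthreshold_protocol, suprathreshold_protocol


@pytest.fixture(scope="session")
def fs_params():
    return synth.make_preset("FS-SST-tonic")


@pytest.fixture(scope="session")
def fs_sweeps(fs_params):
    """Sub- and suprathreshold sweep sets of the tonic FS-SST preset cell."""
    sub = synth.simulate_membrane(fs_params, subthreshold_protocol(), seed=11)
    sup = synth.simulate_membrane(fs_params, suprathreshold_protocol(), seed=12)
    return sub, sup


@pytest.fixture(scope="session")
def fs_features(fs_sweeps):
    return features.extract_features(*fs_sweeps)


def make_quiet_params(**overrides):
    """A noiseless passive membrane with convenient defaults for oracles."""
    defaults = dict(
        membrane_capacitance=100.0,
        leak_conductance=10.0,
        resting_potential=-65.0,
        spike_threshold=-25.0,
        reset_potential=-67.0,
        refractory_period=2.0,
        sag_conductance=0.0,
        adaptation_increment=0.0,
        stutter_amplitude=0.0,
        noise_sd=0.0,
        spike_shape_halfwidth=0.5,
    )
    defaults.update(overrides)
    return synth.NeuronModelParams(**defaults)


@pytest.fixture(scope="session")
def quiet_params():
    return make_quiet_params()


@pytest.fixture(scope="session")
def target_cohort_frame():
    """Feature table built from drawn targets (fast clustering substrate)."""
    import pandas as pd

    rng = np.random.default_rng(42)
    rows = {}
    for preset, line, n in [
        ("FS-SST-tonic", "FS-SST", 11),
        ("FS-SST-stutter", "FS-SST", 3),
        ("FS-PV-tonic", "FS-PV", 3),
        ("FS-PV-stutter", "FS-PV", 8),
    ]:
        spec = synth._spec_for(preset)
        for i in range(n):
            t = synth._draw_targets(spec, rng, 1.0)
            rows[f"{line}-{len(rows)}"] = t | {"group": line, "benchmark": False}
    return pd.DataFrame.from_dict(rows, orient="index")
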