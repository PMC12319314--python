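import numpy as np
import pytest

import chlorotraits as ct


@pytest.fixture
def noiseless_design():
    return ct.AssayDesign(count_noise=False, titer_cv=0.0)


def make_dataset(traits, design, rng=None, growth_rate=None):
    """Assemble a full AssayDataset for one strain."""
    ads = ct.simulate_adsorption_assay(traits, design, rng)
    onestep, depol = ct.simulate_one_step_assay(traits, design, rng)
    decay = ct.simulate_decay_assay(traits, design, rng)
    growth = None
    if growth_rate is not None:
        growth = ct.simulate_growth_assay(traits, design, growth_rate, rng)
    return ct.AssayDataset(traits.strain_id, ads, depol, onestep, decay, growth)
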