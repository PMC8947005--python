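import numpy as np
import pytest

import mlshift as m


@pytest.fixture(scope="session")
def phantom_scan():
    """One rendered phantom with a 7.5 mm midline shift."""
    spec = m.PhantomSpec(patient_id="P0", scan_id="P0_S0", true_mls_mm=7.5, seed=42)
    return m.generate_phantom(spec)


@pytest.fixture(scope="session")
def flat_scan():
    """A phantom with zero shift."""
    spec = m.PhantomSpec(patient_id="P1", scan_id="P1_S0", true_mls_mm=0.0, seed=43)
    return m.generate_phantom(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """A small rendered stratified cohort (12 patients, one scan each)."""
    return m.build_dataset(12, "uniform:0,15", seed=3, type_mix={"ICH": 1.0})


@pytest.fixture(scope="session")
def trained_tiny_model(small_cohort):
    """A briefly trained tiny detector for contract tests (not accuracy)."""
    train = m.samples_from_scans(small_cohort["train"])
    valid = m.samples_from_scans(small_cohort["valid"] + small_cohort["test"])
    cfg = m.DetectorConfig(epochs=6, lr_initial=1e-3, seed=7,
                           tiny_channels=(16, 32, 32))
    model, log = m.train_detector(train, valid, cfg)
    return model, log, cfg
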