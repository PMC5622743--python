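import pytest

import ssbcea


@pytest.fixture(scope="session")
def bundle():
    """Calibrated synthetic input bundle (fixed seed)."""
    return ssbcea.generate_bundle(1, calibrate_to_published=True)


@pytest.fixture(scope="session")
def reference(bundle):
    """Baseline (no-intervention) life-table run for the session bundle."""
    return ssbcea.run_lifetable(bundle.population, bundle.diseases)
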