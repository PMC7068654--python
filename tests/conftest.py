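import pytest

from caflim import workflows


@pytest.fixture(scope="session")
def calibration():
    """Synthetic cuvette calibration + decay-constant correction, shared by
    the pipeline tests (seeded; ~1 s to build)."""
    curve, correction, diagnostics = workflows.build_synthetic_calibration(
        seed=1, photons_per_level=1e6)
    return curve, correction, diagnostics
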