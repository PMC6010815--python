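import numpy as np
import pytest

import isobarrier as ib


@pytest.fixture(scope="session")
def reference_bundle():
    """Pipeline output for the bundled white/pink reference-study inputs."""
    return ib.run_pipeline(ib.reference_study_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(20160724)
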