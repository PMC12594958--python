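import warnings

import pytest


@pytest.fixture(autouse=True)
def _quiet_skimage():
    # morphology deprecation chatter from skimage 0.26 is irrelevant here
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=FutureWarning)
        yield
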