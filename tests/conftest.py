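import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def depth_file(tmp_path):
    """Write records as a 3-column depth table and return the path."""

    def _write(records, name="depth.tsv"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for scaffold, pos, depth in records:
                fh.write(f"{scaffold}\t{pos}\t{depth}\n")
        return path

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)
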