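import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_background(rng, length, forbid_units=("AC",)):
    """Random sequence free of >=3-copy tandems (so planted repeats stand out)."""
    bases = np.array(list("ACGT"))
    while True:
        seq = "".join(rng.choice(bases, size=length))
        if not has_tandem(seq):
            return seq


def has_tandem(seq, max_unit=6, min_reps=3):
    for k in range(1, max_unit + 1):
        for i in range(len(seq) - k * min_reps + 1):
            if seq[i : i + k] * min_reps == seq[i : i + k * min_reps]:
                return True
    return False
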