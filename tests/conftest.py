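import numpy as np
import pytest

from consilience.metrics import TruthSet


@pytest.fixture
def small_truth():
    """Hand-enumerable truth set: 3 true, 4 false items."""
    return TruthSet(
        true_set=frozenset("abc"),
        false_set=frozenset("defg"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20140310)


def pairs_auc(active, decoy, better="lower"):
    """All-pairs AUC oracle: wins count 1, ties 1/2, losses 0."""
    sgn = -1.0 if better == "lower" else 1.0
    total = 0.0
    for a in active:
        for d in decoy:
            if sgn * a > sgn * d:
                total += 1.0
            elif a == d:
                total += 0.5
    return total / (len(active) * len(decoy))
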