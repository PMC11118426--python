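import numpy as np
import pytest

from seqgauge import Alphabet, model_preset

AB = Alphabet("AB")
ABC = Alphabet("ABC")
ABCD = Alphabet("ABCD")


@pytest.fixture
def rng():
    return np.random.default_rng(20240512)


def small_preset_suite():
    """Small models used by certificate-style checks across the suite.

    Covers alpha in {2,3,4} and L in {2,3} for the structured presets, plus
    the all-order model at (alpha=3, L=3).
    """
    specs = []
    for alphabet in (AB, ABC, ABCD):
        for L in (2, 3):
            for name in ("constant", "additive", "pairwise", "nearest-neighbor"):
                specs.append(model_preset(name, alphabet, L))
    specs.append(model_preset("all-order", ABC, 3))
    return specs


@pytest.fixture(params=small_preset_suite(), ids=lambda s: f"{s.alphabet}-L{s.L}-J{s.J}")
def suite_spec(request):
    return request.param
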