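import numpy as np
import pytest

from chromix import EU, HET, GenomeSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def four_equal_spec():
    return GenomeSpec([f"chain{i}" for i in range(4)], [200] * 4)


def make_block_spec(n_chains=4, length=200, seed=10):
    """Reduced block-copolymer spec with ~30% HET and LADs on EU blocks."""
    cls_all, lad_all = [], []
    for c in range(n_chains):
        r = np.random.default_rng(seed + c)
        cls = np.zeros(length, np.int8)
        lad = np.zeros(length, bool)
        pos, state = 0, EU
        while pos < length:
            ln = max(5, int(r.exponential(30 if state == EU else 13)))
            cls[pos:pos + ln] = state
            pos += ln
            state = HET if state == EU else EU
        pos, on = 0, True
        while pos < length:
            ln = max(5, int(r.exponential(20)))
            if on:
                lad[pos:pos + ln] = True
            pos += ln
            on = not on
        lad &= cls == EU
        cls_all.append(cls)
        lad_all.append(lad)
    return GenomeSpec(
        [f"chain{i}" for i in range(n_chains)], [length] * n_chains,
        bead_class=np.concatenate(cls_all), lad_flag=np.concatenate(lad_all),
    )
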