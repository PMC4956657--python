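import numpy as np
import pytest

from mircms.sequence_io import SequenceRecord, SequenceTag, reverse_complement

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=n)])


def make_hairpin(rng, mature_len=21, loop_len=8, arm_mismatches=0, tail=2):
    """Canonical cassette: mature + loop + (near-)revcomp arm + tail.

    Returns (cassette, mature, planted star sequence).
    """
    mature = random_seq(rng, mature_len)
    loop = random_seq(rng, loop_len)
    arm = list(reverse_complement(mature))
    if arm_mismatches:
        pos = rng.choice(np.arange(2, mature_len - 2), size=arm_mismatches,
                         replace=False)
        for p in pos:
            arm[p] = rng.choice([b for b in BASES if b != arm[p]])
    cassette = mature + loop + "".join(arm) + random_seq(rng, tail)
    star = cassette[mature_len + loop_len + 2: 2 * mature_len + loop_len + 2]
    return cassette, mature, star


@pytest.fixture
def rng():
    return np.random.default_rng(20160722)


@pytest.fixture
def tag_factory():
    def make(seq, wa=1, wb=0, tag_id=""):
        return SequenceTag(seq, {"WA": wa, "WB": wb}, id=tag_id)
    return make
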