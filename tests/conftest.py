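import numpy as np
import pytest

from ciliaevol import Transcript


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_transcript(tid, seq, taxon="sp1", **kw):
    return Transcript(id=tid, seq=seq, taxon=taxon, **kw)


def random_seq(rng, n, alphabet="ACGT"):
    return "".join(alphabet[k] for k in rng.integers(0, len(alphabet), n))
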