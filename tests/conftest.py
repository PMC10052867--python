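import numpy as np
import pytest
from hypothesis import settings

from modfoot.io import GenomicBin, Molecule

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230329)


@pytest.fixture
def make_molecule():
    """Factory for molecules with explicit positions and probabilities."""

    def _make(pos, probs, read_id="r1", chrom="chr1", strand="+", meth=None):
        n = len(pos)
        return Molecule(
            read_id=read_id,
            chrom=chrom,
            pos=np.asarray(pos),
            strand=np.full(n, strand, dtype="U1"),
            prob=np.asarray(probs, dtype=float),
            meth=None if meth is None else np.asarray(meth, dtype=bool),
        )

    return _make


@pytest.fixture
def region():
    def _region(chrom="chr1", start=0, end=1000, strand=None):
        return GenomicBin(chrom, start, end, strand=strand)

    return _region
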