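import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from snvhmm.pileup_io import SiteObservation


@pytest.fixture
def rng():
    return np.random.default_rng(20130715)


def make_obs(match_flags, r=None, q=None, chrom="chr1", pos=1, ref="A", alt="T"):
    """Hand-build a SiteObservation from explicit match flags."""
    match = np.asarray(match_flags, dtype=bool)
    L = len(match)
    r = np.full(L, 0.99) if r is None else np.asarray(r, dtype=float)
    q = np.full(L, 0.99) if q is None else np.asarray(q, dtype=float)
    return SiteObservation(
        chrom=chrom,
        pos=pos,
        ref_base=ref,
        alt_base=alt if (~match).any() else None,
        L=L,
        P=int(match.sum()),
        r=r,
        q=q,
        match=match,
    )


@pytest.fixture
def tiny_pileup(tmp_path):
    """Three covered sites on one chromosome, 7-column dialect."""
    text = (
        "chr1\t10\tA\t3\t..T\tIII\t]]]\n"
        "chr1\t11\tC\t2\t..\tII\t]]\n"
        "chr1\t12\tG\t4\tAAA.\tIIII\t]]]]\n"
    )
    p = tmp_path / "tiny.pileup"
    p.write_text(text)
    return p
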