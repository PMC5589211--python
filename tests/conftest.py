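import numpy as np
import pandas as pd
import pytest

from neoscape.variants import MutationRecord


@pytest.fixture
def five_samples():
    return [f"S{i:02d}" for i in range(5)]


@pytest.fixture
def small_catalog(five_samples):
    """Hand-built catalog: 1 truncal missense, 1 shared missense,
    1 private missense, 1 private silent, 1 truncal nonsense."""

    def rec(mid, context, alt, mclass, present, gene="G1", expressed=True):
        return MutationRecord(
            id=mid, chrom="chr1", pos=100, ref_base=context[1], alt_base=alt,
            context=context, gene=gene, protein_change="A10V", mclass=mclass,
            expressed=expressed, present_in=frozenset(present),
        )

    return [
        rec("m_truncal", "ACA", "T", "missense", five_samples),
        rec("m_shared", "TCG", "A", "missense", five_samples[:2], gene="G2"),
        rec("m_private", "GGT", "C", "missense", [five_samples[3]], gene="G3"),
        rec("m_silent", "AAA", "C", "silent", [five_samples[0]], gene="G4"),
        rec("m_nonsense", "CGA", "A", "nonsense", five_samples, gene="G5"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
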