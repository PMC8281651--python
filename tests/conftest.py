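import numpy as np
import pandas as pd
import pytest

from mesohet.clonality import VariantObservation
from mesohet.expression import ExpressionPair
from mesohet.methylation import MethylationPair


def make_obs(alt, depth, sample="S1", pos=100, **kw):
    return VariantObservation(
        sample_id=sample, chrom="chr1", pos=pos, ref="A", alt="T",
        alt_count=alt, depth=depth, **kw,
    )


@pytest.fixture
def expression_pair_factory():
    """Build an ExpressionPair from explicit FPKM/VST columns."""

    def _make(fpkm_a, fpkm_b, vst_a, vst_b, genes=None):
        n = len(fpkm_a)
        genes = genes or [f"g{i}" for i in range(n)]
        fpkm = pd.DataFrame({"A": fpkm_a, "B": fpkm_b}, index=genes)
        vst = pd.DataFrame({"A": vst_a, "B": vst_b}, index=genes)
        return ExpressionPair(fpkm=fpkm, vst=vst)

    return _make


@pytest.fixture
def methylation_pair_factory():
    def _make(beta_a, beta_b, p_a=None, p_b=None, annotation=None):
        n = len(beta_a)
        cpgs = [f"cg{i}" for i in range(n)]
        p_a = p_a if p_a is not None else [0.01] * n
        p_b = p_b if p_b is not None else [0.01] * n
        return MethylationPair(
            betas=pd.DataFrame({"A": beta_a, "B": beta_b}, index=cpgs),
            detection_p=pd.DataFrame({"A": p_a, "B": p_b}, index=cpgs),
            annotation=annotation or {c: None for c in cpgs},
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
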