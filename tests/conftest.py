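from __future__ import annotations

import numpy as np
import pytest

from twosample_mr import HarmonizedInstrument, VariantAssociation


def make_instruments(bgp, sgp, bgd, sgd, rsids=None):
    """Build a harmonized instrument list from plain arrays."""
    n = len(bgp)
    rsids = rsids or [f"rs{k}" for k in range(n)]
    alleles = [("A", "G"), ("C", "T"), ("G", "C"), ("T", "A")]
    return [
        HarmonizedInstrument(
            rsid=rsids[k],
            effect_allele=alleles[k % 4][0],
            other_allele=alleles[k % 4][1],
            beta_gp=float(bgp[k]),
            se_gp=float(sgp[k]),
            beta_gd=float(bgd[k]),
            se_gd=float(sgd[k]),
        )
        for k in range(n)
    ]


def random_instruments(rng, n=10, theta=0.3):
    """Random harmonized set with effects consistent with a causal theta."""
    bgp = rng.uniform(0.01, 0.08, n)
    sgp = rng.uniform(0.001, 0.005, n)
    sgd = rng.uniform(0.01, 0.05, n)
    bgd = theta * bgp + rng.normal(0, sgd)
    return make_instruments(bgp, sgp, bgd, sgd)


@pytest.fixture
def rng():
    return np.random.default_rng(20160804)


@pytest.fixture
def toy_variant():
    def build(rsid="rs1", ea="A", oa="G", beta=0.05, se=0.01, **kw):
        return VariantAssociation(
            rsid=rsid, effect_allele=ea, other_allele=oa, beta=beta, se=se, **kw
        )

    return build
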