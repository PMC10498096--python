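import numpy as np
import pytest

from trumpetplot.model import SumstatsTable, VariantAssociation


def make_record(**kw) -> VariantAssociation:
    base = dict(
        variant_id="rs1",
        chrom="1",
        pos_bp=1000,
        effect_allele="A",
        other_allele="G",
        eaf=0.3,
        beta=0.1,
        se=0.02,
        pvalue=1e-6,
    )
    base.update(kw)
    return VariantAssociation(**base)


def make_table(records, **kw) -> SumstatsTable:
    meta = dict(trait_name="toy", study_n=10_000, trait_model="quantitative")
    meta.update(kw)
    return SumstatsTable(records=list(records), **meta)


def random_records(rng: np.random.Generator, n: int) -> list[VariantAssociation]:
    """n valid records with frequencies spanning the whole spectrum."""
    eaf = 10.0 ** rng.uniform(-4.5, -1e-9, size=n)
    eaf = np.clip(eaf, 1e-5, 1.0 - 1e-5)
    beta = rng.normal(0, 0.3, size=n)
    se = 10.0 ** rng.uniform(-3, -0.5, size=n)
    z2 = (beta / se) ** 2
    pv = np.clip(np.exp(-z2 / 2), 1e-300, 1.0)
    return [
        make_record(
            variant_id=f"rs{i}",
            pos_bp=1000 + i,
            eaf=float(eaf[i]),
            beta=float(beta[i]),
            se=float(se[i]),
            pvalue=float(pv[i]),
        )
        for i in range(n)
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def toy_table() -> SumstatsTable:
    return make_table(
        [
            make_record(variant_id="rs1", pos_bp=100, eaf=0.7, beta=0.2),
            make_record(variant_id="rs2", pos_bp=200, eaf=0.3, beta=-0.1),
            make_record(variant_id="rs3", pos_bp=300, eaf=0.5, beta=0.05),
        ]
    )
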