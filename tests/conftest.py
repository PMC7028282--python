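import pytest

from rsbr import (
    FactorPools,
    HandprintNormalizationSet,
    NormalizationSet,
    WeightingSet,
    builtin_case,
    derived_reference_factors,
)


@pytest.fixture(scope="session")
def sth_case():
    return builtin_case("sth_vietnam")


@pytest.fixture(scope="session")
def schizo_case():
    return builtin_case("schizophrenia_belgium")


@pytest.fixture(scope="session")
def sth_reference():
    """(NF, handprint NF, WF) derived from the published STH rows."""
    return derived_reference_factors("sth_vietnam")


@pytest.fixture(scope="session")
def schizo_reference():
    return derived_reference_factors("schizophrenia_belgium")


@pytest.fixture
def singleton_pools(sth_reference):
    """Pools collapsed to the single reference combination."""
    nf, hnf, wf = sth_reference
    return FactorPools(
        footprint_nfs=[nf],
        handprint_nfs=[hnf],
        wf_main_sets={wf.main_set: [wf]},
        handprint_variants=("base",),
    )


def make_pools(n_fp=2, n_hp=3, wf_shape=(5,), variants=("base",), seed=7):
    """Small hand-built pools with distinct, well-separated factor values."""
    fp = [
        NormalizationSet(
            id=f"nf{i}",
            human_health=1e8 * (i + 1),
            ecosystems=5e6 * (i + 2),
            resources=1e12 * (i + 1.5),
        )
        for i in range(n_fp)
    ]
    hp = [
        HandprintNormalizationSet(id=f"hnf{i}", factor=2.5e9 * (i + 1))
        for i in range(n_hp)
    ]
    mains = {}
    k = 0
    for m, count in enumerate(wf_shape):
        subsets = []
        for _ in range(count):
            hh = 0.2 + 0.05 * (k % 7)
            eco = (1 - hh) * 0.6
            subsets.append(
                WeightingSet(
                    id=f"wf{k}",
                    main_set=f"main{m}",
                    human_health=hh,
                    ecosystems=eco,
                    resources=1 - hh - eco,
                )
            )
            k += 1
        mains[f"main{m}"] = subsets
    return FactorPools(
        footprint_nfs=fp,
        handprint_nfs=hp,
        wf_main_sets=mains,
        handprint_variants=variants,
    )


@pytest.fixture
def small_pools():
    return make_pools()
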