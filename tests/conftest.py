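import numpy as np
import pytest

from titinmech import annotation as ann_mod
from titinmech import simulate
from titinmech.mechanics import SigmoidParams


@pytest.fixture(scope="session")
def titin_annotation():
    return ann_mod.synthetic_titin_annotation()


@pytest.fixture(scope="session")
def wt_probs(titin_annotation):
    return ann_mod.isoform_inclusion_probs(titin_annotation, "WT")


@pytest.fixture(scope="session")
def mutant_probs(titin_annotation):
    return ann_mod.isoform_inclusion_probs(titin_annotation, "Delta112-158")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ff_params():
    return SigmoidParams(p0_min=2.0, p0_max=100.0, f_half=60.0, k=12.0)


def make_samples(probs, annotation, n, depth, genotype, seed0):
    return [
        simulate.simulate_exon_reads(
            simulate.IsoformSpec(probs, depth=depth, seed=seed0 + i),
            annotation,
            sample_id=f"{genotype}-{i}",
            genotype=genotype,
        )
        for i in range(n)
    ]
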