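import numpy as np
import pytest
from hypothesis import settings

from famvar.cohort import CohortVariantSet, Member, Variant

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_variant(vid, carriers, gene=None, pop_af=0.001, wt="T", mut="M",
                 position=100, accession=""):
    return Variant(variant_id=vid, gene=gene or f"GENE_{vid}",
                   protein_accession=accession or f"P_{vid}",
                   wt_aa=wt, position=position, mut_aa=mut, pop_af=pop_af,
                   carriers=set(carriers))


@pytest.fixture
def members():
    """Three families: A (2 affected + 1 unaffected), B (3 affected),
    C (single affected patient)."""
    return [
        Member("A1", "famA", True), Member("A2", "famA", True),
        Member("U1", "famA", False),
        Member("B1", "famB", True), Member("B2", "famB", True),
        Member("B3", "famB", True),
        Member("C1", "famC", True),
    ]


@pytest.fixture
def cohort_factory(members):
    def build(variants):
        return CohortVariantSet(variants=list(variants), members=list(members))
    return build


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
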