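import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from clonemark.catalog import synthetic_signature_catalog
from clonemark.io_formats import VariantRecord

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return synthetic_signature_catalog()


def make_snv(
    chrom="1",
    pos=1000,
    ref="C",
    alt="T",
    t_depth=50,
    t_alt=10,
    n_depth=30,
    n_alt=0,
    sample_id="S_T",
    patient_id="P",
    gene="GENE1",
    effect="nonsynonymous",
    context=None,
):
    if context is None:
        context = f"A{ref}A"
    return VariantRecord(
        patient_id=patient_id,
        sample_id=sample_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        variant_type="SNV",
        gene=gene,
        effect=effect,
        t_depth=t_depth,
        t_alt=t_alt,
        n_depth=n_depth,
        n_alt=n_alt,
        context=context,
    )


def make_indel(
    chrom="1",
    pos=2000,
    ref="A",
    alt="AT",
    t_depth=20,
    t_alt=5,
    n_depth=20,
    n_alt=0,
    sample_id="S_T",
    patient_id="P",
    gene="GENE2",
    effect="nonsynonymous",
):
    return VariantRecord(
        patient_id=patient_id,
        sample_id=sample_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        variant_type="indel",
        gene=gene,
        effect=effect,
        t_depth=t_depth,
        t_alt=t_alt,
        n_depth=n_depth,
        n_alt=n_alt,
        context=None,
    )


def random_snv(rng: np.random.Generator, **overrides):
    """Random record biased toward the filter's decision boundaries."""
    t_depth = int(rng.choice([0, 5, 9, 10, 11, 20, 30, 50, 100]))
    n_depth = int(rng.choice([0, 5, 9, 10, 11, 20, 30, 50]))
    t_alt = int(rng.integers(0, t_depth + 1)) if t_depth else 0
    if t_depth >= 30 and rng.random() < 0.2:
        t_alt = t_depth // 10  # VAF exactly 0.10
    n_alt = int(rng.integers(0, min(n_depth, 3) + 1)) if n_depth else 0
    kwargs = dict(
        pos=int(rng.integers(1, 10_000_000)),
        t_depth=t_depth,
        t_alt=t_alt,
        n_depth=n_depth,
        n_alt=n_alt,
    )
    kwargs.update(overrides)
    return make_snv(**kwargs)
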