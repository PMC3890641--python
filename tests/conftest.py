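from __future__ import annotations

import pytest

from genofinish import synthdata as sd


def small_spec(length=10_000, genes=10, gene_len=800, spacer=200, **kw):
    return sd.GenomeSpec(
        chromosome_length=length,
        n_genes=genes,
        mean_gene_length=gene_len,
        mean_intergenic_length=spacer,
        **kw,
    )


@pytest.fixture(scope="session")
def ref_genome():
    """A 10 kb reference with poly-A tracts, shared across the session."""
    return sd.simulate_reference(small_spec(), seed=42)


@pytest.fixture(scope="session")
def strain_with_truth(ref_genome):
    return sd.mutate_strain(ref_genome, 20, 0.5, 3, seed=7, strain_id="S1")


@pytest.fixture()
def spec_factory():
    return small_spec
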