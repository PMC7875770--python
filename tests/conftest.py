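import numpy as np
import pandas as pd
import pytest

from varscape import simulate, variant_io


@pytest.fixture(scope="session")
def geno_table():
    """Small group-structured genotype table plus metadata."""
    return simulate.simulate_genotype_matrix(
        simulate.GenotypeConfig(n_sites=200, groups={"A": 5, "B": 5}),
        seed=11,
    )


@pytest.fixture(scope="session")
def vcf_path(tmp_path_factory, geno_table):
    table, _ = geno_table
    path = tmp_path_factory.mktemp("vcf") / "fixture.vcf"
    simulate.write_vcf(table, path)
    return path


def manual_table(carriage, pos=None, chrom="chr1", ref=None, alt=None,
                 samples=None, **kw):
    """VariantTable straight from a carriage matrix (rows = variants)."""
    carriage = np.asarray(carriage, dtype=np.int8)
    n, m = carriage.shape
    return variant_io.table_from_arrays(
        chrom,
        np.arange(100, 100 + 10 * n, 10) if pos is None else pos,
        ["A"] * n if ref is None else ref,
        ["C"] * n if alt is None else alt,
        carriage,
        [f"s{i}" for i in range(m)] if samples is None else samples,
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
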