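import pytest

from familyscan.domain_scan import load_packaged_pssm
from familyscan.synthetic_data import generate_genome


@pytest.fixture(scope="session")
def pssm():
    return load_packaged_pssm()


@pytest.fixture(scope="session")
def small_genome():
    """30-gene genome (4x 1R, 8x R2R3, 2x 3R, 16 decoys) with planted truth."""
    return generate_genome(n_chrom=3, n_genes=30,
                           repeat_spec={"1R": 4, "R2R3": 8, "3R": 2}, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_genome, tmp_path_factory):
    """The same genome written out as FASTA/GFF3/truth files."""
    outdir = tmp_path_factory.mktemp("bundle")
    return small_genome.write(outdir)
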