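import pytest

import nanochromprof as ncp
from nanochromprof.synth import SyntheticSpec, generate


@pytest.fixture(scope="session")
def small_genome():
    """A small default-spec synthetic genome (error-free)."""
    return generate(SyntheticSpec(seed=11, n_contigs=120))


@pytest.fixture(scope="session")
def small_genome_files(small_genome, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim")
    paths = small_genome.write(outdir)
    return paths


@pytest.fixture(scope="session")
def reparsed(small_genome_files):
    """The small genome re-read from its emitted FASTA/GFF3."""
    contigs = ncp.read_fasta(small_genome_files["fasta"])
    genes = ncp.read_gff3(small_genome_files["gff3"], contigs)
    return contigs, genes
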