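import numpy as np
import pandas as pd
import pytest

from editsweep.io_formats import Genome
from editsweep.sim import (
    SimulationParams,
    generate_population,
    generate_reference,
    generate_rna_pileups,
)

# small, fast study used by most unit tests
SMALL = SimulationParams(
    genome_length=200_000,
    n_chromosomes=2,
    n_genes=12,
    n_edit_sites=400,
    n_lines=50,
    seed=7,
)

# the default study conditions (used by the acceptance suite)
DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def small_ref():
    return generate_reference(SMALL)


@pytest.fixture(scope="session")
def small_pop(small_ref):
    return generate_population(small_ref, SMALL)


@pytest.fixture(scope="session")
def small_pileups(small_ref, small_pop):
    return generate_rna_pileups(small_ref, small_pop.truth, 6, SMALL)


@pytest.fixture(scope="session")
def default_bundle():
    """Full-scale synthetic study at the default conditions, one per session."""
    params = SimulationParams(seed=DEFAULT_SEED)
    ref = generate_reference(params)
    pop = generate_population(ref, params)
    return params, ref, pop


@pytest.fixture
def toy_genome():
    return Genome({"chr1": "ACGTACGTAACCGGTTAGCT", "chr2": "TTTTAAAACCCCGGGG"})


@pytest.fixture
def two_gene_fixture():
    """Hand-built two-gene genome: one + strand gene, one − strand gene whose
    coding sequence equals the + gene's (reverse-complemented on the genome)."""
    # + gene CDS: ATG AAA CAT TAA  (M K H *)
    plus_cds = "ATGAAACATTAA"
    minus_cds_genomic = "TTAATGTTTCAT"  # revcomp of plus_cds
    seq = "CC" + plus_cds + "GG" + minus_cds_genomic + "AA"
    genome = Genome({"chrT": seq})
    genes = pd.DataFrame(
        {
            "gene_id": ["gp", "gm"],
            "chrom": ["chrT", "chrT"],
            "start": [2, 16],
            "end": [14, 28],
            "strand": ["+", "-"],
        }
    )
    return genome, genes


def rng(seed=0):
    return np.random.default_rng(seed)
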