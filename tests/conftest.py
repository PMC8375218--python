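import pandas as pd
import pytest

from phasevar.repeat_finder import InvertibleLocus
from phasevar.synthetic_data import GenomeSpec, make_genome


def locus_from_truth(row: pd.Series, ref_name: str = "genome") -> InvertibleLocus:
    """Convert one synthetic-truth row into an InvertibleLocus."""
    return InvertibleLocus(
        ref_name=ref_name,
        left_arm=(int(row.left_start), int(row.left_end)),
        right_arm=(int(row.right_start), int(row.right_end)),
        spacer=(int(row.spacer_start), int(row.spacer_end)),
        repeat_seq=row.repeat_seq,
        label=row.label,
    )


@pytest.fixture(scope="session")
def small_genome():
    """50 kb genome with three planted invertible loci."""
    spec = GenomeSpec(genome_length=50_000, n_loci=3, seed=11)
    genome, truth = make_genome(spec)
    return genome, truth


@pytest.fixture(scope="session")
def small_loci(small_genome):
    _, truth = small_genome
    return [locus_from_truth(row) for _, row in truth.iterrows()]
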