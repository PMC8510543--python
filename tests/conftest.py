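import numpy as np
import pytest

from oriconflict.genome import Gene, GenomeAnnotation, Promoter
from oriconflict.simulate import preset, simulate


@pytest.fixture
def toy_genome() -> GenomeAnnotation:
    """100 bp circular genome, origin at 1, terminus at 51 (default),
    with genes on both replichores and strands plus two promoters."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=100))
    genes = [
        Gene("gR_fwd", start=10, end=29, strand="forward"),   # right replichore, CD
        Gene("gR_rev", start=30, end=45, strand="reverse"),   # right replichore, HO
        Gene("gL_fwd", start=60, end=74, strand="forward"),   # left replichore, HO
        Gene("gL_rev", start=80, end=95, strand="reverse"),   # left replichore, CD
    ]
    promoters = [
        Promoter("pF", tss_pos=9, strand="forward", gene_id="gR_fwd"),
        Promoter("pR", tss_pos=46, strand="reverse", gene_id="gR_rev"),
    ]
    return GenomeAnnotation(
        genome_id="toy", length=100, origin_pos=1, sequence=seq,
        genes=genes, promoters=promoters,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A modest null-scenario simulation shared across tests."""
    cfg = preset(
        "null", seed=11, genome_length=60_000, n_genes=60,
        n_lines=40, generations_per_line=1000,
    )
    return simulate(cfg)
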