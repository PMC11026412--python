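import numpy as np
import pytest

from ctsirna import study, synthetic
from ctsirna.io_formats import AnnotatedGenome, Gene, SubFeature


@pytest.fixture(scope="session")
def sim_genome():
    """Default synthetic study genome (92 genes, 5 categories), seed 7."""
    cfg = study.default_config(seed=7)
    genome, truth = synthetic.simulate_genome(cfg)
    return genome, truth


@pytest.fixture(scope="session")
def toy_genome():
    """Hand-built genome with a deliberate rRNA/protein-coding overlap.

    chr1 layout (0-based half-open):
      geneA  protein-coding  +  [100, 400)  with UTRs/CDS/exon children
      rrna1  structural RNA  +  [300, 500)  overlapping geneA's tail
      geneB  protein-coding  -  [700, 1000)
      mir1   pri-miRNA       +  [1200, 1300)
    """
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=1500))
    genes = [
        Gene(
            "geneA", "chr1", 100, 400, "+", "protein-coding",
            [
                SubFeature("five_prime_UTR", 100, 150),
                SubFeature("CDS", 150, 350),
                SubFeature("three_prime_UTR", 350, 400),
                SubFeature("exon", 100, 400),
            ],
        ),
        Gene("rrna1", "chr1", 300, 500, "+", "structural RNA"),
        Gene(
            "geneB", "chr1", 700, 1000, "-", "protein-coding",
            [
                SubFeature("three_prime_UTR", 700, 760),
                SubFeature("CDS", 760, 950),
                SubFeature("five_prime_UTR", 950, 1000),
                SubFeature("exon", 700, 1000),
            ],
        ),
        Gene("mir1", "chr1", 1200, 1300, "+", "pri-miRNA"),
    ]
    return AnnotatedGenome({"chr1": seq}, genes)
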