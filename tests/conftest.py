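import numpy as np
import pytest

from luxerode.genome import AnnotatedGenome, Feature
from luxerode import simulate as sim


@pytest.fixture(scope="session")
def tiny_genome():
    """Three-gene single-contig genome, hand-checkable."""
    #          1-30 CDS (+)      41-70 CDS (-)        81-110 CDS (+)
    g1 = "ATGAAACCCGGGTTTAAACCCGGGTTTTAA"          # 30 nt ORF
    g2 = "ATGCATCATCATCATCATCATCATCATTAA"          # 30 nt ORF (on - strand)
    g3 = "ATGGACGACGACGACGACGACGACGACTGA"          # 30 nt ORF
    from luxerode.genome import revcomp
    seq = "GGGGGGGGGG".join(["", g1, revcomp(g2), g3, ""])
    contig = seq
    feats = [
        Feature("geneA", "c1", 11, 40, "+", "CDS", "functional", "protein A"),
        Feature("geneB", "c1", 51, 80, "-", "CDS", "functional", "protein B"),
        Feature("geneC", "c1", 91, 120, "+", "CDS", "functional", "protein C"),
    ]
    return AnnotatedGenome("tiny", {"c1": contig}, feats).validate()


@pytest.fixture(scope="session")
def small_ancestor():
    return sim.simulate_ancestor(n_genes=50, mean_gene_len=600,
                                 intergenic_len=100, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180626)
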