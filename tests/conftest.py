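import numpy as np
import pytest

import plmkit as pk

TOY_GFF3 = """\
##gff-version 3
chr1\ttoy\tgene\t1500\t2000\t.\t+\t.\tID=g1
chr1\ttoy\tmRNA\t1500\t2000\t.\t+\t.\tID=g1.1;Parent=g1
chr1\ttoy\tfive_prime_UTR\t1500\t1550\t.\t+\t.\tID=g1.1.5utr;Parent=g1.1
chr1\ttoy\tthree_prime_UTR\t1950\t2000\t.\t+\t.\tID=g1.1.3utr;Parent=g1.1
chr1\ttoy\tgene\t1200\t1800\t.\t-\t.\tID=g2
chr1\ttoy\tmRNA\t1200\t1800\t.\t-\t.\tID=g2.1;Parent=g2
chr1\ttoy\tfive_prime_UTR\t1750\t1800\t.\t-\t.\tID=g2.1.5utr;Parent=g2.1
chr1\ttoy\tthree_prime_UTR\t1200\t1250\t.\t-\t.\tID=g2.1.3utr;Parent=g2.1
chr1\ttoy\tgene\t2200\t2600\t.\t+\t.\tID=g3
chr1\ttoy\tmRNA\t2200\t2600\t.\t+\t.\tID=g3.1;Parent=g3
chr1\ttoy\tthree_prime_UTR\t2550\t2600\t.\t+\t.\tID=g3.1.3utr;Parent=g3.1
chr1\ttoy\tgene\t2700\t2900\t.\t+\t.\tID=g4
"""


@pytest.fixture(scope="session")
def toy_genome():
    rng = np.random.default_rng(123)
    seq = "".join(rng.choice(list("ACGT"), size=3000))
    return {"chr1": seq}


@pytest.fixture(scope="session")
def toy_genes():
    return pk.read_gene_models(TOY_GFF3)


@pytest.fixture(scope="session")
def planted_regions():
    """Small 5' region set with a strongly planted 6-mer at offset -35."""
    regions, truth = pk.generate_regions(
        200, 300, 100, plants=[pk.PlantSpec("TATAAA", -35, 2, 0.4)], seed=11
    )
    return regions, truth
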