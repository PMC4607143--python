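import numpy as np
import pytest

from ampliped.genotypes import GenotypeMatrix
from ampliped.panel import Amplicon, AmpliconPanel, Locus


@pytest.fixture
def tiny_panel() -> AmpliconPanel:
    """Two amplicons, 3 + 2 biallelic SNPs."""
    a1 = Amplicon("AMP1", "neutral", [
        Locus("L1", "AMP1", "chr1", 100, "A", ("G",)),
        Locus("L2", "AMP1", "chr1", 250, "C", ("T",)),
        Locus("L3", "AMP1", "chr1", 900, "G", ("A",)),
    ])
    a2 = Amplicon("AMP2", "immune", [
        Locus("L4", "AMP2", "chr2", 50, "T", ("C",)),
        Locus("L5", "AMP2", "chr2", 75, "A", ("C",)),
    ])
    return AmpliconPanel([a1, a2])


@pytest.fixture
def tiny_matrix(tiny_panel) -> GenotypeMatrix:
    calls = [
        [("A", "A"), ("C", "T"), ("G", "G"), ("T", "T"), ("A", "C")],
        [("A", "G"), ("C", "C"), ("G", "A"), None, ("C", "C")],
        [("G", "G"), ("T", "T"), ("A", "A"), ("T", "C"), None],
    ]
    return GenotypeMatrix.from_calls(["s1", "s2", "s3"], tiny_panel.loci, calls)


def random_matrix(panel: AmpliconPanel, n_samples: int, seed: int,
                  missing_rate: float = 0.1) -> GenotypeMatrix:
    """Uniform random genotypes over each locus' declared alleles."""
    rng = np.random.default_rng(seed)
    loci = panel.loci
    pairs = np.empty((n_samples, len(loci), 2), dtype=np.int16)
    for j, locus in enumerate(loci):
        draws = rng.integers(0, locus.n_alleles, size=(n_samples, 2))
        pairs[:, j, 0] = draws.min(axis=1)
        pairs[:, j, 1] = draws.max(axis=1)
    miss = rng.random((n_samples, len(loci))) < missing_rate
    pairs[miss] = -1
    samples = [f"r{i}" for i in range(n_samples)]
    return GenotypeMatrix(samples, loci, pairs)
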