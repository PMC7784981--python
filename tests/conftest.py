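import numpy as np
import pytest

from epirange.pangenome import GeneClusterMatrix, PhenotypeMap


TOY_TABLE = """\
gene_callers_id\tgenome_name\tgene_cluster_id\taccession\tfunction
g1\tA\tc1\tF1\tfunc one
g2\tA\tc2\tF2\tfunc two
g3\tA\tc3\t\t
g4\tB\tc1\tF1\tfunc one
g5\tB\tc2\tF2\tfunc two
g6\tB\tc2\tF2\tfunc two
"""


@pytest.fixture
def toy_table(tmp_path):
    p = tmp_path / "toy.tsv"
    p.write_text(TOY_TABLE)
    return p


@pytest.fixture
def toy_phenotypes():
    return PhenotypeMap(assignments={"A": "resistant", "B": "permissive"})


@pytest.fixture
def study_phenotypes():
    """The default 10/3/10 genome design."""
    from epirange.simulate import default_genomes

    return PhenotypeMap(assignments=default_genomes())


def random_matrix(rng, n_genomes, n_clusters, max_count=1):
    """Random count matrix with no empty clusters, as a GeneClusterMatrix."""
    counts = rng.integers(0, max_count + 1, size=(n_genomes, n_clusters))
    empty = np.flatnonzero((counts >= 1).sum(axis=0) == 0)
    counts[rng.integers(n_genomes, size=empty.size), empty] = 1
    genomes = [f"G{i:02d}" for i in range(n_genomes)]
    clusters = [f"c{j:03d}" for j in range(n_clusters)]
    return GeneClusterMatrix(genomes=genomes, clusters=clusters, counts=counts)
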