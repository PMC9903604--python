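import numpy as np
import pandas as pd
import pytest

from triadexpress.matrix import ExpressionMatrix
from triadexpress.simulate import TriadSimSpec, simulate_triad_counts


def make_matrix(values, genotypes, daps, reps, unit="counts", genes=None):
    """Build a small ExpressionMatrix from a 2-D array and parallel metadata."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    sample_ids = [f"{g}_d{d}_r{r}" for g, d, r in zip(genotypes, daps, reps)]
    vals = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                        columns=sample_ids)
    samples = pd.DataFrame({
        "genotype": genotypes, "dap": daps, "replicate": reps,
    }, index=pd.Index(sample_ids, name="sample_id"))
    return ExpressionMatrix(values=vals, samples=samples, unit=unit)


@pytest.fixture
def triad_matrix():
    """Tiny 4-gene triad with 2 replicates per genotype at one DAP."""
    return make_matrix(
        [[10, 12, 30, 28, 50, 55],
         [0, 0, 5, 7, 1, 1],
         [100, 110, 100, 90, 100, 105],
         [20, 22, 20, 21, 20, 19]],
        genotypes=["M", "M", "H", "H", "P", "P"],
        daps=[3] * 6, reps=[1, 2, 1, 2, 1, 2])


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated triad reused by several structural tests."""
    spec = TriadSimSpec(n_genes=800, seed=123)
    return spec, simulate_triad_counts(spec)
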