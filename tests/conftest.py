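import numpy as np
import pandas as pd
import pytest

from coexqtl.data import ExpressionMatrix, GenotypeTable
from coexqtl.simulate import SimConfig, simulate_genotypes, simulate_expression, simulate_traits


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Down-scaled panel: 27 strains, 300 genes, 6 planted modules of 40."""
    return SimConfig(
        n_genes=300, module_sizes=(40,) * 6, n_markers_per_chr=8, seed=11
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    geno = simulate_genotypes(small_config)
    expr, truth = simulate_expression(small_config, geno)
    traits = simulate_traits(small_config, truth)
    return geno, expr, traits, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def random_expression(rng) -> ExpressionMatrix:
    """Unstructured 20-gene × 10-strain matrix with detection p-values."""
    genes = [f"g{i}" for i in range(20)]
    strains = [f"S{i}" for i in range(10)]
    values = pd.DataFrame(rng.standard_normal((20, 10)), index=genes, columns=strains)
    det = pd.DataFrame(rng.uniform(0, 1, (20, 10)), index=genes, columns=strains)
    return ExpressionMatrix(values, det)


def make_genotypes(calls_dict, chromosome="1"):
    """Build a GenotypeTable from {marker: [calls...]} with synthetic positions."""
    markers = list(calls_dict)
    strains = [f"S{i}" for i in range(len(next(iter(calls_dict.values()))))]
    meta = pd.DataFrame(
        {
            "chromosome": [chromosome] * len(markers),
            "cM": [2.0 * i for i in range(len(markers))],
            "Mb": [4.0 * i for i in range(len(markers))],
        },
        index=pd.Index(markers, name="marker"),
    )
    calls = pd.DataFrame(
        {s: [calls_dict[m][j] for m in markers] for j, s in enumerate(strains)},
        index=meta.index,
    )
    return GenotypeTable(meta, calls)
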