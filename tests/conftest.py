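import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from expansionload.genotypes import MISSING, GenotypeMatrix, PopulationMap

warnings.filterwarnings("ignore", category=UserWarning)

DATA = Path(__file__).parent / "data"


def make_gm(rows, individuals=None, loci=None, depth=20.0, chrom="chr1"):
    """GenotypeMatrix from a sites x individuals list of lists ('.'=missing)."""
    values = np.array([[MISSING if g in (".", None) else int(g) for g in row]
                       for row in rows], dtype=np.int8).T
    n_ind, n_sites = values.shape
    individuals = individuals or [f"ind{i + 1}" for i in range(n_ind)]
    sites = pd.DataFrame({
        "chrom": chrom,
        "pos": np.arange(1, n_sites + 1) * 10,
        "locus": loci or [f"L{j + 1}" for j in range(n_sites)],
        "ref": "A",
        "alt": "C",
        "mean_depth": depth,
    })
    return GenotypeMatrix(values, sites, individuals)


def make_popmap(assignment, distances=None, regions=None):
    """PopulationMap from {individual: population}."""
    pops = list(dict.fromkeys(assignment.values()))
    distances = distances or {p: 100.0 * i for i, p in enumerate(pops)}
    regions = regions or {p: p for p in pops}
    rows = [{"sample": ind, "population": pop, "region": regions[pop],
             "lat": 45.0, "lon": -120.0, "distance_km": distances[pop]}
            for ind, pop in assignment.items()]
    return PopulationMap(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def toy_vcf_path():
    return DATA / "toy.vcf"


@pytest.fixture(scope="session")
def toy_expected():
    df = pd.read_csv(DATA / "toy_expected.tsv", sep="\t", comment="#",
                     dtype=str).set_index("site")
    return df.replace(".", str(MISSING)).astype(int)


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    from expansionload.simulate import write_fixtures
    outdir = tmp_path_factory.mktemp("fixtures")
    return write_fixtures(outdir, seed=11)


@pytest.fixture(scope="session")
def small_expansion():
    """One small expansion run shared across load/stats tests."""
    from expansionload.simulate import ExpansionSimConfig, gen_range_expansion
    cfg = ExpansionSimConfig(n_demes=4, capacity=60, founders=10, dt_found=40,
                             l_neutral=200, l_deleterious=200,
                             generations=200, burn_in=100, sample_size=15,
                             seed=7)
    return gen_range_expansion(cfg)
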