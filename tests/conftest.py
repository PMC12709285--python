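import numpy as np
import pandas as pd
import pytest

from ploidyscan import synthetic_data as sd
from ploidyscan import variants_io as vio
from ploidyscan.cli import tiny_config


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small deterministic bundle: 3 lineages per ploidy, 2 scaffolds,
    two strong planted sweeps."""
    return sd.simulate_dataset(tiny_config(7))


@pytest.fixture(scope="session")
def tiny_dir(tmp_path_factory, tiny_bundle):
    d = tmp_path_factory.mktemp("bundle")
    sd.write_bundle(tiny_bundle, d, overwrite=True)
    return d


@pytest.fixture(scope="session")
def tiny_gm(tiny_dir, tiny_bundle):
    return vio.read_vcf(tiny_dir / "synthetic.vcf", tiny_bundle.samples)


def make_gm(dosage, ploidies, populations, positions=None, scaffold="s1", depth=None,
            lineages=None):
    """Hand-built GenotypeMatrix for unit tests."""
    dosage = np.asarray(dosage, dtype=np.int16)
    n_sites, n_samples = dosage.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1)
    sites = pd.DataFrame(
        {
            "scaffold": scaffold,
            "pos": positions,
            "ref": "A",
            "alt": "T",
            "ancestral": "unknown",
        }
    )
    if depth is None:
        depth = np.full(dosage.shape, 30, dtype=np.int32)
    samples = pd.DataFrame(
        {
            "sample_id": [f"i{j}" for j in range(n_samples)],
            "population": populations,
            "ploidy": ploidies,
            "lineage": lineages if lineages is not None else ["L1"] * n_samples,
        }
    )
    return vio.GenotypeMatrix(
        sites=sites, dosage=dosage, depth=np.asarray(depth, dtype=np.int32), samples=samples
    )
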