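import warnings

import pytest

import ecoscan as es

SMALL_REGIONS = {"sub-Saharan Africa": 3, "Europe": 3, "East Asia": 3, "Oceania": 3}


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale fixture: 12 populations in 4 regions, 3,000 SNPs, strong
    planted signal (4% effect SNPs) so construction checks have headroom."""
    return es.SimulationConfig(
        seed=7,
        n_populations=12,
        region_sizes=dict(SMALL_REGIONS),
        n_snps=3000,
        snp_spacing=200_000,
        n_contigs=4,
        fraction_effect=0.04,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return es.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_pipeline(small_data):
    """Worldwide scan + rank tables on the small fixture."""
    return es.subset_scan(
        small_data["counts"], small_data["env"], small_data["panel"], "worldwide", seed=7
    )
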