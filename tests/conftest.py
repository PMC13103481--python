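import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic hexaploid dataset shared across tests."""
    from hexorigin import simdata

    params = simdata.HistoryParams(n_genes=60, codons_per_gene=300, seed=7)
    cds, truth = simdata.simulate_haplotype_cds(params)
    cmap, overlaps, alleles, hits = simdata.fragment_and_contacts(truth, seed=7)
    counts = simdata.simulate_expression(truth, seed=7)
    return {
        "params": params, "cds": cds, "truth": truth, "cmap": cmap,
        "overlaps": overlaps, "alleles": alleles, "hits": hits,
        "counts": counts,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
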