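import numpy as np
import pytest

from locusadmix import AdmixtureEvent, SimConfig, simulate
from locusadmix.pipeline import run_locus_by_locus
from locusadmix.popassign import PopulationScheme
from locusadmix.synthgen import scheme_from_config


@pytest.fixture
def small_scheme() -> PopulationScheme:
    """Three populations, one supergroup (European = Wine + EuropeanOak)."""
    return PopulationScheme(
        populations=["Wine", "EuropeanOak", "Malaysia"],
        supergroups={"European": ["Wine", "EuropeanOak"]},
        refs={
            "Wine": ["Wine_ref1", "Wine_ref2"],
            "EuropeanOak": ["EuropeanOak_ref1", "EuropeanOak_ref2"],
            "Malaysia": ["Malaysia_ref1", "Malaysia_ref2"],
        },
    )


@pytest.fixture
def seven_pop_scheme() -> PopulationScheme:
    return scheme_from_config(SimConfig())


def planted_config(seed: int, loci_per_strain=(1, 2, 4)) -> SimConfig:
    """Seven-population study-style config with planted introgression."""
    donors = {"Wine": "NorthCarolinaOak", "Sake": "Malaysia",
              "PennsylvaniaOak": "WestAfrica"}
    rng = np.random.default_rng(seed + 10_000)
    events = []
    for (base, donor), m in zip(donors.items(), loci_per_strain):
        loci = tuple(int(i) for i in rng.choice(16, size=m, replace=False))
        events.append(AdmixtureEvent(f"{base}_adm", base, donor, loci))
    return SimConfig(
        n_loci=16, locus_length=300, n_queries_per_pop=1,
        admixture_events=events, seed=seed,
    )


@pytest.fixture(scope="session")
def planted_run():
    """One full pipeline run on a planted-admixture dataset (shared)."""
    cfg = planted_config(seed=11)
    dataset, truth = simulate(cfg)
    scheme = scheme_from_config(cfg)
    result = run_locus_by_locus(dataset, scheme, n_bootstrap=200, seed=5)
    return cfg, dataset, truth, scheme, result
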