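import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sim_cfg():
    from brafscan.simulate import SyntheticConfig

    return SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def energy_records(sim_cfg):
    from brafscan.simulate import generate_energy_tables

    return generate_energy_tables(sim_cfg)


@pytest.fixture(scope="session")
def profile28(sim_cfg):
    from brafscan.ensemble import profile_from_pdb_strings
    from brafscan.simulate import generate_structure_ensemble

    ensemble = generate_structure_ensemble(sim_cfg, n_structures=28)
    return profile_from_pdb_strings(ensemble, residue_range=sim_cfg.residue_range)


@pytest.fixture(scope="session")
def cohort(sim_cfg):
    from brafscan.pipeline import generate_cohort

    return generate_cohort(seed=sim_cfg.seed, sim_cfg=sim_cfg)
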