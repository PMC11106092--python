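import pathlib

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

DATA_DIR = pathlib.Path(__file__).parent.parent / "src" / "msemarker" / "data"
MILK_FASTA = DATA_DIR / "milk_proteins_synthetic.fasta"


@pytest.fixture(scope="session")
def milk_fasta_path() -> pathlib.Path:
    return MILK_FASTA


@pytest.fixture(scope="session")
def milk_space():
    """Full default search space over the bundled milk-protein database.

    Built once per session (~15 s); shared by identification and
    acceptance tests.
    """
    from msemarker.identify import build_search_space

    return build_search_space([MILK_FASTA])


@pytest.fixture()
def vlp_unmodified():
    from msemarker.chem.digest import PeptideRecord

    return PeptideRecord("VLPVPQKAVPYPQR", "beta_casein", 185, 198, 1)


@pytest.fixture()
def vlp_glycated():
    from msemarker.chem.digest import PeptideRecord
    from msemarker.chem.modifications import LACTULOSYLLYSINE

    return PeptideRecord(
        "VLPVPQKAVPYPQR",
        "beta_casein",
        185,
        198,
        1,
        modifications=(LACTULOSYLLYSINE.site(7),),
    )


@pytest.fixture(scope="session")
def small_study():
    """A reduced simulated study for fast feature/chemometrics tests:
    5 markers, 60 noise analytes, 4+4 samples, short gradient."""
    from msemarker.simulate import default_markers, SimulationConfig, simulate_study

    config = SimulationConfig(
        planted=default_markers(),
        seed=20240915,
        n_noise=60,
        n_heated=4,
        n_non_heated=4,
        rt_start=80.0,
        rt_end=320.0,
    )
    runs, sheet, truth = simulate_study(config)
    return config, runs, sheet, truth
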