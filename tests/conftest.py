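import pytest

from ecostoich import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic study (6 sites x 4 plots, seed 42)."""
    return generate_dataset(SimulationConfig(seed=42))


@pytest.fixture
def survey_csv(tmp_path):
    path = tmp_path / "survey.csv"
    path.write_text(
        "plot_id,species,biomass,leaf_C,leaf_N,leaf_P\n"
        "P1,Artemisia,12.5,450.0,23.5,1.8\n"
        "P1,Stipa,4.0,430.0,20.0,1.5\n"
        "P2,Stipa,8.0,440.0,25.0,2.0\n"
    )
    return path
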