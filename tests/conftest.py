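import pytest

from krillsurvey.simulate import SurveyScenario, generate_survey


@pytest.fixture(scope="session")
def default_survey():
    """One default-scenario synthetic survey shared across tests."""
    return generate_survey(SurveyScenario(seed=0))


@pytest.fixture(scope="session")
def survey_dir(tmp_path_factory):
    """The same default survey written out as CSV files."""
    out = tmp_path_factory.mktemp("survey")
    generate_survey(SurveyScenario(seed=0), out_dir=out)
    return out
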