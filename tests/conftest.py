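import pytest
from hypothesis import settings

from ethnosurvey.survey_data import Respondent, SurveyDataset, UseReport
from ethnosurvey.synthetic import GeneratorConfig, generate_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_respondent(rid="R1", **overrides) -> Respondent:
    base = dict(
        respondent_id=rid,
        country="Benin",
        group="Fon",
        gender="man",
        age_years=40,
        age_category="adult",
        schooling="none",
        activity="farming",
        religion="christian",
        migratory_status="autochthon",
        owns_trees=True,
        n_trees=2,
        ownership_mode="legacy",
        habitat="farm",
        land_area_ha=1.0,
        perceived_growth="slow",
        perceived_time_to_fruiting_years=5.0,
        perceived_availability="decline",
        knows_taboo=False,
        knows_superstition=False,
        perceives_market=False,
        willing_to_cultivate=False,
    )
    base.update(overrides)
    return Respondent(**base)


def make_report(rid="R1", **overrides) -> UseReport:
    base = dict(
        respondent_id=rid,
        use_label="sweetener",
        category="food",
        body_system="non_medicinal",
        plant_part="fruit",
        preparation="direct",
        source_relation="father",
        source_gender="man",
    )
    base.update(overrides)
    return UseReport(**base)


@pytest.fixture
def tiny_dataset() -> SurveyDataset:
    """3 respondents, 5 use reports, fully valid."""
    respondents = [
        make_respondent("R1"),
        make_respondent("R2", gender="woman", age_years=25, age_category="young",
                        owns_trees=False, n_trees=0, ownership_mode=None,
                        habitat=None),
        make_respondent("R3", age_years=65, age_category="old",
                        willing_to_cultivate=True, max_acreage_ha=0.5,
                        max_price_usd=1.0),
    ]
    reports = [
        make_report("R1"),
        make_report("R1", use_label="malaria", category="medicinal",
                    body_system="general_health", plant_part="leaf",
                    preparation="decoction"),
        make_report("R2", source_relation="mother", source_gender="woman"),
        make_report("R3"),
        make_report("R3", use_label="lucky_charm", category="magico_spiritual",
                    plant_part="root", source_relation="friend"),
    ]
    return SurveyDataset(respondents=respondents, use_reports=reports)


@pytest.fixture(scope="session")
def default_dataset() -> SurveyDataset:
    """The default synthetic survey at a fixed seed, shared across tests."""
    return generate_dataset(GeneratorConfig(), seed=7)


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()
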