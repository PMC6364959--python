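import numpy as np
import pytest

from painpheno.cohort.features import build_feature_vectors
from painpheno.cohort.groups import build_cohort
from painpheno.nlp.lexicon import Lexicon
from painpheno.nlp.pipeline import run_phenotype
from painpheno.outcomes import compute_outcomes
from painpheno.synthetic_ehr import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def micro_lexicon() -> Lexicon:
    """Small lexicon for oracle-equivalence stress testing."""
    return Lexicon(
        concept_terms=("depression", "sadness", "low mood"),
        exclusion_patterns=("st depression",),
        pre_negation_triggers=("no", "denies", "without", "no evidence of"),
        post_negation_triggers=("unlikely", "ruled out"),
        termination_terms=("but", "however"),
    )


@pytest.fixture(scope="session")
def micro_vocab() -> list[str]:
    """~30-word vocabulary including concept/trigger/termination words."""
    return [
        "depression", "sadness", "low", "mood", "no", "denies", "without",
        "evidence", "unlikely", "ruled", "out", "but", "however", "st",
        "patient", "reports", "feels", "today", "anxiety", "stable", "exam",
        "chronic", "mild", "pain", "notes", "visit", "well", "the", "of", "has",
    ]


@pytest.fixture(scope="session")
def extract_small():
    """Shared 200-patient synthetic extract."""
    return generate_cohort(GeneratorConfig(n_patients=200, seed=42))


@pytest.fixture(scope="session")
def pipeline_small(extract_small):
    """Extract run through phenotyping, cohort building and outcomes."""
    ex = extract_small
    surgery_dates = dict(
        zip(ex.encounters["patient_id"].astype(str), ex.encounters["surgery_date"])
    )
    nlp = run_phenotype(ex.notes, surgery_dates)
    tables = {
        name: getattr(ex, name)
        for name in ("patients", "encounters", "diagnoses", "medications", "vitals", "pain")
    }
    cohort, attrition = build_cohort(tables, nlp["patient_flags"])
    features = build_feature_vectors(cohort, ex.medications)
    outcomes = compute_outcomes(cohort, ex.pain)
    return {
        "extract": ex,
        "nlp": nlp,
        "cohort": cohort,
        "attrition": attrition,
        "features": features,
        "outcomes": outcomes,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
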