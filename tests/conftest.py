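"""Shared fixtures: synthetic datasets generated once per session."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from halopha import synthetic_data as sd

#: Stationary vs mid-exponential fold changes planted throughout the qPCR tests
#: (valeric-acid-supplemented culture values).
PLANTED_FOLDS = {
    ("phaC1", "stationary", "mid_exponential"): 3.75,
    ("phaC2", "stationary", "mid_exponential"): 2.56,
    ("phaC3", "stationary", "mid_exponential"): 5.86,
    ("phaC_Hme", "stationary", "mid_exponential"): 0.33,
}


@pytest.fixture(scope="session")
def references():
    return sd.synthetic_references(seed=1)


@pytest.fixture(scope="session")
def survey_truths():
    return [
        sd.SurveyTruth(
            "Species_A", (sd.PlantedHit("PhaC1", 80.0),),
            phaE_present=True, phaE_to_phaC_distance=50,
        ),
        sd.SurveyTruth(
            "Species_B",
            (sd.PlantedHit("PhaC_Hme", 90.0), sd.PlantedHit("PhaC3", 70.0)),
        ),
        sd.SurveyTruth(
            "Species_C",
            (
                sd.PlantedHit("PhaC_Hme", 92.0),
                sd.PlantedHit("PhaC1", 85.0),
                sd.PlantedHit("PhaC2", 75.0, truncation=0.62),
                sd.PlantedHit("PhaC3", 68.0),
            ),
            phaE_present=True, phaE_to_phaC_distance=120,
        ),
        sd.SurveyTruth("Species_D", (sd.PlantedHit("PhaC2", 55.0),)),
    ]


@pytest.fixture(scope="session")
def survey_dataset(tmp_path_factory, references, survey_truths):
    out = tmp_path_factory.mktemp("survey")
    return sd.generate_survey_dataset(survey_truths, references, out, seed=7)


@pytest.fixture(scope="session")
def qpcr_noise_free():
    spec = sd.QpcrSimSpec(fold_changes=PLANTED_FOLDS, seed=11)
    return spec, sd.generate_qpcr_dataset(spec)
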