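import datetime as dt

import pytest

import ahpdx

#: the 4-factor hyperglycemia judgment set (HDL moderately over LDL, etc.)
HYPER_FACTORS = ("HDL", "LDL", "Triglyceridea", "Age")
HYPER_JUDGMENTS = (
    ("HDL", "LDL", 3),
    ("HDL", "Triglyceridea", 7),
    ("HDL", "Age", 7),
    ("LDL", "Triglyceridea", 5),
    ("LDL", "Age", 5),
    ("Triglyceridea", "Age", 1),
)


@pytest.fixture(scope="session")
def hyper_matrix():
    return ahpdx.build_matrix(HYPER_FACTORS, HYPER_JUDGMENTS)


@pytest.fixture(scope="session")
def hyper_weights(hyper_matrix):
    return ahpdx.principal_weights(hyper_matrix)


@pytest.fixture()
def hyper_profile():
    return ahpdx.load_profile(ahpdx.bundled_profile_path("hyperglycemia"))


@pytest.fixture()
def male_patient():
    return ahpdx.Patient("p001", "male", dt.date(1980, 3, 5), dt.date(2012, 1, 1))


@pytest.fixture()
def worked_panel():
    """HDL over 40, LDL under 80, triglycerides and age in range."""
    return ahpdx.LabPanel(
        "panel-1",
        "p001",
        dt.date(2012, 6, 1),
        analytes=(
            ahpdx.Analyte("HDL", 45, "mg/dL"),
            ahpdx.Analyte("LDL", 70, "mg/dL"),
            ahpdx.Analyte("Triglyceridea", 120, "mg/dL"),
        ),
    )


@pytest.fixture()
def in_range_panel():
    return ahpdx.LabPanel(
        "panel-2",
        "p001",
        dt.date(2012, 6, 1),
        analytes=(
            ahpdx.Analyte("HDL", 35, "mg/dL"),
            ahpdx.Analyte("LDL", 100, "mg/dL"),
            ahpdx.Analyte("Triglyceridea", 120, "mg/dL"),
        ),
    )
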