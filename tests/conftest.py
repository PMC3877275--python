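import numpy as np
import pandas as pd
import pytest

from growthscape.synth import ScenarioConfig, make_scenario


# Printed main-prey diet compositions (individual percent volume, in
# published descending order) for the warm and cold survey years; used
# as fixed inputs to the main-prey selection rule.
TABLE1_WARM = [
    ("Limacina helicina", 26.33),
    ("Pseudocalanus sp.", 26.04),
    ("Oikopleura sp.", 11.86),
    ("Centropages abdominalis", 8.98),
    ("Thysanoessa raschii", 8.48),
    ("Thysanoessa sp.", 4.63),
    ("Acartia clausi", 3.40),
    ("Calanus marshallae", 1.71),
]
TABLE1_COLD = [
    ("Limacina helicina", 35.45),
    ("Thysanoessa inermis", 27.08),
    ("Calanus marshallae", 13.87),
    ("Neocalanus cristatus", 4.84),
    ("Thysanoessa inspinata", 3.16),
    ("Thysanoessa raschii", 3.09),
    ("Neocalanus plumchrus", 2.98),
    ("Eucalanus bungii", 2.95),
]


@pytest.fixture(scope="session")
def warm_bundle():
    return make_scenario(ScenarioConfig(regime="warm", n_stations=20, seed=11))


@pytest.fixture(scope="session")
def cold_bundle():
    return make_scenario(ScenarioConfig(regime="cold", n_stations=20, seed=11))


@pytest.fixture
def table1_warm():
    return pd.Series(dict(TABLE1_WARM))


@pytest.fixture
def table1_cold():
    return pd.Series(dict(TABLE1_COLD))
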