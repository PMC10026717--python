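import io

import numpy as np
import pandas as pd
import pytest

from troutstock.data import Dataset, read_fish_table
from troutstock.simulate import AllometryParams, GrowthParams, SyntheticConfig, simulate_population

TOY_CSV = """id,year,tract,gear,TL_cm,W_g,age_yr,transect_id,recapture_of
f01,2017,TOR2,A,22.5,107,2.3,T1,
f02,2017,TOR2,A,10.0,10,0.9,T1,
f03,2017,TOR3,B,45.0,900,4.5,,
f04,2020,TOR1,A,30.0,,3.1,T2,
f05,2020,TOR2,B,68.0,3000,6.0,,
"""


@pytest.fixture
def toy_dataset() -> Dataset:
    return read_fish_table(io.StringIO(TOY_CSV))


@pytest.fixture
def noiseless_config() -> SyntheticConfig:
    return SyntheticConfig(
        n=400,
        seed=7,
        growth=GrowthParams(sigma_TL=0.0),
        allometry=AllometryParams(sigma_log10W=0.0),
        missing_mass_frac=0.0,
    )


@pytest.fixture
def noiseless_population(noiseless_config) -> Dataset:
    return simulate_population(noiseless_config)
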