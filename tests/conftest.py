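import pandas as pd
import pytest

from retroharm.engine import harmonise_study_wave, pool, tabulate
from retroharm.fixtures import school_travel_fixture


@pytest.fixture(scope="session")
def bundle():
    """The packaged three-study worked example, regenerated in memory."""
    return school_travel_fixture()


@pytest.fixture(scope="session")
def harmonised(bundle):
    """All three harmonised variables applied to the fixture: name -> (dataset, recodes)."""
    out = {}
    for name, spec in bundle.specs.items():
        fragments, recodes = [], []
        for table in bundle.tables.values():
            fragment, recode = harmonise_study_wave(table, spec, bundle.dictionary)
            fragments.append(fragment)
            recodes.append(recode)
        out[name] = (pool(fragments, spec), recodes)
    return out


@pytest.fixture(scope="session")
def tabulations(harmonised):
    return {name: tabulate(ds) for name, (ds, _) in harmonised.items()}


def series(values, **kwargs):
    return pd.Series(values, dtype="object", **kwargs)
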