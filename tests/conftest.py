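import pytest
from hypothesis import settings

from lineup2ht import FIXTURE_NAMES, TwoHTModel, load_fixture

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_fits():
    """Comparison-standard and restricted fits of all eight bundled studies.

    Computed once per session; many tests check different facets of the
    same fits.
    """
    out = {}
    for name in FIXTURE_NAMES:
        fixture = load_fixture(name)
        comparison = TwoHTModel(fixture.data, fixture.comparison_spec).fit()
        restricted = {
            rname: TwoHTModel(fixture.data, rspec).fit(compute_se=False)
            for rname, rspec in fixture.restriction_specs.items()
        }
        out[name] = {
            "fixture": fixture,
            "comparison": comparison,
            "restricted": restricted,
        }
    return out
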