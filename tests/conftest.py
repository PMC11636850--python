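import pytest

from kalpha import parse_reliability_csv
from kalpha.synthetic import WORKED_EXAMPLE_CSV

#: 5 items x 4 raters, 3 categories, complete data.
TOY_CSV = "1,1,1,1\n2,2,3,2\n3,3,3,3\n3,3,3,3\n2,2,2,2"

#: Same panel with two cells missing.
TOY_MISSING_CSV = "1,1,NA,1\n2,2,3,2\n3,3,3,3\n3,NA,3,3\n2,2,2,2"


@pytest.fixture(scope="session")
def example_csv():
    """Raw text of the bundled 12 x 4 worked example (alpha = 0.743)."""
    return WORKED_EXAMPLE_CSV


@pytest.fixture(scope="session")
def example_matrix(example_csv):
    return parse_reliability_csv(example_csv)


@pytest.fixture(scope="session")
def toy_matrix():
    return parse_reliability_csv(TOY_CSV)


@pytest.fixture(scope="session")
def toy_missing_matrix():
    return parse_reliability_csv(TOY_MISSING_CSV)
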