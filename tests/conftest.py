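import pytest

from stepspec import duplex as dx
from stepspec import inference as inf
from stepspec import restraints as rst


@pytest.fixture(scope="session")
def panel():
    """The packaged 13-duplex binding panel."""
    return inf.read_observations(rst.packaged_panel())


@pytest.fixture(scope="session")
def panel_table():
    """Raw panel CSV rows including the binding/missed annotations."""
    import pandas as pd

    return pd.read_csv(rst.packaged_panel(), dtype=str).fillna("")


@pytest.fixture(scope="session")
def noe_peaks():
    """Parsed packaged NOE contact table (both complexes)."""
    return rst.parse_noe_table(rst.packaged_noe_table())


@pytest.fixture(scope="session")
def d2():
    return dx.validate_palindrome("CGATATCG", codename="D2")


@pytest.fixture(scope="session")
def d3():
    return dx.validate_palindrome("CCCTAGGG", codename="D3")
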