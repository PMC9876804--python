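import pytest

from recallcost.ledger import MacroTable
from recallcost.synthetic import generate_paper_fixture
from recallcost.valuation import value_ledger


@pytest.fixture(scope="session")
def macro():
    """Small macro table with convenient round-number series."""
    return MacroTable(
        deflator={
            ("USD", 2018): 110.0,
            ("USD", 2019): 112.2,
            ("VND", 2018): 97.0,
            ("VND", 2019): 100.0,
            ("XOF", 2018): 98.0,
            ("XOF", 2019): 100.0,
        },
        fx={
            ("VND", 2018): 22700.0,
            ("VND", 2019): 23000.0,
            ("XOF", 2018): 555.0,
            ("XOF", 2019): 575.0,
        },
    )


@pytest.fixture(scope="session")
def vn_fixture():
    return generate_paper_fixture("vietnam")


@pytest.fixture(scope="session")
def bf_fixture():
    return generate_paper_fixture("burkina_faso")


@pytest.fixture(scope="session")
def vn_valued(vn_fixture):
    fx = vn_fixture
    return value_ledger(fx.items, fx.wages, fx.macro, fx.params)


@pytest.fixture(scope="session")
def bf_valued(bf_fixture):
    fx = bf_fixture
    return value_ledger(fx.items, fx.wages, fx.macro, fx.params)
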