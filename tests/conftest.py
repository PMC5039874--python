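import pytest

from anginacea import (
    evaluate_strategy,
    incremental_analysis,
    paper_fixture,
)


@pytest.fixture(scope="session")
def params():
    """Packaged base-case parameter set."""
    return paper_fixture()


@pytest.fixture(scope="session")
def base_results(params):
    """(intervention result, comparator result, incremental) for the base case."""
    a = evaluate_strategy(params, params.intervention)
    b = evaluate_strategy(params, params.comparator)
    return a, b, incremental_analysis(a, b)
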