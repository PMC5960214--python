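import pandas as pd
import pytest

from bwsprefs import (
    BlockDesign,
    CohortSpec,
    ResponseTable,
    build_bibd,
    expand,
    simulate_cohort,
    statin_catalogue,
)
from bwsprefs.catalogue import OutcomeCatalogue


@pytest.fixture(scope="session")
def catalogue():
    return statin_catalogue()


@pytest.fixture(scope="session")
def design13():
    return build_bibd(13, 4)


@pytest.fixture(scope="session")
def fano():
    return build_bibd(7, 3)


@pytest.fixture(scope="session")
def abcd_catalogue():
    """Four generic outcomes, D the reference."""
    return OutcomeCatalogue(
        outcomes=("A", "B", "C", "D"),
        harm_flags=(False, False, True, True),
        reference="D",
    )


@pytest.fixture(scope="session")
def single_block_design():
    """A trivially valid (4, 1, 1, 4, 1) design: one block of all 4 outcomes."""
    return BlockDesign(v=4, b=1, r=1, k=4, lam=1, blocks=(frozenset({0, 1, 2, 3}),))


@pytest.fixture(scope="session")
def small_cohort(catalogue, design13):
    """40 respondents at scale 1, evenly spaced utilities; reused read-only."""
    u = {o: 0.5 * i for i, o in enumerate(reversed(catalogue.outcomes))}
    spec = CohortSpec(site="unit", n_respondents=40, true_utilities=u, seed=7)
    return simulate_cohort(spec, design13, catalogue)


@pytest.fixture(scope="session")
def small_paired(small_cohort, design13, catalogue):
    return expand(small_cohort, design13, catalogue)


def manual_response_table(rows, site="manual"):
    """Build a ResponseTable from (respondent, scenario_id, best, worst) tuples."""
    frame = pd.DataFrame(
        rows, columns=["respondent_id", "scenario_id", "best_outcome", "worst_outcome"]
    )
    frame.insert(1, "site", site)
    cov = pd.DataFrame(
        {
            "respondent_id": frame["respondent_id"].unique(),
            "site": site,
            "age": 50.0,
            "sex": "female",
            "education_years": 10.0,
        }
    )
    return ResponseTable(responses=frame, covariates=cov)
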