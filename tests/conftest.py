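import numpy as np
import pytest

from hpdsize import (
    BetaPrior,
    ExpertPanel,
    elicited_quartiles,
    fit_bspline_prior,
)

#: the worked-example panel: eight experts' guesses of a renal-scar rate
PANEL_OPINIONS = (0.30, 0.25, 0.15, 0.40, 0.30, 0.20, 0.20, 0.30)


@pytest.fixture(scope="session")
def uti_panel() -> ExpertPanel:
    return ExpertPanel(PANEL_OPINIONS, label="UTI worked example")


@pytest.fixture(scope="session")
def uti_quartiles(uti_panel):
    return elicited_quartiles(uti_panel)


@pytest.fixture(scope="session")
def beta_informative() -> BetaPrior:
    return BetaPrior(8.0, 22.0)


@pytest.fixture(scope="session")
def bspline_low(uti_quartiles):
    return fit_bspline_prior(uti_quartiles, degree=4, phi=1.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220)
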