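import numpy as np
import pandas as pd
import pytest

from reefcast.dynamics import ReefState, SiteParams
from reefcast.sites import make_site


@pytest.fixture
def healthy_state() -> ReefState:
    """A plausible healthy reef state used across dynamics tests."""
    return ReefState(
        coral=0.30,
        eac=0.52,
        macroturf=0.12,
        macroalgae=0.06,
        herbivore_biomass=7.0,
        piscivore_biomass=1.2,
        urchin_biomass=10.0,
    )


@pytest.fixture
def default_params() -> SiteParams:
    return SiteParams()


@pytest.fixture
def lucero() :
    return make_site("lucero_like")


@pytest.fixture
def tomasa():
    return make_site("tomasa_like")


def random_valid_state(rng: np.random.Generator, with_urchins: bool = True) -> ReefState:
    covers = rng.dirichlet(np.ones(4))
    return ReefState(
        coral=float(covers[0]),
        eac=float(covers[1]),
        macroturf=float(covers[2]),
        macroalgae=float(covers[3]),
        herbivore_biomass=float(rng.uniform(0, 30)),
        piscivore_biomass=float(rng.uniform(0, 10)),
        urchin_biomass=float(rng.uniform(0, 30)) if with_urchins else 0.0,
    )


def balanced_design(n_rep: int = 2) -> pd.DataFrame:
    """A 2 x 3 x 3 crossed design mirroring the scenario factorial."""
    return pd.DataFrame(
        [
            (w, f, b)
            for w in ("regulated", "unregulated")
            for f in ("none", "moderate", "high")
            for b in ("none", "once", "twice")
            for _ in range(n_rep)
        ],
        columns=["water_quality", "fishing", "bleaching"],
    )
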