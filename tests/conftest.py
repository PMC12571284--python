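import pandas as pd
import pytest

from florascape.simulate import SimConfig, gen_species_catalog


def small_kernel(classes, moves=()):
    """Row-stochastic annual kernel; moves = [(frm, to, rate), ...]."""
    k = pd.DataFrame(0.0, index=list(classes), columns=list(classes))
    for c in classes:
        k.loc[c, c] = 1.0
    for frm, to, rate in moves:
        k.loc[frm, frm] -= rate
        k.loc[frm, to] += rate
    return k


@pytest.fixture
def small_cfg():
    """Three-class landscape small enough for exhaustive checks."""
    classes = ("savanna", "agriculture", "forest")
    return SimConfig(
        classes=classes,
        pool_sizes={"savanna": 120, "agriculture": 80, "forest": 100},
        overlap_design=((("savanna", "agriculture"), 30), (("savanna", "forest"), 20)),
        sar_c={"savanna": 40.0, "agriculture": 30.0, "forest": 35.0},
        sar_z={"savanna": 0.25, "agriculture": 0.2, "forest": 0.3},
        n_plots=40,
        n_wards=12,
        years=(2000, 2010),
        landscape_shares={"savanna": 0.5, "agriculture": 0.3, "forest": 0.2},
        transition_kernel=small_kernel(
            classes, [("savanna", "agriculture", 0.02), ("forest", "agriculture", 0.01)]
        ),
        pop0=10_000.0,
        pop_growth=0.02,
        seed=7,
    )


@pytest.fixture(scope="session")
def default_catalog():
    cfg = SimConfig(seed=11)
    return cfg, gen_species_catalog(cfg)
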