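"""LULC change accounting: shares, transitions, net/gross, rates."""

import numpy as np
import pandas as pd
import pytest

from florascape.change import (
    ClassAreaTable,
    annual_rate,
    class_shares,
    net_change_from_areas,
    net_gross_change,
    percent_change,
    transition_matrix,
)
from florascape.exceptions import ValidationError
from florascape.kilimanjaro import (
    BUILTUP_SURFACE_KM2,
    LULC_AREAS_KM2,
    natural_area_km2,
)


@pytest.fixture
def area_table():
    return ClassAreaTable(pd.DataFrame(LULC_AREAS_KM2).T.sort_index())


def test_published_share_arithmetic(area_table):
    """Savanna was 75 % of the mapped 1911 area; agriculture 45 % in 2022."""
    assert class_shares(area_table, 1911, rounded=True)["savanna"] == 75
    assert class_shares(area_table, 2022, rounded=True)["agriculture"] == 45


def test_single_class_is_hundred_percent():
    t = ClassAreaTable(pd.DataFrame({"savanna": [123.0]}, index=[2000]))
    assert class_shares(t, 2000)["savanna"] == pytest.approx(100.0)


def test_rounded_shares_sum_to_about_100(area_table):
    for year in (1976, 2002, 2022):
        shares = class_shares(area_table, year, rounded=True)
        assert abs(shares.sum() - 100) <= len(shares) / 2


def test_identical_grids_are_purely_diagonal():
    g = np.array([[1, 2], [2, 1]])
    m = transition_matrix(g, g, cell_area_km2=1.0)
    off = m.flows.to_numpy() - np.diag(np.diag(m.flows.to_numpy()))
    assert (off == 0).all()
    assert m.total_area == 4.0


def test_toy_cross_tab_by_hand():
    # [A,A;B,B] → [A,B;B,B]: flow A→B = 1, persistence A = 1, B = 2
    g1 = np.array([[1, 1], [2, 2]])
    g2 = np.array([[1, 2], [2, 2]])
    m = transition_matrix(g1, g2, 1.0, legend={1: "A", 2: "B"})
    assert m.flows.loc["A", "B"] == 1.0
    assert m.flows.loc["A", "A"] == 1.0
    assert m.flows.loc["B", "B"] == 2.0
    ng = net_gross_change(m)
    assert ng.loc["A", "net"] == -1.0
    assert ng.loc["B", "net"] == 1.0
    assert (ng["gross"] == 1.0).all()


def test_shape_mismatch_and_unknown_code_rejected():
    with pytest.raises(ValidationError, match="shapes"):
        transition_matrix(np.ones((2, 2)), np.ones((3, 2)), 1.0)
    with pytest.raises(ValidationError, match="unknown category"):
        transition_matrix(np.array([[9]]), np.array([[9]]), 1.0, legend={1: "A"})


def test_nodata_cells_excluded():
    g1 = np.array([[1, 0], [2, 2]])
    g2 = np.array([[1, 1], [0, 2]])
    m = transition_matrix(g1, g2, 2.0, nodata=0)
    assert m.total_area == 4.0  # two valid cells x 2 km²


def test_transition_matches_per_cell_tally_oracle():
    """Exact cross-tab oracle: a plain Python per-cell tally on a 100×100
    grid equals the vectorised matrix, and totals are conserved."""
    rng = np.random.default_rng(23)
    g1 = rng.integers(1, 6, size=(100, 100))
    g2 = rng.integers(1, 6, size=(100, 100))
    m = transition_matrix(g1, g2, 0.25)
    tally = {}
    for i in range(100):
        for j in range(100):
            tally[(g1[i, j], g2[i, j])] = tally.get((g1[i, j], g2[i, j]), 0) + 1
    for (a, b), n in tally.items():
        assert m.flows.loc[a, b] == pytest.approx(n * 0.25)
    assert m.total_area == pytest.approx(100 * 100 * 0.25)
    ng = net_gross_change(m)
    assert ng["net"].sum() == pytest.approx(0.0, abs=1e-9)


def test_generated_grids_match_kernel_within_multinomial_bounds(small_cfg):
    """Empirical transition proportions from generator grids sit within 4
    standard errors of the n-step kernel rows."""
    from florascape.simulate import gen_grid_pair

    misses = 0
    for seed in range(3):
        cfg = small_cfg
        cfg.seed = seed
        g1, g2, legend = gen_grid_pair(cfg, shape=(100, 100), n_years=10)
        k10 = np.linalg.matrix_power(
            cfg.transition_kernel.to_numpy(float), 10
        )
        m = transition_matrix(g1, g2, 1.0, legend=legend)
        classes = list(cfg.classes)
        for i, c in enumerate(classes):
            row_n = m.flows.loc[c].sum()
            if row_n < 50:
                continue
            for j, d in enumerate(classes):
                p = k10[i, j]
                phat = m.flows.loc[c, d] / row_n
                se = max(np.sqrt(p * (1 - p) / row_n), 1e-4)
                if abs(phat - p) > 4 * se:
                    misses += 1
    assert misses == 0


def test_anthropogenic_expansion_signs(small_cfg):
    """Under an erosion kernel every natural class has net <= 0 and every
    anthropogenic class net >= 0 (qualitative accounting property)."""
    from florascape.simulate import gen_grid_pair

    g1, g2, legend = gen_grid_pair(small_cfg, shape=(80, 80), n_years=20)
    ng = net_gross_change(transition_matrix(g1, g2, 1.0, legend=legend))
    assert ng.loc["savanna", "net"] <= 0
    assert ng.loc["forest", "net"] <= 0
    assert ng.loc["agriculture", "net"] >= 0


def test_net_only_from_area_table(area_table):
    net = net_change_from_areas(area_table, 1976, 2022)
    assert net.loc["savanna", "net"] == pytest.approx(588 - 1090)
    assert net.loc["built_up", "net"] == pytest.approx(74 - 6)
    assert "gross" not in net.columns  # unidentifiable without maps


def test_published_builtup_percent_changes():
    siha = BUILTUP_SURFACE_KM2["Siha"]
    hai = BUILTUP_SURFACE_KM2["Hai"]
    assert percent_change(siha[1975], siha[2000], rounded=True) == 49
    assert percent_change(siha[2000], siha[2020], rounded=True) == 115
    assert percent_change(hai[2000], hai[2020], rounded=True) == 73
    mr = BUILTUP_SURFACE_KM2["Moshi Rural"]
    assert percent_change(mr[1975], mr[2000], rounded=True) == 38


def test_percent_change_edges():
    assert percent_change(5.0, 5.0) == 0.0
    with pytest.raises(ValidationError):
        percent_change(0.0, 5.0)


def test_annual_rate_closed_forms():
    r = annual_rate(100.0, 100.0, 10)
    assert r.compound == 0.0 and r.linear == 0.0
    doubling = annual_rate(1.0, 2.0, 10)
    assert doubling.compound == pytest.approx(2**0.1 - 1)
    # natural-habitat decline 1911→1976: 2948 → 1572 km² over 65 years
    assert natural_area_km2(1911) == 2948
    assert natural_area_km2(1976) == 1572
    rate = annual_rate(natural_area_km2(1911), natural_area_km2(1976), 65)
    assert rate.compound == pytest.approx(-0.0096, abs=0.0003)
    with pytest.raises(ValidationError):
        annual_rate(0.0, 1.0, 10)


def test_closed_area_invariant():
    bad = pd.DataFrame(
        {"a": [100.0, 300.0], "b": [100.0, 100.0]}, index=[2000, 2010]
    )
    with pytest.raises(ValidationError, match="closed"):
        ClassAreaTable(bad)
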