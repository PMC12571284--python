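"""Ward-level species density estimation."""

import numpy as np
import pytest

from florascape.exceptions import ValidationError
from florascape.overlap import ReductionEntry, ReductionTable, build_reduction_table
from florascape.releves import ClassSpeciesList
from florascape.sar import SARParams
from florascape.wards import WardYearRecord, richness_table, ward_group_density


def make_list(name, n):
    return ClassSpeciesList(name, set(f"{name}{i}" for i in range(n)), 1, {"all": n})


def setup_classes(richness_1km, factors):
    """Class lists + SAR params at 1 km² + a reduction table with the given
    per-subset factors for group 'all'."""
    lists = {c: make_list(c, max(int(s), 1)) for c, s in richness_1km.items()}
    sar = {
        c: SARParams(c, c=float(s), z=0.25, ref_area_km2=1.0)
        for c, s in richness_1km.items()
    }
    table = ReductionTable(classes=tuple(sorted(richness_1km)))
    for subset, f in factors.items():
        table.entries[(frozenset(subset), "all")] = ReductionEntry(0, 0, f)
    return lists, sar, table


def test_pure_ward_density_equals_class_richness():
    lists, sar, table = setup_classes({"savanna": 200}, {("savanna",): 1.0})
    rec = WardYearRecord("w1", 2000, 10.0, {"savanna": 1.0})
    d = ward_group_density(rec, sar, lists, table, "all")
    assert d.species_per_km2 == pytest.approx(200.0)


def test_two_class_ward_hand_computation():
    # p = 0.5/0.5, S = 200/100, f = 0.8 → D = 0.8·(100 + 50) = 120
    lists, sar, table = setup_classes(
        {"a": 200, "b": 100}, {("a", "b"): 0.8, ("a",): 1.0, ("b",): 1.0}
    )
    rec = WardYearRecord("w1", 2000, 5.0, {"a": 0.5, "b": 0.5})
    d = ward_group_density(rec, sar, lists, table, "all")
    assert d.species_per_km2 == pytest.approx(120.0)


def test_nine_equal_classes_published_scale():
    """Nine classes with equal shares, 1 km² richness summing 3995 and
    f = 0.51 → D = 0.51·3995/9 ≈ 226."""
    names = [f"c{i}" for i in range(9)]
    s = 3995 / 9
    lists, sar, table = setup_classes(
        {c: s for c in names}, {tuple(names): 0.51}
    )
    rec = WardYearRecord("w1", 2000, 50.0, {c: 1 / 9 for c in names})
    d = ward_group_density(rec, sar, lists, table, "all")
    assert d.species_per_km2 == pytest.approx(0.51 * 3995 / 9, rel=1e-6)
    assert d.species_per_km2 == pytest.approx(226.4, abs=0.1)


def test_presence_threshold_controls_factor_subset():
    """A 0.5 % sliver does not change the factor subset, but its area share
    still contributes to the weighted sum."""
    lists, sar, table = setup_classes(
        {"a": 200, "b": 100},
        {("a", "b"): 0.5, ("a",): 1.0, ("b",): 1.0},
    )
    rec = WardYearRecord("w1", 2000, 5.0, {"a": 0.995, "b": 0.005})
    d = ward_group_density(rec, sar, lists, table, "all", presence_threshold=0.01)
    assert d.species_per_km2 == pytest.approx(1.0 * (0.995 * 200 + 0.005 * 100))
    d2 = ward_group_density(rec, sar, lists, table, "all", presence_threshold=0.001)
    assert d2.species_per_km2 == pytest.approx(0.5 * (0.995 * 200 + 0.005 * 100))


def test_missing_sar_entry_names_class():
    lists, sar, table = setup_classes({"a": 200}, {("a",): 1.0})
    lists["b"] = make_list("b", 50)
    rec = WardYearRecord("w1", 2000, 5.0, {"a": 0.5, "b": 0.5})
    with pytest.raises(ValidationError, match="'b'"):
        ward_group_density(rec, sar, lists, table, "all")


def test_empty_class_contributes_nothing():
    lists, sar, table = setup_classes({"a": 200}, {("a",): 1.0})
    lists["water"] = ClassSpeciesList("water", set(), 0, {"all": 0})
    rec = WardYearRecord("w1", 2000, 5.0, {"a": 0.6, "water": 0.4})
    d = ward_group_density(rec, sar, lists, table, "all")
    assert d.species_per_km2 == pytest.approx(0.6 * 200)


def test_proportions_must_sum_to_one():
    with pytest.raises(ValidationError, match="sum"):
        WardYearRecord("w1", 2000, 5.0, {"a": 0.5, "b": 0.4})


def test_density_invariant_under_ward_split():
    """Splitting a ward into two with identical composition leaves the
    unweighted mean unchanged."""
    lists, sar, table = setup_classes(
        {"a": 200, "b": 100}, {("a", "b"): 0.8, ("a",): 1.0, ("b",): 1.0}
    )
    whole = [WardYearRecord("w1", 2000, 10.0, {"a": 0.5, "b": 0.5}, 500)]
    halves = [
        WardYearRecord("w1a", 2000, 5.0, {"a": 0.5, "b": 0.5}, 250),
        WardYearRecord("w1b", 2000, 5.0, {"a": 0.5, "b": 0.5}, 250),
    ]
    _, m1 = richness_table(whole, sar, lists, table, groups=("all",))
    _, m2 = richness_table(halves, sar, lists, table, groups=("all",))
    assert m1["species_per_km2"].iloc[0] == pytest.approx(
        m2["species_per_km2"].iloc[0]
    )


def test_ward_mean_bounded_by_max_class_richness():
    rng = np.random.default_rng(5)
    richness = {"a": 320.0, "b": 150.0, "c": 90.0}
    lists = {c: make_list(c, int(s)) for c, s in richness.items()}
    sar = {c: SARParams(c, c=s, z=0.2) for c, s in richness.items()}
    table = build_reduction_table(lists, groups=("all",))
    recs = []
    for i in range(20):
        p = rng.dirichlet([1.0, 1.0, 1.0])
        recs.append(
            WardYearRecord(f"w{i}", 2000, 10.0, dict(zip(richness, p)), 100)
        )
    _, means = richness_table(recs, sar, lists, table, groups=("all",))
    assert (means["species_per_km2"] <= max(richness.values())).all()


def test_mean_densities_decline_when_natural_classes_shrink(small_cfg):
    """End-to-end simulation property: with an erosion kernel, the mean
    natural density declines monotonically over the census years."""
    import io

    from florascape.releves import build_class_lists, read_catalog, read_releves
    from florascape.sar import fit_sar_per_class
    from florascape.simulate import gen_releves, gen_species_catalog, gen_ward_series
    from florascape.wards import records_from_tables

    declines = 0
    for seed in range(3):
        cfg = small_cfg
        cfg.seed = seed
        cat_df = gen_species_catalog(cfg)
        cat = read_catalog(io.StringIO(cat_df.to_csv(index=False)))
        rels = read_releves(io.StringIO(gen_releves(cfg, cat_df).to_csv(index=False)), cat)
        lists = build_class_lists(rels, cat, {})
        sar = fit_sar_per_class(rels)
        table = build_reduction_table(lists, cat, groups=("all", "natural"))
        wards, census = gen_ward_series(cfg)
        recs = records_from_tables(wards, census)
        _, means = richness_table(recs, sar, lists, table, groups=("natural",))
        vals = means.sort_values("year")["species_per_km2"].to_numpy()
        if np.all(np.diff(vals) < 0):
            declines += 1
    assert declines == 3
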