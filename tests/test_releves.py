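"""Relevé ingestion and per-class species-list construction."""

import io
import textwrap

import pandas as pd
import pytest

from florascape.exceptions import ConfigurationError, ValidationError
from florascape.releves import (
    Releve,
    build_class_lists,
    class_lists_frame,
    natural_species_set,
    read_catalog,
    read_releves,
)


def catalog_frame(ids, endemic=(), redlist=(), neophyte=()):
    df = pd.DataFrame(
        {
            "species_id": list(ids),
            "name": list(ids),
            "classes": "savanna",
            "endemic": [i in endemic for i in ids],
            "redlist": [i in redlist for i in ids],
            "neophyte": [i in neophyte for i in ids],
        }
    )
    return read_catalog(io.StringIO(df.to_csv(index=False)))


def releve_csv(text):
    return io.StringIO(textwrap.dedent(text))


def test_duplicate_plot_species_rows_collapse():
    cat = catalog_frame(["s1", "s2"])
    rels = read_releves(
        releve_csv(
            """\
            plot_id,class,plot_area_km2,species_id
            p1,savanna,0.01,s1
            p1,savanna,0.01,s1
            p1,savanna,0.01,s2
            """
        ),
        cat,
    )
    assert len(rels) == 1
    assert rels[0].species_ids == {"s1", "s2"}


def test_empty_file_gives_empty_list(caplog):
    with caplog.at_level("WARNING"):
        rels = read_releves(releve_csv("plot_id,class,plot_area_km2,species_id\n"))
    assert rels == []
    assert "empty" in caplog.text


def test_unknown_class_names_offending_row():
    with pytest.raises(ValidationError, match="row 0.*moonbase"):
        read_releves(
            releve_csv(
                """\
                plot_id,class,plot_area_km2,species_id
                p1,moonbase,0.01,s1
                """
            )
        )


def test_unknown_species_errors_unless_permissive():
    cat = catalog_frame(["s1"])
    csv = """\
        plot_id,class,plot_area_km2,species_id
        p1,savanna,0.01,sX
        """
    with pytest.raises(ValidationError, match="(?i)sx"):
        read_releves(releve_csv(csv), cat)
    rels = read_releves(releve_csv(csv), cat, permissive=True)
    assert rels[0].species_ids == {"unlisted"}


def test_species_ids_normalized_before_matching():
    cat = catalog_frame(["s1"])
    rels = read_releves(
        releve_csv(
            """\
            plot_id,class,plot_area_km2,species_id
            p1,Savanna,0.01," S1 "
            """
        ),
        cat,
    )
    assert rels[0].lulc_class == "savanna"
    assert rels[0].species_ids == {"s1"}


def test_default_merge_folds_plantation_and_builtup_into_agriculture():
    cat = catalog_frame(["s1", "s2", "s3"])
    rels = [
        Releve("p1", "agriculture", 0.01, {"s1"}),
        Releve("p2", "forest_plantation", 0.01, {"s2"}),
        Releve("p3", "built_up", 0.01, {"s3"}),
    ]
    lists = build_class_lists(rels, cat)
    assert lists["agriculture"].species == {"s1", "s2", "s3"}
    assert lists["agriculture"].n_releves == 3


def test_merge_map_chain_rejected():
    cat = catalog_frame(["s1"])
    with pytest.raises(ConfigurationError, match="chains"):
        build_class_lists(
            [Releve("p1", "savanna", 0.01, {"s1"})],
            cat,
            {"built_up": "grassland", "grassland": "savanna"},
        )


def test_class_union_and_group_counts():
    """Two relevés in one class sharing 2 of 5 species each → richness 8;
    group counts come from catalog flags."""
    cat = catalog_frame(
        [f"s{i}" for i in range(1, 9)], endemic={"s1"}, neophyte={"s7", "s8"}
    )
    rels = [
        Releve("p1", "savanna", 0.01, {"s1", "s2", "s3", "s4", "s5"}),
        Releve("p2", "savanna", 0.01, {"s4", "s5", "s6", "s7", "s8"}),
    ]
    lists = build_class_lists(rels, cat)
    sav = lists["savanna"]
    assert len(sav.species) == 8
    assert sav.group_counts["endemic"] == 1
    assert sav.group_counts["neophyte"] == 2
    assert lists["all_classes"].group_counts["all"] == 8


def test_single_releve_list_is_its_species():
    cat = catalog_frame(["s1", "s2", "s3", "s4", "s5"])
    rels = [Releve("p1", "forest", 0.01, {"s1", "s2", "s3", "s4", "s5"})]
    lists = build_class_lists(rels, cat)
    assert lists["forest"].species == {"s1", "s2", "s3", "s4", "s5"}


def test_grand_total_subadditive():
    """Union richness <= sum of class richness, equal iff disjoint."""
    cat = catalog_frame([f"s{i}" for i in range(1, 7)])
    disjoint = [
        Releve("p1", "forest", 0.01, {"s1", "s2"}),
        Releve("p2", "savanna", 0.01, {"s3", "s4"}),
    ]
    lists = build_class_lists(disjoint, cat)
    assert lists["all_classes"].group_counts["all"] == 4
    overlapping = disjoint + [Releve("p3", "grassland", 0.01, {"s2", "s3"})]
    lists = build_class_lists(overlapping, cat)
    per_class = sum(
        len(e.species) for c, e in lists.items() if c != "all_classes"
    )
    assert lists["all_classes"].group_counts["all"] < per_class


def test_natural_union():
    cat = catalog_frame([f"s{i}" for i in range(1, 10)])
    rels = [
        Releve("p1", "forest", 0.01, {"s1", "s2"}),
        Releve("p2", "regeneration", 0.01, {"s3"}),
        Releve("p3", "savanna", 0.01, {"s4", "s5", "s1"}),
        Releve("p4", "agriculture", 0.01, {"s6"}),
    ]
    lists = build_class_lists(rels, cat)
    assert natural_species_set(lists) == {"s1", "s2", "s3", "s4", "s5"}
    # forest ⊂ savanna: union absorbs the subset
    rels2 = [
        Releve("p1", "forest", 0.01, {"s1"}),
        Releve("p2", "regeneration", 0.01, {"s3"}),
        Releve("p3", "savanna", 0.01, {"s1", "s2"}),
    ]
    assert natural_species_set(build_class_lists(rels2, cat)) == {"s1", "s2", "s3"}


def test_natural_union_requires_all_three_classes():
    cat = catalog_frame(["s1"])
    lists = build_class_lists([Releve("p1", "forest", 0.01, {"s1"})], cat)
    with pytest.raises(ValidationError, match="missing natural classes"):
        natural_species_set(lists)


def test_generator_roundtrip_matches_ground_truth(default_catalog):
    """Class lists built from generated relevés stay within the generated
    pools, and the catalog realizes the designed 772-plot structure."""
    from florascape.simulate import class_pools, gen_releves

    cfg, cat_df = default_catalog
    rel_df = gen_releves(cfg, cat_df)
    assert rel_df["plot_id"].nunique() == 772
    cat = read_catalog(io.StringIO(cat_df.to_csv(index=False)))
    rels = read_releves(io.StringIO(rel_df.to_csv(index=False)), cat)
    lists = build_class_lists(rels, cat, {})
    pools = {c: set(v) for c, v in class_pools(cat_df).items()}
    for c, entry in lists.items():
        if c == "all_classes":
            continue
        assert entry.species <= pools[c]
    frame = class_lists_frame(lists)
    assert frame.iloc[-1]["class"] == "all_classes"
    assert (
        frame.iloc[-1]["n_releves"]
        == frame.iloc[:-1]["n_releves"].sum()
        == 772
    )
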