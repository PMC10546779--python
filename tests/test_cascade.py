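"""Cascade stages: subset invariants, provenance chains, determinism."""

import pytest

from mgcascade import io_tables
from mgcascade.cascade import (
    geneset_from_annotated,
    stage_ab_phagocytic,
    stage_dmeg,
    stage_hhcy,
)
from mgcascade.model import AnnotatedGeneList, ValidationError
from mgcascade.setalgebra import union_sets

from .conftest import cascade_of, make_set


def test_ab_stage_requires_directions():
    ad = make_set("human_ad", "human", {"A": ("up", 2.0)})
    direction_free = geneset_from_annotated(AnnotatedGeneList("ab", frozenset({"A"})))
    with pytest.raises(ValidationError):
        stage_ab_phagocytic(ad, ad, direction_free)


def test_ab_stage_concordant_discordant_split():
    human = make_set("human_ad", "human", {"A": ("up", 2.0), "B": ("down", -2.0), "C": ("up", 3.0)})
    mouse = make_set("mouse_ad", "mouse", {"A": ("up", 2.0), "D": ("down", -1.6)})
    ab = make_set("ab", "mouse", {"A": ("up", 1.8), "B": ("up", 2.0), "D": ("down", -2.0)})
    ab_h, ab_m, ab_h_disc = stage_ab_phagocytic(human, mouse, ab)
    assert ab_h.symbols() == {"A"}
    assert ab_h_disc.symbols() == {"B"}
    assert ab_m.symbols() == {"A", "D"}


def test_dmeg_stage_requires_annotations():
    bare = AnnotatedGeneList("dmeg", frozenset({"X"}))
    ab = make_set("ab", "mouse", {"X": ("up", 2.0)})
    mods = AnnotatedGeneList("mods", frozenset())
    endo = make_set("endo", "cross", {})
    with pytest.raises(ValidationError, match="X"):
        stage_dmeg(bare, ab, mods, endo)


def test_dmeg_stage_all_hyper_gives_empty_hypo_tier():
    dmeg = AnnotatedGeneList(
        "dmeg",
        frozenset({"X", "Y"}),
        {
            s: {"methylation_direction": "hyper", "expression_direction": "up",
                "promoter_dm": False}
            for s in ("X", "Y")
        },
    )
    ab = make_set("ab", "mouse", {"X": ("up", 2.0), "Y": ("up", 2.0)})
    tiers = stage_dmeg(dmeg, ab, AnnotatedGeneList("mods", frozenset()),
                       make_set("endo", "cross", {}))
    assert tiers["dmeg_ab"].symbols() == {"X", "Y"}
    assert len(tiers["dmeg_hypomethylated"]) == 0
    assert len(tiers["dmeg_promoter_hypo"]) == 0


def test_hhcy_stage_annotates_categories():
    cbs = make_set("cbs", "mouse", {"IGF1": ("down", -1.79), "ZZZ": ("up", 2.0)})
    cats = {
        "gwas_phagocytic": make_set("gwas_phago", "cross", {"IGF1": ("down", -1.5)}),
        "modifier": AnnotatedGeneList("mods", frozenset({"NOPE"})),
    }
    union, per_cat = stage_hhcy(cbs, cats)
    assert union.symbols() == {"IGF1"}
    assert union.members["IGF1"].avg_fc == -1.79  # Cbs fold change carried
    assert per_cat["gwas_phagocytic"].symbols() == {"IGF1"}
    assert len(per_cat["modifier"]) == 0


def test_tier_subset_invariants(small_result):
    t = small_result.tiers
    assert t["ab_phago_human"].symbols() <= t["human_ad"].symbols()
    assert t["ab_phago_mouse"].symbols() <= t["mouse_ad"].symbols()
    assert t["common_concordant"].symbols() <= t["human_ad"].symbols() & t["mouse_ad"].symbols()
    ad_union = t["human_ad"].symbols() | t["mouse_ad"].symbols()
    assert t["phago_modifier"].symbols() <= ad_union
    assert t["endocytosis"].symbols() <= ad_union
    assert t["phagocytic_combined"].symbols() == (
        t["ab_phago_human"].symbols() | t["ab_phago_mouse"].symbols()
        | t["phago_modifier"].symbols() | t["endocytosis"].symbols()
    )
    assert t["dmeg_combined"].symbols() == (
        t["dmeg_endocytic"].symbols() | t["dmeg_ab"].symbols()
        | t["dmeg_modifier"].symbols()
    )
    assert t["dmeg_promoter_hypo"].symbols() <= t["dmeg_hypomethylated"].symbols()
    assert t["dmeg_hypomethylated"].symbols() <= t["dmeg_combined"].symbols()
    assert t["gwas_phagocytic"].symbols() <= t["phagocytic_combined"].symbols()
    assert t["gwas_phagocytic"].symbols() <= t["gwas_mg"].symbols()
    assert t["hhcy_phagocytic"].symbols() <= t["cbs_degs"].symbols()


def test_provenance_chains_reach_sources(small_sim, small_result):
    """Every combined-tier member traces back to dataset ids or list names."""
    known_sources = {t.dataset_id for t in small_sim.human_tables}
    known_sources |= {t.dataset_id for t in small_sim.mouse_tables}
    known_sources |= {
        "ab_mg_degs", "phagocytosis_modifiers", "endocytosis_genes",
        "gwas_ad_genes", "ad_dmeg", small_sim.cbs_table.dataset_id,
    }
    for tier_name in ("phagocytic_combined", "hhcy_phagocytic", "gwas_mg"):
        for sym, entry in small_result.tiers[tier_name].members.items():
            assert entry.sources, f"{tier_name}:{sym} has no provenance"
            dataset_level = set(entry.sources) & known_sources
            assert dataset_level, f"{tier_name}:{sym} does not reach a source"


def test_stage_counts_match_serialized_tiers(small_result, tmp_path):
    io_tables.write_tier_outputs(small_result, tmp_path)
    back = io_tables.read_tier_outputs(tmp_path)
    assert back.metadata["stage_counts"] == {
        name: len(tier) for name, tier in sorted(back.tiers.items())
    }


def test_category_a_configurations_agree_on_the_union(small_sim):
    """The HHcy union tier is invariant to the category-A reading."""
    endo_cfg = cascade_of(small_sim, category_a="endocytosis")
    comb_cfg = cascade_of(small_sim, category_a="combined")
    assert (
        endo_cfg.tiers["hhcy_phagocytic"].symbols()
        == comb_cfg.tiers["hhcy_phagocytic"].symbols()
    )
    # category A itself grows under the broader reading
    assert (
        endo_cfg.tiers["hhcy_cat_phagocytic"].symbols()
        <= comb_cfg.tiers["hhcy_cat_phagocytic"].symbols()
    )


def test_rerun_is_byte_identical(small_sim, tmp_path):
    out1, out2 = tmp_path / "run1", tmp_path / "run2"
    io_tables.write_tier_outputs(cascade_of(small_sim), out1)
    io_tables.write_tier_outputs(cascade_of(small_sim), out2)
    for p1 in sorted(out1.iterdir()):
        p2 = out2 / p1.name
        assert p1.read_bytes() == p2.read_bytes()
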