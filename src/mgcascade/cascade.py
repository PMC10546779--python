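"""Orchestration of the tiered cross-species meta-analysis.

Stage order: (1) per-species AD microglia consensus from per-dataset DEG
tables; (2) overlay with the amyloid-plaque-engulfing (Abeta+) microglia
signature, split into concordant (compensatory activation) and human
discordant (impaired phagocytosis) tiers; (3) overlays with the CRISPR
phagocytosis-modifier screen and the endocytosis-related gene list;
(4) union into the combined phagocytic tier; (5) overlay of methylation-
regulated (DM/EG) genes onto the three phagocytosis gene sets; (6) GWAS
gene overlays; (7) overlay of the hyperhomocysteinemia (Cbs knockout)
microglia DEGs onto the five phagocytosis-related categories. Every stage
is independently callable with explicit inputs so published intermediate
gene lists can enter the cascade mid-way.
"""

from __future__ import annotations

import hashlib
import json
from typing import Mapping, Optional, Sequence

from .harmonize import ConsensusConfig, apply_deg_criteria, consensus_merge
from .model import (
    CROSS,
    AnnotatedGeneList,
    CascadeResult,
    DEGTable,
    GeneEntry,
    RegulatedGeneSet,
    ValidationError,
)
from .setalgebra import (
    SetLike,
    intersect_concordant,
    intersect_discordant,
    intersect_symbols,
    overlap_with_list,
    union_sets,
)

#: tier names every full cascade result carries
CORE_TIERS = (
    "human_ad",
    "mouse_ad",
    "common_concordant",
    "common_discordant",
    "ab_phago_human",
    "ab_phago_mouse",
    "ab_phago_human_discordant",
    "phago_modifier",
    "endocytosis",
    "phagocytic_combined",
    "dmeg_endocytic",
    "dmeg_ab",
    "dmeg_modifier",
    "dmeg_combined",
    "dmeg_hypomethylated",
    "gwas_mg",
    "gwas_phagocytic",
    "hhcy_phagocytic",
)

HUMAN_DEFAULT = ConsensusConfig(p_field="adjusted", min_support=1)
MOUSE_DEFAULT = ConsensusConfig(p_field="adjusted", min_support=2)
#: the Cbs-knockout bulk RNA-seq table is filtered on the raw p-value
CBS_DEFAULT = ConsensusConfig(p_field="raw", min_support=1)


def stage_ad_consensus(
    human_tables: Sequence[DEGTable],
    mouse_tables: Sequence[DEGTable],
    human_cfg: ConsensusConfig = HUMAN_DEFAULT,
    mouse_cfg: ConsensusConfig = MOUSE_DEFAULT,
) -> tuple[RegulatedGeneSet, RegulatedGeneSet]:
    """Filter each dataset and merge into per-species AD consensus sets."""
    human_filtered = [apply_deg_criteria(t, human_cfg) for t in human_tables]
    mouse_filtered = [apply_deg_criteria(t, mouse_cfg) for t in mouse_tables]
    human_ad = consensus_merge(human_filtered, human_cfg, name="human_ad")
    mouse_ad = consensus_merge(mouse_filtered, mouse_cfg, name="mouse_ad")
    return human_ad, mouse_ad


def stage_ab_phagocytic(
    human_ad: RegulatedGeneSet,
    mouse_ad: RegulatedGeneSet,
    ab_set: RegulatedGeneSet,
) -> tuple[RegulatedGeneSet, RegulatedGeneSet, RegulatedGeneSet]:
    """Overlay the Abeta+ microglia DEG signature on both AD consensus sets.

    Returns the concordant human and mouse tiers (functional-validated
    phagocytic DEGs) and the human discordant tier (genes moving opposite
    to the engulfment signature, the impaired-phagocytosis signature).
    """
    if any(e.direction is None for e in ab_set.members.values()):
        raise ValidationError("ab_set must carry a direction for every member")
    ab_h = intersect_concordant(human_ad, ab_set, name="ab_phago_human")
    ab_m = intersect_concordant(mouse_ad, ab_set, name="ab_phago_mouse")
    ab_h_disc = intersect_discordant(human_ad, ab_set, name="ab_phago_human_discordant")
    return ab_h, ab_m, ab_h_disc


def stage_modifier_and_endocytosis(
    human_ad: RegulatedGeneSet,
    mouse_ad: RegulatedGeneSet,
    modifiers: AnnotatedGeneList,
    endo: AnnotatedGeneList,
) -> dict[str, RegulatedGeneSet]:
    """Overlay the CRISPR phagocytosis-modifier and endocytosis lists.

    Each list is intersected with both species then unioned with species
    provenance retained; the cross-species shared endocytosis subset
    (symbol-level, concordant or not) is reported as its own tier.
    """
    mod_h = overlap_with_list(human_ad, modifiers, name="phago_modifier_human")
    mod_m = overlap_with_list(mouse_ad, modifiers, name="phago_modifier_mouse")
    endo_h = overlap_with_list(human_ad, endo, name="endocytosis_human")
    endo_m = overlap_with_list(mouse_ad, endo, name="endocytosis_mouse")
    return {
        "phago_modifier": union_sets([mod_h, mod_m], name="phago_modifier"),
        "phago_modifier_human": mod_h,
        "phago_modifier_mouse": mod_m,
        "endocytosis": union_sets([endo_h, endo_m], name="endocytosis"),
        "endocytosis_human": endo_h,
        "endocytosis_mouse": endo_m,
        "endocytosis_common": intersect_symbols(endo_h, endo_m, name="endocytosis_common"),
    }


def stage_combine_phagocytic(
    ab_phago_human: RegulatedGeneSet,
    ab_phago_mouse: RegulatedGeneSet,
    phago_modifier: RegulatedGeneSet,
    endocytosis: RegulatedGeneSet,
) -> tuple[RegulatedGeneSet, RegulatedGeneSet]:
    """Union the three phagocytic components; report the cross-species
    functional-validated shared subset."""
    combined = union_sets(
        [ab_phago_human, ab_phago_mouse, phago_modifier, endocytosis],
        name="phagocytic_combined",
    )
    shared = intersect_concordant(ab_phago_human, ab_phago_mouse, name="ab_phago_shared")
    return combined, shared


def geneset_from_annotated(
    l: AnnotatedGeneList, name: Optional[str] = None, species: str = CROSS
) -> RegulatedGeneSet:
    """Lift an annotated list into a regulated set using its recorded
    expression directions (never recomputed)."""
    members: dict[str, GeneEntry] = {}
    for sym in sorted(l.symbols):
        direction = l.annotation(sym).get("expression_direction")
        members[sym] = GeneEntry(
            direction=direction,
            avg_fc=None,
            sources=(l.name,),
            source_directions=((l.name, direction),) if direction else (),
            ambiguous=direction is None,
        )
    return RegulatedGeneSet(name or l.name, species, members)


def stage_dmeg(
    dmeg_list: AnnotatedGeneList,
    ab_set: RegulatedGeneSet,
    modifiers: AnnotatedGeneList,
    endocytosis_tier: RegulatedGeneSet,
) -> dict[str, RegulatedGeneSet]:
    """Overlay methylation-regulated genes on the three phagocytosis sets.

    Every DM/EG member must carry both a methylation and an expression
    direction (consumed as annotations from the source methylome study).
    Returns the three component overlaps, their union, the hypomethylated
    subset, and the promoter-hypomethylated subset.
    """
    missing = sorted(
        s
        for s in dmeg_list.symbols
        if "methylation_direction" not in dmeg_list.annotation(s)
        or "expression_direction" not in dmeg_list.annotation(s)
    )
    if missing:
        raise ValidationError(
            f"DM/EG members lacking methylation/expression annotation: {missing[:10]}"
        )
    dmeg_set = geneset_from_annotated(dmeg_list)
    dmeg_endocytic = overlap_with_list(dmeg_set, endocytosis_tier, name="dmeg_endocytic")
    dmeg_ab = overlap_with_list(dmeg_set, ab_set, name="dmeg_ab")
    dmeg_modifier = overlap_with_list(dmeg_set, modifiers, name="dmeg_modifier")
    dmeg_combined = union_sets(
        [dmeg_endocytic, dmeg_ab, dmeg_modifier], name="dmeg_combined"
    )
    hypo = dmeg_combined.subset(
        (
            s
            for s in dmeg_combined.members
            if dmeg_list.annotation(s).get("methylation_direction") == "hypo"
        ),
        name="dmeg_hypomethylated",
    )
    promoter = hypo.subset(
        (s for s in hypo.members if dmeg_list.annotation(s).get("promoter_dm")),
        name="dmeg_promoter_hypo",
    )
    return {
        "dmeg_endocytic": dmeg_endocytic,
        "dmeg_ab": dmeg_ab,
        "dmeg_modifier": dmeg_modifier,
        "dmeg_combined": dmeg_combined,
        "dmeg_hypomethylated": hypo,
        "dmeg_promoter_hypo": promoter,
    }


def stage_gwas(
    gwas: AnnotatedGeneList,
    human_ad: RegulatedGeneSet,
    mouse_ad: RegulatedGeneSet,
    phagocytic_combined: RegulatedGeneSet,
) -> dict[str, RegulatedGeneSet]:
    """Overlay the curated GWAS AD gene list on the AD and phagocytic tiers."""
    g_h = overlap_with_list(human_ad, gwas, name="gwas_mg_human")
    g_m = overlap_with_list(mouse_ad, gwas, name="gwas_mg_mouse")
    return {
        "gwas_mg": union_sets([g_h, g_m], name="gwas_mg"),
        "gwas_mg_human": g_h,
        "gwas_mg_mouse": g_m,
        "gwas_shared": intersect_symbols(g_h, g_m, name="gwas_shared"),
        "gwas_phagocytic": overlap_with_list(
            phagocytic_combined, gwas, name="gwas_phagocytic"
        ),
    }


def stage_hhcy(
    cbs_degs: RegulatedGeneSet,
    five_category_sets: Mapping[str, SetLike],
) -> tuple[RegulatedGeneSet, dict[str, RegulatedGeneSet]]:
    """Overlay the Cbs-knockout (HHcy) microglia DEGs on the five
    phagocytosis-related categories.

    Returns the deduplicated union (each member keeping the Cbs fold change
    and the names of the categories it hit) and the per-category overlaps.
    Symbols compare case-insensitively across species via normalization.
    """
    per_category: dict[str, RegulatedGeneSet] = {}
    for cat_name, cat_set in five_category_sets.items():
        per_category[cat_name] = overlap_with_list(
            cbs_degs, cat_set, name=f"hhcy_cat_{cat_name}"
        )
    union = union_sets(list(per_category.values()), name="hhcy_phagocytic")
    return union, per_category


def _digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_cascade(
    human_tables: Sequence[DEGTable],
    mouse_tables: Sequence[DEGTable],
    ab_set: RegulatedGeneSet,
    modifiers: AnnotatedGeneList,
    endocytosis: AnnotatedGeneList,
    dmeg_list: AnnotatedGeneList,
    gwas_list: AnnotatedGeneList,
    cbs_table: DEGTable,
    human_cfg: ConsensusConfig = HUMAN_DEFAULT,
    mouse_cfg: ConsensusConfig = MOUSE_DEFAULT,
    cbs_cfg: ConsensusConfig = CBS_DEFAULT,
    category_a: str = "endocytosis",
) -> CascadeResult:
    """Run every stage and return the full tiered result.

    ``category_a`` selects which tier stands in for "phagocytic AD MG DEGs"
    in the HHcy overlay: the endocytosis-related tier (default) or the
    combined phagocytic union (``"combined"``).
    """
    if category_a not in ("endocytosis", "combined"):
        raise ValidationError(f"category_a must be 'endocytosis' or 'combined'")

    human_ad, mouse_ad = stage_ad_consensus(
        human_tables, mouse_tables, human_cfg, mouse_cfg
    )
    tiers: dict[str, RegulatedGeneSet] = {
        "human_ad": human_ad,
        "mouse_ad": mouse_ad,
        "common_concordant": intersect_concordant(
            human_ad, mouse_ad, name="common_concordant"
        ),
        "common_discordant": intersect_discordant(
            human_ad, mouse_ad, name="common_discordant"
        ),
    }

    ab_h, ab_m, ab_h_disc = stage_ab_phagocytic(human_ad, mouse_ad, ab_set)
    tiers.update(
        {
            "ab_phago_human": ab_h,
            "ab_phago_mouse": ab_m,
            "ab_phago_human_discordant": ab_h_disc,
            "ab_phago_mouse_discordant": intersect_discordant(
                mouse_ad, ab_set, name="ab_phago_mouse_discordant"
            ),
        }
    )

    tiers.update(
        stage_modifier_and_endocytosis(human_ad, mouse_ad, modifiers, endocytosis)
    )

    combined, ab_shared = stage_combine_phagocytic(
        ab_h, ab_m, tiers["phago_modifier"], tiers["endocytosis"]
    )
    tiers["phagocytic_combined"] = combined
    tiers["ab_phago_shared"] = ab_shared

    tiers.update(stage_dmeg(dmeg_list, ab_set, modifiers, tiers["endocytosis"]))
    tiers.update(stage_gwas(gwas_list, human_ad, mouse_ad, combined))

    cbs_filtered = apply_deg_criteria(cbs_table, cbs_cfg)
    cbs_degs = consensus_merge([cbs_filtered], cbs_cfg, name="cbs_degs")
    tiers["cbs_degs"] = cbs_degs
    categories: dict[str, SetLike] = {
        "phagocytic": combined if category_a == "combined" else tiers["endocytosis"],
        "ab_mg": ab_set,
        "modifier": modifiers,
        "dmeg_hypo": tiers["dmeg_hypomethylated"],
        "gwas_phagocytic": tiers["gwas_phagocytic"],
    }
    hhcy, per_cat = stage_hhcy(cbs_degs, categories)
    tiers["hhcy_phagocytic"] = hhcy
    for cat_name, cat_tier in per_cat.items():
        tiers[f"hhcy_cat_{cat_name}"] = cat_tier

    metadata = {
        "config": {
            "human": human_cfg.__dict__,
            "mouse": mouse_cfg.__dict__,
            "cbs": cbs_cfg.__dict__,
            "category_a": category_a,
        },
        "config_hash": _digest(
            {
                "human": human_cfg.__dict__,
                "mouse": mouse_cfg.__dict__,
                "cbs": cbs_cfg.__dict__,
                "category_a": category_a,
            }
        ),
        "input_digests": {
            "human_tables": _digest(
                [[t.dataset_id, [(r.symbol, r.fc, r.adj_p) for r in t]] for t in human_tables]
            ),
            "mouse_tables": _digest(
                [[t.dataset_id, [(r.symbol, r.fc, r.adj_p) for r in t]] for t in mouse_tables]
            ),
            "ab_set": _digest(sorted(ab_set.members)),
            "modifiers": _digest(sorted(modifiers.symbols)),
            "endocytosis": _digest(sorted(endocytosis.symbols)),
            "dmeg": _digest(sorted(dmeg_list.symbols)),
            "gwas": _digest(sorted(gwas_list.symbols)),
            "cbs_table": _digest([(r.symbol, r.fc, r.p_value) for r in cbs_table]),
        },
        "stage_counts": {},
    }
    metadata["stage_counts"] = {name: len(tier) for name, tier in sorted(tiers.items())}
    return CascadeResult(tiers=tiers, metadata=metadata)
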