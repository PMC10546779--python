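"""Synthetic multi-dataset DEG compendia with planted overlap structure.

The generator emulates the statistical shape of the real study inputs: four
human and seven mouse AD microglia DEG tables, an amyloid-engulfing (Abeta+)
microglia signature with directions, CRISPR phagocytosis-modifier /
endocytosis / GWAS curated lists, a methylation-annotated (DM/EG) list, and
a Cbs-knockout microglia DEG table. Tier memberships are *planted*: the
generator first allocates a gene universe so that running the cascade rules
on the noiseless plant yields exactly the configured tier sizes (defaults
are the study's published tier geometry), then emits per-dataset calls.

Planted calls always satisfy the selection criteria: fold-change magnitudes
are drawn from a lognormal truncated at the threshold and planted p-values
from a Beta(a<1, 1) rescaled below the significance cutoff, so that with
``detect_prob=1`` and ``direction_flip_prob=0`` cascade recovery of the
plant is exact. Noise enters through per-call dropout (``detect_prob``),
direction flips (``direction_flip_prob``), and decoy genes that the
consensus rules must reject (sub-threshold calls, cross-dataset direction
conflicts, and single-dataset mouse calls).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .model import (
    DOWN,
    HUMAN,
    MOUSE,
    UP,
    AnnotatedGeneList,
    DEGRecord,
    DEGTable,
    GeneEntry,
    RegulatedGeneSet,
    ValidationError,
)

AB_SOURCE = "ab_mg_screen"
CBS_SOURCE = "cbs_ko_mg"


@dataclass
class TierSizes:
    """Planted tier geometry. Defaults reproduce the published study."""

    human_ad: int = 409
    human_ad_up: int = 232
    mouse_ad: int = 777
    mouse_ad_up: int = 498
    common_concordant: int = 37
    common_concordant_up: int = 22
    common_discordant: int = 23
    ab_list: int = 377
    ab_list_up: int = 184
    ab_phago_human: int = 20
    ab_phago_human_up: int = 12
    ab_phago_mouse: int = 110
    ab_phago_mouse_up: int = 69
    ab_phago_shared: int = 9
    ab_phago_human_discordant: int = 14
    modifiers_list: int = 286
    modifier_tier: int = 15
    modifier_common: int = 1
    endo_list: int = 2172
    endo_human: int = 66
    endo_mouse: int = 165
    endo_common: int = 16
    endo_common_concordant: int = 12
    endo_common_concordant_up: int = 8
    phagocytic_combined: int = 326
    dmeg_list: int = 559
    dmeg_endocytic: int = 16
    dmeg_ab: int = 14
    dmeg_modifier: int = 10
    dmeg_combined: int = 36
    dmeg_hypomethylated: int = 23
    dmeg_hypomethylated_up: int = 20
    dmeg_promoter_hypo: int = 7
    gwas_list: int = 431
    gwas_human: int = 17
    gwas_mouse: int = 30
    gwas_shared: int = 4
    gwas_shared_up: int = 3
    gwas_phagocytic: int = 20
    cbs_degs: int = 353
    hhcy_cat_phagocytic: int = 3
    hhcy_cat_ab: int = 3  # includes the one GWAS-phagocytic duplicate gene
    hhcy_cat_modifier: int = 4  # includes the one DM/EG duplicate gene

    @classmethod
    def empty(cls) -> "TierSizes":
        """All planted tiers empty (decoy-only compendium)."""
        return cls(**{f.name: 0 for f in dataclasses.fields(cls)})

    def scaled(self, factor: float) -> "TierSizes":
        """Proportionally smaller geometry (for fast tests)."""
        values = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            values[f.name] = int(round(v * factor))
        return TierSizes(**values)


@dataclass
class SimParams:
    """Generator configuration; ``seed`` fixes all randomness."""

    seed: int = 0
    n_genes: int = 12000
    n_human_datasets: int = 4
    n_mouse_datasets: int = 7
    detect_prob: float = 1.0
    direction_flip_prob: float = 0.0
    fc_mu: float = math.log(2.5)  # lognormal location of FC magnitudes
    fc_sigma: float = 0.6
    fc_min: float = 1.5
    p_threshold: float = 0.05
    planted_p_beta_a: float = 0.1
    ortholog_fraction: float = 0.9
    n_decoy_conflict_human: int = 30
    n_decoy_conflict_mouse: int = 40
    n_decoy_subthreshold: int = 60  # per species
    n_decoy_low_support_mouse: int = 40
    tiers: TierSizes = field(default_factory=TierSizes)

    def __post_init__(self) -> None:
        for name in ("detect_prob", "direction_flip_prob", "ortholog_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.n_human_datasets < 1 or self.n_mouse_datasets < 2:
            raise ValidationError("need >= 1 human and >= 2 mouse datasets")
        if not (0.0 < self.p_threshold < 1.0):
            raise ValidationError("p_threshold must be in (0, 1)")
        if self.fc_min <= 1.0:
            raise ValidationError("fc_min must be > 1")


@dataclass
class _Gene:
    symbol: str
    human_dir: Optional[str] = None
    mouse_dir: Optional[str] = None
    ab_dir: Optional[str] = None
    in_modifiers: bool = False
    in_endo: bool = False
    in_gwas: bool = False
    dmeg: Optional[dict] = None
    cbs_dir: Optional[str] = None
    cbs_fc: Optional[float] = None  # exact planted magnitude, if any


@dataclass
class SyntheticTruth:
    """Planted per-tier memberships and marker genes."""

    tiers: dict[str, frozenset[str]]
    markers: dict[str, str] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {name: len(s) for name, s in sorted(self.tiers.items())}


@dataclass
class SimulatedCompendium:
    human_tables: list[DEGTable]
    mouse_tables: list[DEGTable]
    gene_lists: dict  # ab_mg: RegulatedGeneSet; modifiers/endocytosis: lists
    dmeg_list: AnnotatedGeneList
    gwas_list: AnnotatedGeneList
    cbs_table: DEGTable
    truth: SyntheticTruth
    params: SimParams


def _split_quota(sizes: Sequence[int], total_up: int) -> list[int]:
    """Largest-remainder split of an up-regulated quota across subgroups."""
    n = sum(sizes)
    if not (0 <= total_up <= n):
        raise ValidationError(f"up quota {total_up} infeasible for {n} genes")
    if n == 0:
        return [0] * len(sizes)
    raw = [s * total_up / n for s in sizes]
    ups = [min(int(r), s) for r, s in zip(raw, sizes)]
    remainder = total_up - sum(ups)
    order = sorted(
        range(len(sizes)), key=lambda i: raw[i] - int(raw[i]), reverse=True
    )
    for i in order:
        if remainder == 0:
            break
        if ups[i] < sizes[i]:
            ups[i] += 1
            remainder -= 1
    if remainder:
        raise ValidationError("could not distribute direction quota")
    return ups


def _dirs(n: int, n_up: int) -> list[str]:
    return [UP] * n_up + [DOWN] * (n - n_up)


class _SymbolFactory:
    def __init__(self, rng: np.random.Generator, ortholog_fraction: float):
        self._counter = 0
        self._mouse_counter = 0
        self._rng = rng
        self._ortholog_fraction = ortholog_fraction

    def shared(self) -> str:
        self._counter += 1
        return f"GN{self._counter:05d}"

    def mouse_only(self) -> str:
        # a fraction of mouse-only genes carry names without a human-style
        # counterpart, mirroring genes with no symbol-matched ortholog
        if self._rng.random() < self._ortholog_fraction:
            return self.shared()
        self._mouse_counter += 1
        return f"MUSG{self._mouse_counter:05d}"


def _build_dmeg_slots(t: TierSizes) -> list[dict]:
    """Annotation slots for the planted DM/EG overlap genes."""
    n_hypo = t.dmeg_hypomethylated
    n_hypo_up = t.dmeg_hypomethylated_up
    n_hyper = t.dmeg_combined - n_hypo
    if n_hypo_up > n_hypo or n_hyper < 0 or t.dmeg_promoter_hypo > n_hypo:
        raise ValidationError("infeasible DM/EG hypomethylation geometry")
    slots = []
    for i in range(n_hypo):
        slots.append(
            {
                "methylation_direction": "hypo",
                "expression_direction": UP if i < n_hypo_up else DOWN,
                "promoter_dm": i < t.dmeg_promoter_hypo,
            }
        )
    for i in range(n_hyper):
        slots.append(
            {
                "methylation_direction": "hyper",
                "expression_direction": UP if i % 2 == 0 else DOWN,
                "promoter_dm": False,
            }
        )
    return slots


def _plant(params: SimParams, rng: np.random.Generator) -> tuple[list[_Gene], dict]:
    """Allocate the gene universe so cascade rules recover the tier sizes."""
    t = params.tiers
    genes: list[_Gene] = []
    sf = _SymbolFactory(rng, params.ortholog_fraction)
    special: dict = {}

    def add(symbol: str, **kw) -> _Gene:
        g = _Gene(symbol=symbol, **kw)
        genes.append(g)
        return g

    # --- derived block sizes -------------------------------------------------
    shared_ab = t.ab_phago_shared
    h_only_ab = t.ab_phago_human - shared_ab
    m_only_ab = t.ab_phago_mouse - shared_ab
    endo_tier = t.endo_human + t.endo_mouse - t.endo_common
    ab_union = t.ab_phago_human + t.ab_phago_mouse - shared_ab
    overlap_ab_endo = ab_union + t.modifier_tier + endo_tier - t.phagocytic_combined
    endo_common_disc = t.endo_common - t.endo_common_concordant
    common_leftover = (
        t.common_concordant
        - shared_ab
        - t.endo_common_concordant
        - t.modifier_common
    )
    disc_leftover = t.common_discordant - endo_common_disc
    endo_h_fresh = t.endo_human - t.endo_common
    endo_m_fresh = t.endo_mouse - t.endo_common - overlap_ab_endo
    for name, v in {
        "human-only ab tier": h_only_ab,
        "mouse-only ab tier": m_only_ab,
        "ab/endo tier overlap": overlap_ab_endo,
        "endo common discordant": endo_common_disc,
        "common leftover": common_leftover,
        "discordant leftover": disc_leftover,
        "human-only endo tier": endo_h_fresh,
        "mouse-only endo tier": endo_m_fresh,
    }.items():
        if v < 0:
            raise ValidationError(f"infeasible planted sizes: {name} = {v}")
    if overlap_ab_endo > m_only_ab:
        raise ValidationError("ab/endo overlap exceeds the mouse-only ab tier")

    # HHcy category geometry (Cbs-hit duplicates live in categories B and C)
    n_cat_b_fresh = t.hhcy_cat_ab - (1 if t.gwas_phagocytic else 0)
    n_cat_c_fresh = t.hhcy_cat_modifier - (1 if t.dmeg_modifier else 0)
    if n_cat_b_fresh < 0 or n_cat_c_fresh < 0:
        raise ValidationError("infeasible HHcy category sizes")

    # DM/EG component duplicate split
    dup_total = t.dmeg_endocytic + t.dmeg_ab + t.dmeg_modifier - t.dmeg_combined
    if dup_total < 0:
        raise ValidationError("dmeg_combined exceeds the sum of its components")
    dup_endo_ab = min(dup_total // 2, t.dmeg_endocytic, t.dmeg_ab, overlap_ab_endo)
    dup_ab_mod = dup_total - dup_endo_ab
    has_cacna = t.dmeg_modifier > 0 and t.hhcy_cat_modifier > 0
    if dup_ab_mod > min(t.dmeg_ab - dup_endo_ab, t.dmeg_modifier):
        raise ValidationError("cannot realize DM/EG component overlaps")
    dmeg_endo_fresh = t.dmeg_endocytic - dup_endo_ab
    dmeg_ab_only = t.dmeg_ab - dup_endo_ab - dup_ab_mod
    dmeg_mod_fresh = t.dmeg_modifier - dup_ab_mod - (1 if has_cacna else 0)
    if min(dmeg_endo_fresh, dmeg_ab_only, dmeg_mod_fresh) < 0:
        raise ValidationError("cannot realize DM/EG component overlaps")
    if endo_h_fresh + endo_m_fresh < dmeg_endo_fresh:
        raise ValidationError("endocytosis tier too small for DM/EG plant")
    dmeg_endo_h = min(
        dmeg_endo_fresh, max(0, dmeg_endo_fresh * endo_h_fresh // max(1, endo_h_fresh + endo_m_fresh))
    )
    dmeg_endo_m = dmeg_endo_fresh - dmeg_endo_h
    if dmeg_endo_m > endo_m_fresh or dmeg_endo_h > endo_h_fresh:
        raise ValidationError("endocytosis tier too small for DM/EG plant")
    dmeg_slots = _build_dmeg_slots(t)

    # GWAS geometry: shared genes sit in the concordant endo-common block;
    # phagocytic GWAS genes sit on combined-tier members.
    if t.gwas_shared > t.endo_common_concordant:
        raise ValidationError("gwas_shared exceeds the concordant endo-common block")
    if t.gwas_shared_up > min(t.gwas_shared, t.endo_common_concordant_up):
        raise ValidationError("gwas_shared_up infeasible")
    has_igf1 = t.gwas_phagocytic > 0 and t.hhcy_cat_ab > 0 and m_only_ab > 0
    g_combined_rest = t.gwas_phagocytic - t.gwas_shared - (1 if has_igf1 else 0)
    if g_combined_rest < 0:
        raise ValidationError("gwas_phagocytic smaller than its forced members")
    g_h_combined = min(
        g_combined_rest,
        t.gwas_human - t.gwas_shared,
        endo_h_fresh - dmeg_endo_h,
    )
    g_m_combined = g_combined_rest - g_h_combined
    g_h_plain = t.gwas_human - t.gwas_shared - g_h_combined
    g_m_plain = (
        t.gwas_mouse - t.gwas_shared - g_m_combined - (1 if has_igf1 else 0)
    )
    if min(g_h_combined, g_m_combined, g_h_plain, g_m_plain) < 0:
        raise ValidationError("infeasible GWAS allocation")
    if g_m_combined > endo_m_fresh - dmeg_endo_m - t.hhcy_cat_phagocytic:
        raise ValidationError("mouse endocytosis tier too small for GWAS plant")

    # shared Abeta-tier direction split: find a feasible up-count
    for s_u in range(shared_ab + 1):
        lo_h, lo_m = t.ab_phago_human_up - s_u, t.ab_phago_mouse_up - s_u
        l_u = (
            t.common_concordant_up
            - s_u
            - t.endo_common_concordant_up
            - t.modifier_common  # the modifier-common gene is planted "up"
        )
        if 0 <= lo_h <= h_only_ab and 0 <= lo_m <= m_only_ab and 0 <= l_u <= common_leftover:
            break
    else:
        raise ValidationError("no feasible direction split for the shared ab tier")

    # --- common concordant block --------------------------------------------
    for d in _dirs(shared_ab, s_u):
        add(sf.shared(), human_dir=d, mouse_dir=d, ab_dir=d)
    endo_common_genes = []
    for i, d in enumerate(_dirs(t.endo_common_concordant, t.endo_common_concordant_up)):
        g = add(sf.shared(), human_dir=d, mouse_dir=d, in_endo=True)
        endo_common_genes.append(g)
    # GWAS shared genes: concordant endo-common members, mostly up
    ups = [g for g in endo_common_genes if g.human_dir == UP]
    downs = [g for g in endo_common_genes if g.human_dir == DOWN]
    n_shared_down = t.gwas_shared - t.gwas_shared_up
    if n_shared_down > len(downs):
        raise ValidationError("gwas_shared down-genes infeasible")
    for g in ups[: t.gwas_shared_up] + downs[:n_shared_down]:
        g.in_gwas = True
    for _ in range(t.modifier_common):
        add(sf.shared(), human_dir=UP, mouse_dir=UP, in_modifiers=True)
    for d in _dirs(common_leftover, l_u):
        add(sf.shared(), human_dir=d, mouse_dir=d)

    # --- common discordant block ---------------------------------------------
    def flip(d: str) -> str:
        return DOWN if d == UP else UP

    disc_h_up = (t.common_discordant + 1) // 2
    disc_dirs = _dirs(t.common_discordant, disc_h_up)
    for i, d in enumerate(disc_dirs):
        add(
            sf.shared(),
            human_dir=d,
            mouse_dir=flip(d),
            in_endo=i < endo_common_disc,
        )

    # --- species-specific Abeta tier blocks ----------------------------------
    for d in _dirs(h_only_ab, lo_h):
        add(sf.shared(), human_dir=d, ab_dir=d)
    for i, d in enumerate(_dirs(t.ab_phago_human_discordant, t.ab_phago_human_discordant // 2)):
        add(sf.shared(), human_dir=d, ab_dir=flip(d))
    m_ab_genes = []
    up_endo, up_rest = _split_quota([overlap_ab_endo, m_only_ab - overlap_ab_endo], lo_m)
    for i, d in enumerate(_dirs(overlap_ab_endo, up_endo)):
        m_ab_genes.append(add(sf.mouse_only(), mouse_dir=d, ab_dir=d, in_endo=True))
    for d in _dirs(m_only_ab - overlap_ab_endo, up_rest):
        m_ab_genes.append(add(sf.mouse_only(), mouse_dir=d, ab_dir=d))
    if has_igf1:
        igf1 = next(
            g for g in m_ab_genes if not g.in_endo and g.mouse_dir == DOWN
        )
        igf1.in_gwas = True
        igf1.cbs_dir = DOWN
        igf1.cbs_fc = -1.79  # planted HHcy effect size on the Igf1 analog
        special["gwas_phagocytic_cbs_hit"] = igf1.symbol

    # --- endocytosis tier blocks ---------------------------------------------
    endo_h_genes = [
        add(sf.shared(), human_dir=d, in_endo=True)
        for d in _dirs(endo_h_fresh, (endo_h_fresh + 1) // 2)
    ]
    endo_m_genes = [
        add(sf.mouse_only(), mouse_dir=d, in_endo=True)
        for d in _dirs(endo_m_fresh, (endo_m_fresh + 1) // 2)
    ]
    for g in endo_m_genes[: t.hhcy_cat_phagocytic]:
        g.cbs_dir = flip(g.mouse_dir)  # HHcy reverses these phagocytic genes
    cat_a_symbols = [g.symbol for g in endo_m_genes[: t.hhcy_cat_phagocytic]]
    offset = t.hhcy_cat_phagocytic
    for g in endo_m_genes[offset : offset + g_m_combined]:
        g.in_gwas = True
    for g in endo_h_genes[:g_h_combined]:
        g.in_gwas = True

    # --- modifier tier --------------------------------------------------------
    mod_rest = t.modifier_tier - t.modifier_common
    mod_h = mod_rest * t.human_ad // max(1, t.human_ad + t.mouse_ad)
    mod_m = mod_rest - mod_h
    for d in _dirs(mod_h, (mod_h + 1) // 2):
        add(sf.shared(), human_dir=d, in_modifiers=True)
    for d in _dirs(mod_m, (mod_m + 1) // 2):
        add(sf.mouse_only(), mouse_dir=d, in_modifiers=True)

    # --- plain GWAS AD genes (outside the combined tier) ----------------------
    for d in _dirs(g_h_plain, (g_h_plain + 1) // 2):
        add(sf.shared(), human_dir=d, in_gwas=True)
    for d in _dirs(g_m_plain, (g_m_plain + 1) // 2):
        add(sf.mouse_only(), mouse_dir=d, in_gwas=True)

    # --- DM/EG marking ---------------------------------------------------------
    slot_iter = iter(dmeg_slots)

    def mark_dmeg(pool: list[_Gene], count: int, dir_attr: Optional[str]) -> None:
        for _ in range(count):
            slot = next(slot_iter)
            if dir_attr is None:
                raise AssertionError
            candidates = [
                g
                for g in pool
                if g.dmeg is None and getattr(g, dir_attr) == slot["expression_direction"]
            ]
            if not candidates:
                raise ValidationError(
                    "no direction-compatible gene available for a DM/EG slot"
                )
            candidates[0].dmeg = slot

    if has_cacna:
        slot = next(slot_iter)
        if slot["methylation_direction"] != "hypo" or slot["expression_direction"] != UP:
            raise ValidationError("DM/EG slots cannot host the hypo-up modifier hit")
        cacna = add(sf.mouse_only(), in_modifiers=True, dmeg=slot, cbs_dir=UP)
        special["dmeg_hypo_cbs_hit"] = cacna.symbol
    mark_dmeg([g for g in m_ab_genes if g.in_endo], dup_endo_ab, "mouse_dir")
    dup_ab_mod_genes = []
    for _ in range(dup_ab_mod):
        slot = next(slot_iter)
        g = add(
            sf.shared(),
            ab_dir=slot["expression_direction"],
            in_modifiers=True,
            dmeg=slot,
        )
        dup_ab_mod_genes.append(g)
    dmeg_ab_only_genes = []
    for _ in range(dmeg_ab_only):
        slot = next(slot_iter)
        dmeg_ab_only_genes.append(
            add(sf.shared(), ab_dir=slot["expression_direction"], dmeg=slot)
        )
    mark_dmeg(endo_h_genes[g_h_combined:], dmeg_endo_h, "human_dir")
    mark_dmeg(endo_m_genes[offset + g_m_combined :], dmeg_endo_m, "mouse_dir")
    for _ in range(dmeg_mod_fresh):
        slot = next(slot_iter)
        add(sf.mouse_only(), in_modifiers=True, dmeg=slot)

    # --- HHcy category hits outside AD tiers ----------------------------------
    cat_b_genes = []
    for i in range(n_cat_b_fresh):
        g = add(sf.mouse_only(), ab_dir=UP if i % 2 else DOWN, cbs_dir=DOWN)
        cat_b_genes.append(g)
    for i in range(n_cat_c_fresh):
        add(sf.mouse_only(), in_modifiers=True, cbs_dir=DOWN if i % 2 else UP)

    # --- list and table fillers -----------------------------------------------
    n_ab_so_far = sum(1 for g in genes if g.ab_dir is not None)
    ab_up_so_far = sum(1 for g in genes if g.ab_dir == UP)
    ab_fill = t.ab_list - n_ab_so_far
    ab_fill_up = t.ab_list_up - ab_up_so_far
    if ab_fill < 0 or not (0 <= ab_fill_up <= ab_fill):
        raise ValidationError("infeasible Abeta list direction totals")
    for d in _dirs(ab_fill, ab_fill_up):
        add(sf.mouse_only(), ab_dir=d)

    n_mod = sum(1 for g in genes if g.in_modifiers)
    if t.modifiers_list < n_mod:
        raise ValidationError("modifiers_list smaller than its planted members")
    for _ in range(t.modifiers_list - n_mod):
        add(sf.mouse_only(), in_modifiers=True)

    n_endo = sum(1 for g in genes if g.in_endo)
    if t.endo_list < n_endo:
        raise ValidationError("endo_list smaller than its planted members")
    for _ in range(t.endo_list - n_endo):
        add(sf.shared(), in_endo=True)

    n_gwas = sum(1 for g in genes if g.in_gwas)
    if t.gwas_list < n_gwas:
        raise ValidationError("gwas_list smaller than its planted members")
    for _ in range(t.gwas_list - n_gwas):
        add(sf.shared(), in_gwas=True)

    n_dmeg = sum(1 for g in genes if g.dmeg is not None)
    if t.dmeg_list < n_dmeg:
        raise ValidationError("dmeg_list smaller than its planted members")
    for _ in range(t.dmeg_list - n_dmeg):
        add(
            sf.shared(),
            dmeg={
                "methylation_direction": "hypo" if rng.random() < 0.5 else "hyper",
                "expression_direction": UP if rng.random() < 0.5 else DOWN,
                "promoter_dm": bool(rng.random() < 0.3),
            },
        )

    n_cbs = sum(1 for g in genes if g.cbs_dir is not None)
    if t.cbs_degs < n_cbs:
        raise ValidationError("cbs_degs smaller than its planted category hits")
    for i in range(t.cbs_degs - n_cbs):
        add(sf.mouse_only(), cbs_dir=UP if i % 2 else DOWN)

    # --- AD consensus fillers ---------------------------------------------------
    n_h = sum(1 for g in genes if g.human_dir is not None)
    h_up = sum(1 for g in genes if g.human_dir == UP)
    h_fill, h_fill_up = t.human_ad - n_h, t.human_ad_up - h_up
    if h_fill < 0 or not (0 <= h_fill_up <= h_fill):
        raise ValidationError("infeasible human AD direction totals")
    for d in _dirs(h_fill, h_fill_up):
        add(sf.shared(), human_dir=d)
    n_m = sum(1 for g in genes if g.mouse_dir is not None)
    m_up = sum(1 for g in genes if g.mouse_dir == UP)
    m_fill, m_fill_up = t.mouse_ad - n_m, t.mouse_ad_up - m_up
    if m_fill < 0 or not (0 <= m_fill_up <= m_fill):
        raise ValidationError("infeasible mouse AD direction totals")
    for d in _dirs(m_fill, m_fill_up):
        add(sf.mouse_only(), mouse_dir=d)

    if len(genes) > params.n_genes:
        raise ValidationError(
            f"planted structure needs {len(genes)} genes, universe is {params.n_genes}"
        )
    special["hhcy_cat_phagocytic"] = cat_a_symbols
    return genes, special


def _derive_truth(genes: list[_Gene], special: dict, category_a: str) -> SyntheticTruth:
    """Apply the cascade rules to the noiseless plant, independently of the
    pipeline implementation."""
    human = {g.symbol: g.human_dir for g in genes if g.human_dir}
    mouse = {g.symbol: g.mouse_dir for g in genes if g.mouse_dir}
    ab = {g.symbol: g.ab_dir for g in genes if g.ab_dir}
    in_ad = lambda g: g.human_dir is not None or g.mouse_dir is not None

    tiers: dict[str, frozenset[str]] = {}

    def put(name, syms):
        tiers[name] = frozenset(syms)

    put("human_ad", human)
    put("mouse_ad", mouse)
    put(
        "common_concordant",
        [s for s in human if s in mouse and human[s] == mouse[s]],
    )
    put(
        "common_discordant",
        [s for s in human if s in mouse and human[s] != mouse[s]],
    )
    put("ab_phago_human", [s for s in human if s in ab and human[s] == ab[s]])
    put("ab_phago_mouse", [s for s in mouse if s in ab and mouse[s] == ab[s]])
    put(
        "ab_phago_human_discordant",
        [s for s in human if s in ab and human[s] != ab[s]],
    )
    put(
        "ab_phago_mouse_discordant",
        [s for s in mouse if s in ab and mouse[s] != ab[s]],
    )
    put(
        "ab_phago_shared",
        tiers["ab_phago_human"] & tiers["ab_phago_mouse"],
    )
    put("phago_modifier", [g.symbol for g in genes if g.in_modifiers and in_ad(g)])
    put(
        "phago_modifier_human",
        [g.symbol for g in genes if g.in_modifiers and g.human_dir],
    )
    put(
        "phago_modifier_mouse",
        [g.symbol for g in genes if g.in_modifiers and g.mouse_dir],
    )
    put("endocytosis_human", [g.symbol for g in genes if g.in_endo and g.human_dir])
    put("endocytosis_mouse", [g.symbol for g in genes if g.in_endo and g.mouse_dir])
    put("endocytosis", tiers["endocytosis_human"] | tiers["endocytosis_mouse"])
    put(
        "endocytosis_common",
        tiers["endocytosis_human"] & tiers["endocytosis_mouse"],
    )
    put(
        "phagocytic_combined",
        tiers["ab_phago_human"]
        | tiers["ab_phago_mouse"]
        | tiers["phago_modifier"]
        | tiers["endocytosis"],
    )
    dmeg = {g.symbol: g.dmeg for g in genes if g.dmeg is not None}
    put("dmeg_endocytic", [s for s in dmeg if s in tiers["endocytosis"]])
    put("dmeg_ab", [s for s in dmeg if s in ab])
    put(
        "dmeg_modifier",
        [g.symbol for g in genes if g.dmeg is not None and g.in_modifiers],
    )
    put(
        "dmeg_combined",
        tiers["dmeg_endocytic"] | tiers["dmeg_ab"] | tiers["dmeg_modifier"],
    )
    put(
        "dmeg_hypomethylated",
        [
            s
            for s in tiers["dmeg_combined"]
            if dmeg[s]["methylation_direction"] == "hypo"
        ],
    )
    put(
        "dmeg_promoter_hypo",
        [s for s in tiers["dmeg_hypomethylated"] if dmeg[s]["promoter_dm"]],
    )
    put("gwas_mg_human", [g.symbol for g in genes if g.in_gwas and g.human_dir])
    put("gwas_mg_mouse", [g.symbol for g in genes if g.in_gwas and g.mouse_dir])
    put("gwas_mg", tiers["gwas_mg_human"] | tiers["gwas_mg_mouse"])
    put("gwas_shared", tiers["gwas_mg_human"] & tiers["gwas_mg_mouse"])
    put(
        "gwas_phagocytic",
        [
            g.symbol
            for g in genes
            if g.in_gwas and g.symbol in tiers["phagocytic_combined"]
        ],
    )
    cbs = frozenset(g.symbol for g in genes if g.cbs_dir is not None)
    put("cbs_degs", cbs)
    cat_a_tier = (
        tiers["phagocytic_combined"] if category_a == "combined" else tiers["endocytosis"]
    )
    put("hhcy_cat_phagocytic", cbs & cat_a_tier)
    put("hhcy_cat_ab_mg", cbs & frozenset(ab))
    put(
        "hhcy_cat_modifier",
        [g.symbol for g in genes if g.cbs_dir and g.in_modifiers],
    )
    put("hhcy_cat_dmeg_hypo", cbs & tiers["dmeg_hypomethylated"])
    put("hhcy_cat_gwas_phagocytic", cbs & tiers["gwas_phagocytic"])
    put(
        "hhcy_phagocytic",
        tiers["hhcy_cat_phagocytic"]
        | tiers["hhcy_cat_ab_mg"]
        | tiers["hhcy_cat_modifier"]
        | tiers["hhcy_cat_dmeg_hypo"]
        | tiers["hhcy_cat_gwas_phagocytic"],
    )
    markers = {k: v for k, v in special.items() if isinstance(v, str)}
    return SyntheticTruth(tiers=tiers, markers=markers)


def _magnitude(params: SimParams, rng: np.random.Generator) -> float:
    for _ in range(200):
        m = float(rng.lognormal(params.fc_mu, params.fc_sigma))
        if m >= params.fc_min:
            return m
    return params.fc_min


def _planted_p(params: SimParams, rng: np.random.Generator) -> float:
    return float(rng.beta(params.planted_p_beta_a, 1.0)) * params.p_threshold * (1 - 1e-9)


def _record(
    symbol: str,
    species: str,
    dataset_id: str,
    direction: str,
    magnitude: float,
    p: float,
    p_field: str,
) -> DEGRecord:
    fc = magnitude if direction == UP else -magnitude
    kwargs = {"adj_p": p, "p_value": p / 2} if p_field == "adjusted" else {"p_value": p}
    return DEGRecord(
        symbol=symbol, species=species, dataset_id=dataset_id, fc=fc, **kwargs
    )


def _species_tables(
    genes: list[_Gene],
    species: str,
    n_datasets: int,
    params: SimParams,
    rng: np.random.Generator,
    n_conflict: int,
    n_low_support: int,
    sf_start: int,
) -> list[DEGTable]:
    dir_attr = "human_dir" if species == HUMAN else "mouse_dir"
    caser = (lambda s: s) if species == HUMAN else (lambda s: s.capitalize())
    ids = [f"{species}_ds{i + 1}" for i in range(n_datasets)]
    per_dataset: list[list[DEGRecord]] = [[] for _ in ids]

    for g in genes:
        d = getattr(g, dir_attr)
        if d is None:
            continue
        for k, ds in enumerate(ids):
            if rng.random() >= params.detect_prob:
                continue
            call_dir = d
            if rng.random() < params.direction_flip_prob:
                call_dir = DOWN if call_dir == UP else UP
            per_dataset[k].append(
                _record(
                    caser(g.symbol), species, ds,
                    call_dir, _magnitude(params, rng), _planted_p(params, rng),
                    "adjusted",
                )
            )

    counter = sf_start
    for i in range(n_conflict):
        counter += 1
        sym = caser(f"DECOYC{species[0].upper()}{counter:05d}")
        a, b = rng.choice(n_datasets, size=2, replace=False)
        per_dataset[a].append(
            _record(sym, species, ids[a], UP, _magnitude(params, rng),
                    _planted_p(params, rng), "adjusted")
        )
        per_dataset[b].append(
            _record(sym, species, ids[b], DOWN, _magnitude(params, rng),
                    _planted_p(params, rng), "adjusted")
        )
    for i in range(params.n_decoy_subthreshold):
        counter += 1
        sym = caser(f"DECOYS{species[0].upper()}{counter:05d}")
        k = int(rng.integers(n_datasets))
        d = UP if i % 2 else DOWN
        if i % 2:  # magnitude below the fold-change cutoff
            mag = float(rng.uniform(1.02, params.fc_min - 0.02))
            p = _planted_p(params, rng)
        else:  # non-significant p
            mag = _magnitude(params, rng)
            p = float(rng.uniform(params.p_threshold * 1.5, 1.0))
        per_dataset[k].append(_record(sym, species, ids[k], d, mag, p, "adjusted"))
    for i in range(n_low_support):
        counter += 1
        sym = caser(f"DECOYL{species[0].upper()}{counter:05d}")
        k = int(rng.integers(n_datasets))
        per_dataset[k].append(
            _record(sym, species, ids[k], UP if i % 2 else DOWN,
                    _magnitude(params, rng), _planted_p(params, rng), "adjusted")
        )

    return [
        DEGTable(dataset_id=ds, species=species, records=recs)
        for ds, recs in zip(ids, per_dataset)
    ]


def simulate_compendium(
    params: Optional[SimParams] = None, category_a: str = "endocytosis"
) -> SimulatedCompendium:
    """Generate a full synthetic input compendium plus its planted truth.

    All outputs are deterministic functions of ``params`` (including its
    seed). With ``detect_prob=1`` and ``direction_flip_prob=0`` the cascade
    recovers every truth tier exactly.
    """
    params = params or SimParams()
    rng = np.random.default_rng(params.seed)
    genes, special = _plant(params, rng)
    truth = _derive_truth(genes, special, category_a)

    human_tables = _species_tables(
        genes, HUMAN, params.n_human_datasets, params, rng,
        params.n_decoy_conflict_human, 0, 0,
    )
    mouse_tables = _species_tables(
        genes, MOUSE, params.n_mouse_datasets, params, rng,
        params.n_decoy_conflict_mouse, params.n_decoy_low_support_mouse, 0,
    )

    ab_members: dict[str, GeneEntry] = {}
    for g in sorted((g for g in genes if g.ab_dir), key=lambda g: g.symbol):
        mag = _magnitude(params, rng)
        ab_members[g.symbol] = GeneEntry(
            direction=g.ab_dir,
            avg_fc=mag if g.ab_dir == UP else -mag,
            sources=(AB_SOURCE,),
            source_directions=((AB_SOURCE, g.ab_dir),),
        )
    ab_set = RegulatedGeneSet("ab_mg_degs", MOUSE, ab_members)

    modifiers = AnnotatedGeneList(
        "phagocytosis_modifiers",
        frozenset(g.symbol for g in genes if g.in_modifiers),
    )
    endo = AnnotatedGeneList(
        "endocytosis_genes", frozenset(g.symbol for g in genes if g.in_endo)
    )
    gwas = AnnotatedGeneList(
        "gwas_ad_genes", frozenset(g.symbol for g in genes if g.in_gwas)
    )
    dmeg = AnnotatedGeneList(
        "ad_dmeg",
        frozenset(g.symbol for g in genes if g.dmeg is not None),
        {g.symbol: dict(g.dmeg) for g in genes if g.dmeg is not None},
    )

    cbs_records = []
    for g in (g for g in genes if g.cbs_dir is not None):
        if g.cbs_fc is not None:
            fc = g.cbs_fc
        else:
            mag = _magnitude(params, rng)
            fc = mag if g.cbs_dir == UP else -mag
        cbs_records.append(
            DEGRecord(
                symbol=g.symbol.capitalize(),
                species=MOUSE,
                dataset_id=CBS_SOURCE,
                fc=fc,
                p_value=_planted_p(params, rng),
            )
        )
    cbs_table = DEGTable(dataset_id=CBS_SOURCE, species=MOUSE, records=cbs_records)

    return SimulatedCompendium(
        human_tables=human_tables,
        mouse_tables=mouse_tables,
        gene_lists={"ab_mg": ab_set, "modifiers": modifiers, "endocytosis": endo},
        dmeg_list=dmeg,
        gwas_list=gwas,
        cbs_table=cbs_table,
        truth=truth,
        params=params,
    )


def degrade(
    tables: Sequence[DEGTable],
    detect_prob: float,
    direction_flip_prob: float,
    seed: int,
) -> list[DEGTable]:
    """Thin and perturb DEG tables: drop each call with probability
    ``1 - detect_prob``, flip its direction with ``direction_flip_prob``."""
    if not (0.0 <= detect_prob <= 1.0 and 0.0 <= direction_flip_prob <= 1.0):
        raise ValidationError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for table in tables:
        kept = []
        for rec in table:
            if rng.random() >= detect_prob:
                continue
            if rng.random() < direction_flip_prob:
                rec = DEGRecord(
                    symbol=rec.symbol,
                    species=rec.species,
                    dataset_id=rec.dataset_id,
                    fc=None if rec.fc is None else -rec.fc,
                    p_value=rec.p_value,
                    adj_p=rec.adj_p,
                    direction=(
                        None
                        if rec.direction is None
                        else (DOWN if rec.direction == UP else UP)
                    ),
                )
            kept.append(rec)
        out.append(DEGTable(dataset_id=table.dataset_id, species=table.species, records=kept))
    return out
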