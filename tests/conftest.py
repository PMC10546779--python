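import numpy as np
import pytest

from mgcascade.cascade import run_cascade
from mgcascade.model import DEGRecord, DEGTable, GeneEntry, RegulatedGeneSet
from mgcascade.synthetic import SimParams, TierSizes, simulate_compendium

#: a small but fully consistent tier geometry for fast tests
SMALL_TIERS = TierSizes(
    human_ad=60, human_ad_up=35,
    mouse_ad=90, mouse_ad_up=50,
    common_concordant=12, common_concordant_up=7, common_discordant=6,
    ab_list=50, ab_list_up=25,
    ab_phago_human=6, ab_phago_human_up=4,
    ab_phago_mouse=14, ab_phago_mouse_up=8,
    ab_phago_shared=3, ab_phago_human_discordant=4,
    modifiers_list=30, modifier_tier=5, modifier_common=1,
    endo_list=120, endo_human=12, endo_mouse=24,
    endo_common=5, endo_common_concordant=4, endo_common_concordant_up=3,
    phagocytic_combined=49,
    dmeg_list=40, dmeg_endocytic=4, dmeg_ab=4, dmeg_modifier=3,
    dmeg_combined=9, dmeg_hypomethylated=6, dmeg_hypomethylated_up=5,
    dmeg_promoter_hypo=2,
    gwas_list=40, gwas_human=6, gwas_mouse=8,
    gwas_shared=2, gwas_shared_up=2, gwas_phagocytic=6,
    cbs_degs=30,
    hhcy_cat_phagocytic=2, hhcy_cat_ab=2, hhcy_cat_modifier=2,
)


def small_params(seed: int = 7, **overrides) -> SimParams:
    defaults = dict(
        seed=seed,
        n_genes=2000,
        tiers=SMALL_TIERS,
        n_decoy_conflict_human=5,
        n_decoy_conflict_mouse=8,
        n_decoy_subthreshold=10,
        n_decoy_low_support_mouse=6,
    )
    defaults.update(overrides)
    return SimParams(**defaults)


def cascade_of(sim, **kwargs):
    return run_cascade(
        sim.human_tables,
        sim.mouse_tables,
        sim.gene_lists["ab_mg"],
        sim.gene_lists["modifiers"],
        sim.gene_lists["endocytosis"],
        sim.dmeg_list,
        sim.gwas_list,
        sim.cbs_table,
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_sim():
    return simulate_compendium(small_params())


@pytest.fixture(scope="session")
def small_result(small_sim):
    return cascade_of(small_sim)


@pytest.fixture(scope="session")
def study_sim():
    """Compendium planted at the published study's tier geometry."""
    return simulate_compendium(SimParams(seed=11))


@pytest.fixture(scope="session")
def study_result(study_sim):
    return cascade_of(study_sim)


def make_set(name: str, species: str, members: dict) -> RegulatedGeneSet:
    """Build a regulated set from {symbol: (direction, avg_fc)} shorthand."""
    return RegulatedGeneSet(
        name=name,
        species=species,
        members={
            sym: GeneEntry(
                direction=d,
                avg_fc=fc,
                sources=(name,),
                source_directions=((name, d),),
            )
            for sym, (d, fc) in members.items()
        },
    )


def make_table(dataset_id: str, species: str, rows) -> DEGTable:
    """rows: iterable of (symbol, fc, p, adj_p)."""
    return DEGTable(
        dataset_id=dataset_id,
        species=species,
        records=[
            DEGRecord(
                symbol=sym, species=species, dataset_id=dataset_id,
                fc=fc, p_value=p, adj_p=adj,
            )
            for sym, fc, p, adj in rows
        ],
    )


def random_geneset(
    rng: np.random.Generator,
    name: str,
    n: int,
    universe: int = 400,
    species: str = "cross",
) -> RegulatedGeneSet:
    symbols = rng.choice(universe, size=min(n, universe), replace=False)
    members = {}
    for i in sorted(symbols):
        sym = f"G{i:04d}"
        d = "up" if rng.random() < 0.5 else "down"
        mag = float(1.5 + rng.random() * 3)
        members[sym] = GeneEntry(
            direction=d,
            avg_fc=mag if d == "up" else -mag,
            sources=(name,),
            source_directions=((name, d),),
        )
    return RegulatedGeneSet(name=name, species=species, members=members)
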