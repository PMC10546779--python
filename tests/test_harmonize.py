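"""Symbol normalization, DEG criteria, and consensus-merge rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgcascade.harmonize import (
    ConsensusConfig,
    apply_deg_criteria,
    apply_ortholog_map,
    collapse_duplicates,
    consensus_merge,
    normalize_symbol,
)
from mgcascade.model import DEGRecord, DEGTable, ValidationError

from .conftest import make_table

ADJ = ConsensusConfig(p_field="adjusted")


@pytest.mark.parametrize(
    "raw,expected",
    [("Trem2", "TREM2"), ("  Apoe ", "APOE"), ("tReM2", "TREM2"), ("H 2-D1", "H2-D1")],
)
def test_normalize_symbol_examples(raw, expected):
    assert normalize_symbol(raw) == expected


@given(st.text(alphabet=st.characters(categories=["L", "N"]), min_size=1, max_size=20))
@settings(max_examples=200, derandomize=True)
def test_normalize_symbol_idempotent(raw):
    once = normalize_symbol(raw)
    assert normalize_symbol(once) == once
    assert once == once.strip().upper()


@pytest.mark.parametrize("raw", ["", "   ", "\t\n"])
def test_normalize_symbol_rejects_blank(raw):
    with pytest.raises(ValidationError):
        normalize_symbol(raw)


def test_deg_criteria_boundaries():
    """FC cutoff is inclusive (>= 1.5); the p cutoff is strict (< 0.05)."""
    table = make_table(
        "d1",
        "human",
        [
            ("KEEP1", 1.5, None, 0.049),       # exactly at the FC threshold
            ("DROP_P", 2.0, None, 0.05),       # p not strictly below
            ("DROP_FC", 1.49, None, 0.001),
            ("KEEP2", -1.5, None, 0.01),       # magnitude counts, not sign
            ("DROP_NA", 3.0, None, None),      # missing configured p-value
        ],
    )
    out = apply_deg_criteria(table, ADJ)
    assert [r.symbol for r in out] == ["KEEP1", "KEEP2"]
    assert out.meta["n_dropped_missing_p"] == 1
    assert out.meta["n_failed_criteria"] == 2
    # raw-p configuration consults the other field
    raw_cfg = ConsensusConfig(p_field="raw")
    assert len(apply_deg_criteria(table, raw_cfg)) == 0


def test_deg_criteria_matches_record_by_record_filter():
    rng = np.random.default_rng(42)
    rows = []
    for i in range(200):
        mag = float(rng.uniform(1.0, 4.0))
        fc = mag if rng.random() < 0.5 else -mag
        rows.append((f"G{i}", fc, None, float(rng.uniform(0, 0.2))))
    table = make_table("d1", "human", rows)
    expected = {
        sym for sym, fc, _, adj in rows if abs(fc) >= 1.5 and adj < 0.05
    }
    out = apply_deg_criteria(table, ADJ)
    assert {r.symbol for r in out} == expected
    assert out.meta["n_retained"] + out.meta["n_failed_criteria"] == len(rows)


def test_consensus_min_support_and_conflicts():
    cfg = ConsensusConfig(min_support=2)
    tables = [
        make_table("m1", "mouse", [("Aaa", 2.0, None, 0.01), ("Bbb", 2.0, None, 0.01),
                                   ("Ccc", 2.0, None, 0.01)]),
        make_table("m2", "mouse", [("Aaa", 3.0, None, 0.01), ("Bbb", -2.0, None, 0.01)]),
        make_table("m3", "mouse", [("Ddd", 2.0, None, 0.01)]),
    ]
    merged = consensus_merge(tables, cfg)
    # Aaa: supported twice, concordant, mean FC
    assert merged.members["AAA"].avg_fc == pytest.approx(2.5)
    assert merged.members["AAA"].sources == ("m1", "m2")
    # Bbb: direction conflict across datasets -> excluded
    # Ccc, Ddd: support 1 < 2 -> excluded
    assert merged.symbols() == {"AAA"}


def test_consensus_single_table_is_its_gene_set():
    t = make_table("h1", "human", [("A", 2.0, None, 0.01), ("B", -1.6, None, 0.02)])
    merged = consensus_merge([t], ConsensusConfig(min_support=1))
    assert merged.symbols() == {"A", "B"}
    assert merged.members["B"].direction == "down"


def test_consensus_matches_nested_loop_tally():
    rng = np.random.default_rng(13)
    n_genes, n_tables = 120, 4
    tables = []
    calls: dict[str, list[str]] = {}
    for t in range(n_tables):
        rows = []
        for g in range(n_genes):
            if rng.random() < 0.4:
                d = "up" if rng.random() < 0.6 else "down"
                mag = float(rng.uniform(1.5, 4))
                rows.append((f"G{g}", mag if d == "up" else -mag, None, 0.01))
                calls.setdefault(f"G{g}", []).append(d)
        tables.append(make_table(f"t{t}", "mouse", rows))
    for min_support in (1, 2, 3):
        cfg = ConsensusConfig(min_support=min_support)
        expected = {
            s for s, ds in calls.items()
            if len(ds) >= min_support and len(set(ds)) == 1
        }
        assert consensus_merge(tables, cfg).symbols() == expected


def test_consensus_monotone_in_min_support():
    rng = np.random.default_rng(5)
    tables = []
    for t in range(5):
        rows = []
        for g in range(80):
            if rng.random() < 0.5:
                mag = float(rng.uniform(1.5, 3))
                rows.append((f"G{g}", mag if rng.random() < 0.7 else -mag, None, 0.01))
        tables.append(make_table(f"t{t}", "human", rows))
    sizes = [
        len(consensus_merge(tables, ConsensusConfig(min_support=k)))
        for k in range(1, 6)
    ]
    assert sizes == sorted(sizes, reverse=True)


def test_consensus_self_duplication_invariance():
    """Doubling the compendium and the support rule leaves membership fixed."""
    rng = np.random.default_rng(3)
    tables = []
    for t in range(3):
        rows = []
        for g in range(60):
            if rng.random() < 0.5:
                mag = float(rng.uniform(1.5, 3))
                rows.append((f"G{g}", mag if rng.random() < 0.7 else -mag, None, 0.01))
        tables.append(make_table(f"t{t}", "mouse", rows))
    doubled = tables + [
        DEGTable(f"{t.dataset_id}_copy", t.species, [
            DEGRecord(symbol=r.symbol, species=r.species,
                      dataset_id=f"{t.dataset_id}_copy", fc=r.fc,
                      p_value=r.p_value, adj_p=r.adj_p)
            for r in t
        ])
        for t in tables
    ]
    base = consensus_merge(tables, ConsensusConfig(min_support=2)).symbols()
    scaled = consensus_merge(doubled, ConsensusConfig(min_support=4)).symbols()
    assert base == scaled


def test_consensus_rejects_mixed_species_and_duplicate_ids():
    h = make_table("a", "human", [("A", 2.0, None, 0.01)])
    m = make_table("b", "mouse", [("A", 2.0, None, 0.01)])
    with pytest.raises(ValidationError):
        consensus_merge([h, m], ConsensusConfig())
    with pytest.raises(ValidationError):
        consensus_merge([h, h], ConsensusConfig())


def test_within_table_duplicates_collapse_to_smallest_p():
    table = make_table(
        "d", "human",
        [("Dup", 2.0, None, 0.04), ("DUP", 3.0, None, 0.001),
         ("Conf", 2.0, None, 0.01), ("conf", -2.0, None, 0.02),
         ("Solo", 1.8, None, 0.03)],
    )
    collapsed = collapse_duplicates(table, ADJ)
    by_symbol = {normalize_symbol(r.symbol): r for r in collapsed}
    assert by_symbol["DUP"].fc == 3.0  # the smaller-p record wins
    assert "CONF" not in by_symbol     # within-table direction conflict
    assert collapsed.meta["conflict_symbols"] == ["CONF"]


def test_direction_only_records_join_without_magnitude():
    t = DEGTable("d", "human", [
        DEGRecord(symbol="A", species="human", dataset_id="d", direction="up"),
        DEGRecord(symbol="B", species="human", dataset_id="d", fc=2.0),
    ])
    merged = consensus_merge([t], ConsensusConfig(min_support=1))
    assert merged.members["A"].avg_fc is None
    assert merged.members["A"].direction == "up"
    assert merged.members["B"].avg_fc == 2.0


def test_log2_average_scale_switch():
    tables = [
        make_table("a", "human", [("G", 2.0, None, 0.01)]),
        make_table("b", "human", [("G", 8.0, None, 0.01)]),
    ]
    linear = consensus_merge(tables, ConsensusConfig(min_support=2))
    log2 = consensus_merge(
        tables, ConsensusConfig(min_support=2, fc_average_scale="log2")
    )
    assert linear.members["G"].avg_fc == pytest.approx(5.0)
    assert log2.members["G"].avg_fc == pytest.approx(4.0)  # geometric mean


def test_ortholog_map_translates_symbols():
    t = make_table("m", "mouse", [("Gene1", 2.0, None, 0.01)])
    merged = consensus_merge([t], ConsensusConfig())
    mapped = apply_ortholog_map(merged, {"Gene1": "HUMGENE1"})
    assert mapped.symbols() == {"HUMGENE1"}
    assert mapped.members["HUMGENE1"].direction == "up"
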