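"""Symbol normalization, DEG filtering, and multi-dataset consensus merging.

Consensus rule: a gene enters the per-species consensus set iff it was called
in at least ``min_support`` datasets *and* every call agrees in direction;
direction conflicts across datasets exclude the gene outright. Human AD
microglia sets use ``min_support=1`` (union minus conflicts over the four
patient datasets); mouse sets require support in at least two of the seven
model datasets, reflecting the genetic similarity of APP/PS1-type models.
The retained genes are assigned the average fold change over their
supporting datasets.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    DOWN,
    UP,
    DEGRecord,
    DEGTable,
    GeneEntry,
    RegulatedGeneSet,
    ValidationError,
    log2_from_signed_fc,
    signed_fc_from_log2,
)


def normalize_symbol(raw: str) -> str:
    """Normalize a gene identifier: trim, uppercase, strip internal whitespace.

    Idempotent; matches human symbols ("TREM2") to mouse symbols ("Trem2").
    """
    if raw is None:
        raise ValidationError("gene symbol is missing")
    sym = "".join(str(raw).split()).upper()
    if not sym:
        raise ValidationError(f"gene symbol {raw!r} empty after normalization")
    return sym


@dataclass(frozen=True)
class ConsensusConfig:
    """Thresholds and support rules for DEG filtering and consensus merging.

    fc_threshold
        minimum linear fold-change magnitude, inclusive (default 1.5).
    p_field
        which p-value the filter consults: ``"raw"`` or ``"adjusted"``.
    p_threshold
        strict upper bound on the consulted p-value (default 0.05).
    min_support
        minimum number of supporting datasets (human rule 1, mouse rule 2).
    conflict_policy
        only ``"exclude"`` is defined: cross-dataset direction conflicts
        drop the gene.
    fc_average_scale
        ``"linear"`` averages signed fold changes arithmetically;
        ``"log2"`` averages signed log2 fold changes and converts back.
    """

    fc_threshold: float = 1.5
    p_field: str = "adjusted"
    p_threshold: float = 0.05
    min_support: int = 1
    conflict_policy: str = "exclude"
    fc_average_scale: str = "linear"

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1.0:
            raise ValidationError("fc_threshold must be > 1")
        if not (0.0 < self.p_threshold < 1.0):
            raise ValidationError("p_threshold must be in (0, 1)")
        if self.p_field not in ("raw", "adjusted"):
            raise ValidationError(f"unknown p_field {self.p_field!r}")
        if self.min_support < 1:
            raise ValidationError("min_support must be >= 1")
        if self.conflict_policy != "exclude":
            raise ValidationError(f"unsupported conflict_policy {self.conflict_policy!r}")
        if self.fc_average_scale not in ("linear", "log2"):
            raise ValidationError(f"unknown fc_average_scale {self.fc_average_scale!r}")

    def p_of(self, record: DEGRecord) -> Optional[float]:
        return record.p_value if self.p_field == "raw" else record.adj_p

    @classmethod
    def from_mapping(cls, data: Mapping) -> "ConsensusConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in dict(data).items() if k in known})


def apply_deg_criteria(table: DEGTable, cfg: ConsensusConfig) -> DEGTable:
    """Retain records with |FC| >= fc_threshold and p < p_threshold.

    The fold-change bound is inclusive, the p bound strict. Records lacking
    the configured p-value field, or lacking a fold-change magnitude, cannot
    demonstrate the criteria and are dropped; drop counts are recorded in the
    returned table's ``meta``.
    """
    kept: list[DEGRecord] = []
    n_missing_p = n_missing_fc = n_failed = 0
    for rec in table:
        p = cfg.p_of(rec)
        if p is None:
            n_missing_p += 1
            continue
        if rec.magnitude is None:
            n_missing_fc += 1
            continue
        if rec.magnitude >= cfg.fc_threshold and p < cfg.p_threshold:
            kept.append(rec)
        else:
            n_failed += 1
    return DEGTable(
        dataset_id=table.dataset_id,
        species=table.species,
        records=kept,
        meta={
            "n_input": len(table),
            "n_retained": len(kept),
            "n_dropped_missing_p": n_missing_p,
            "n_dropped_missing_fc": n_missing_fc,
            "n_failed_criteria": n_failed,
        },
    )


def collapse_duplicates(table: DEGTable, cfg: ConsensusConfig) -> DEGTable:
    """Collapse repeated symbols within one table.

    Duplicates with a consistent direction collapse to the record with the
    smallest configured p-value (ties broken by larger magnitude, then input
    order); duplicates with conflicting directions drop the gene from this
    table entirely, recorded in ``meta["conflict_symbols"]``.
    """
    groups: dict[str, list[tuple[int, DEGRecord]]] = {}
    for i, rec in enumerate(table):
        groups.setdefault(normalize_symbol(rec.symbol), []).append((i, rec))

    kept: list[tuple[int, DEGRecord]] = []
    conflicts: list[str] = []
    for sym, recs in groups.items():
        dirs = {r.direction for _, r in recs}
        if len(dirs) > 1:
            conflicts.append(sym)
            continue

        def rank(item: tuple[int, DEGRecord]) -> tuple:
            i, r = item
            p = cfg.p_of(r)
            if p is None:
                p = r.p_value if r.p_value is not None else r.adj_p
            mag = r.magnitude or 1.0
            return (p if p is not None else 2.0, -mag, i)

        kept.append(min(recs, key=rank))
    kept.sort(key=lambda item: item[0])
    return DEGTable(
        dataset_id=table.dataset_id,
        species=table.species,
        records=[r for _, r in kept],
        meta={**table.meta, "conflict_symbols": sorted(conflicts)},
    )


def _average_fc(fcs: Sequence[float], scale: str) -> Optional[float]:
    if not fcs:
        return None
    if scale == "linear":
        return statistics.fmean(fcs)
    mean_l2 = statistics.fmean(log2_from_signed_fc(f) for f in fcs)
    return signed_fc_from_log2(mean_l2)


def consensus_merge(
    tables: Sequence[DEGTable], cfg: ConsensusConfig, name: Optional[str] = None
) -> RegulatedGeneSet:
    """Merge same-species per-dataset DEG tables into one consensus set.

    Membership: called in >= ``min_support`` tables, all calls concordant.
    Fold change: average of signed FCs over supporting datasets that report
    a magnitude (direction-only rows support membership but are excluded
    from the average). Output is sorted lexicographically by symbol.
    """
    if not tables:
        raise ValidationError("consensus_merge needs at least one table")
    species = tables[0].species
    if any(t.species != species for t in tables):
        raise ValidationError("consensus_merge received mixed-species tables")
    seen_ids = [t.dataset_id for t in tables]
    if len(set(seen_ids)) != len(seen_ids):
        raise ValidationError(f"duplicate dataset ids in input: {seen_ids}")

    calls: dict[str, list[DEGRecord]] = {}
    for table in tables:
        for rec in collapse_duplicates(table, cfg):
            calls.setdefault(normalize_symbol(rec.symbol), []).append(rec)

    members: dict[str, GeneEntry] = {}
    for sym in sorted(calls):
        recs = calls[sym]
        if len(recs) < cfg.min_support:
            continue
        dirs = {r.direction for r in recs}
        if len(dirs) > 1:
            continue  # cross-dataset direction conflict: excluded
        direction = dirs.pop()
        avg = _average_fc([r.fc for r in recs if r.fc is not None], cfg.fc_average_scale)
        members[sym] = GeneEntry(
            direction=direction,
            avg_fc=avg,
            sources=tuple(sorted(r.dataset_id for r in recs)),
            source_directions=tuple(
                sorted((r.dataset_id, r.direction) for r in recs)
            ),
        )
    return RegulatedGeneSet(
        name=name or f"{species}_consensus", species=species, members=members
    )


def apply_ortholog_map(
    geneset: RegulatedGeneSet, mapping: Mapping[str, str]
) -> RegulatedGeneSet:
    """Rename members through an explicit ortholog table (source -> target).

    Symbols absent from the mapping keep their normalized form, preserving
    the default case-insensitive string matching. A mapping that merges two
    members with conflicting directions raises.
    """
    norm_map = {normalize_symbol(k): normalize_symbol(v) for k, v in mapping.items()}
    members: dict[str, GeneEntry] = {}
    for sym in geneset.sorted_symbols():
        target = norm_map.get(sym, sym)
        entry = geneset.members[sym]
        if target in members and members[target].direction != entry.direction:
            raise ValidationError(
                f"ortholog map merges {sym!r} into {target!r} with a direction conflict"
            )
        members[target] = entry
    return RegulatedGeneSet(name=geneset.name, species=geneset.species, members=members)
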