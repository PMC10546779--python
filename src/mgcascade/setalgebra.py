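"""Direction-aware, provenance-tracking algebra over regulated gene sets.

Every cascade stage reduces to four primitives: the concordant and
discordant intersections of two regulated sets, the overlap of a regulated
set with a direction-free curated list, and the provenance-keeping union.
For any pair of regulated sets, concordant + discordant partitions the plain
symbol intersection; genes lacking a direction on either side are excluded
from both and reported.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

from .model import CROSS, AnnotatedGeneList, GeneEntry, RegulatedGeneSet

SetLike = Union[AnnotatedGeneList, RegulatedGeneSet]


def _list_symbols(l: SetLike) -> frozenset[str]:
    return l.symbols if isinstance(l, AnnotatedGeneList) else l.symbols()


def _cross_species(a: RegulatedGeneSet, b: RegulatedGeneSet) -> str:
    return a.species if a.species == b.species else CROSS


def _merged_entry(sym: str, a: RegulatedGeneSet, b: RegulatedGeneSet) -> GeneEntry:
    ea, eb = a.members[sym], b.members[sym]
    return GeneEntry(
        direction=ea.direction,
        avg_fc=ea.avg_fc,
        sources=tuple(sorted(set(ea.sources) | set(eb.sources))),
        source_directions=tuple(
            sorted(set(ea.source_directions) | set(eb.source_directions)
                   | {(a.name, ea.direction), (b.name, eb.direction)})
        ),
    )


@dataclass
class OverlapResult:
    """Concordant/discordant split of the symbol intersection of two sets."""

    concordant: RegulatedGeneSet
    discordant: RegulatedGeneSet
    #: symbols present in both sets but direction-free on at least one side
    undirected: frozenset[str]


def overlap(a: RegulatedGeneSet, b: RegulatedGeneSet, name: str = "") -> OverlapResult:
    shared = sorted(a.symbols() & b.symbols())
    conc: dict[str, GeneEntry] = {}
    disc: dict[str, GeneEntry] = {}
    undirected = []
    for sym in shared:
        da, db = a.members[sym].direction, b.members[sym].direction
        if da is None or db is None:
            undirected.append(sym)
        elif da == db:
            conc[sym] = _merged_entry(sym, a, b)
        else:
            disc[sym] = _merged_entry(sym, a, b)
    species = _cross_species(a, b)
    base = name or f"{a.name}&{b.name}"
    return OverlapResult(
        concordant=RegulatedGeneSet(f"{base}:concordant", species, conc),
        discordant=RegulatedGeneSet(f"{base}:discordant", species, disc),
        undirected=frozenset(undirected),
    )


def intersect_concordant(
    a: RegulatedGeneSet, b: RegulatedGeneSet, name: Optional[str] = None
) -> RegulatedGeneSet:
    """Genes in both sets with equal direction; provenance merged from both.

    The left side's average FC is retained; each side's recorded direction
    is kept in the per-gene provenance.
    """
    result = overlap(a, b).concordant
    if name:
        result.name = name
    return result


def intersect_discordant(
    a: RegulatedGeneSet, b: RegulatedGeneSet, name: Optional[str] = None
) -> RegulatedGeneSet:
    """Genes in both sets with opposite directions."""
    result = overlap(a, b).discordant
    if name:
        result.name = name
    return result


def intersect_symbols(
    a: RegulatedGeneSet, b: RegulatedGeneSet, name: Optional[str] = None
) -> RegulatedGeneSet:
    """Direction-blind symbol intersection (concordant plus discordant)."""
    res = overlap(a, b)
    return union_sets([res.concordant, res.discordant], name=name or f"{a.name}&{b.name}")


def overlap_with_list(
    s: RegulatedGeneSet, l: SetLike, name: Optional[str] = None
) -> RegulatedGeneSet:
    """Members of ``s`` whose symbol appears in the curated list ``l``.

    Directions, fold changes, and provenance are carried from ``s``; the
    list's name is appended to each member's sources.
    """
    keep = _list_symbols(l)
    lname = l.name
    members: dict[str, GeneEntry] = {}
    for sym in s.sorted_symbols():
        if sym in keep:
            e = s.members[sym]
            members[sym] = GeneEntry(
                direction=e.direction,
                avg_fc=e.avg_fc,
                sources=tuple(sorted(set(e.sources) | {lname})),
                source_directions=e.source_directions,
                ambiguous=e.ambiguous,
            )
    return RegulatedGeneSet(name or f"{s.name}&{lname}", s.species, members)


def union_sets(
    sets: Sequence[RegulatedGeneSet], name: Optional[str] = None
) -> RegulatedGeneSet:
    """Symbol union keeping all provenance.

    A gene appearing in several inputs with one consistent direction keeps
    it (average FC = mean of the available per-input averages); if input
    directions conflict the gene is retained, flagged ambiguous, with the
    direction recorded per source.
    """
    order: list[str] = []
    pools: dict[str, list[GeneEntry]] = {}
    for s in sets:
        for sym in s.sorted_symbols():
            if sym not in pools:
                pools[sym] = []
                order.append(sym)
            pools[sym].append(s.members[sym])

    species = {s.species for s in sets}
    out_species = species.pop() if len(species) == 1 else CROSS
    members: dict[str, GeneEntry] = {}
    for sym in sorted(order):
        entries = pools[sym]
        dirs = {e.direction for e in entries}
        sources = tuple(sorted({src for e in entries for src in e.sources}))
        src_dirs = tuple(
            sorted({sd for e in entries for sd in e.source_directions})
        )
        if len(dirs) == 1 and None not in dirs:
            fcs = [e.avg_fc for e in entries if e.avg_fc is not None]
            members[sym] = GeneEntry(
                direction=dirs.pop(),
                avg_fc=statistics.fmean(fcs) if fcs else None,
                sources=sources,
                source_directions=src_dirs,
                ambiguous=any(e.ambiguous for e in entries),
            )
        else:
            members[sym] = GeneEntry(
                direction=None,
                avg_fc=None,
                sources=sources,
                source_directions=src_dirs,
                ambiguous=True,
            )
    return RegulatedGeneSet(name or "union", out_species, members)


def venn_counts(sets: Sequence[RegulatedGeneSet]) -> dict[str, int]:
    """Disjoint-region counts for 2 or 3 regulated sets.

    Regions are labelled by the names of the sets whose exclusive overlap
    they represent, joined by ``&`` (e.g. ``"A&B"`` is in-A-and-B-not-C).
    Region counts sum to the size of the symbol union.
    """
    if not (2 <= len(sets) <= 3):
        raise ValueError(f"venn_counts supports 2 or 3 sets, got {len(sets)}")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        names = [f"{n}#{i}" for i, n in enumerate(names)]
    symbol_sets = [s.symbols() for s in sets]
    regions: dict[str, int] = {}
    n = len(sets)
    for mask in range(1, 2 ** n):
        inside = [i for i in range(n) if mask >> i & 1]
        outside = [i for i in range(n) if not mask >> i & 1]
        region = frozenset.intersection(*(symbol_sets[i] for i in inside))
        for i in outside:
            region -= symbol_sets[i]
        regions["&".join(names[i] for i in inside)] = len(region)
    return regions
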