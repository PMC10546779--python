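"""Core containers for differential-expression calls and regulated gene sets.

The pipeline's universal currency is the :class:`RegulatedGeneSet`: a named,
species-tagged mapping from a normalized gene symbol to its regulation
direction, average fold change, and supporting-source provenance. Per-dataset
inputs arrive as :class:`DEGTable` (collections of :class:`DEGRecord`), and
direction-free curated lists (endocytosis genes, CRISPR phagocytosis
modifiers, GWAS genes, methylation-annotated genes) are
:class:`AnnotatedGeneList`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

HUMAN = "human"
MOUSE = "mouse"
CROSS = "cross"
VALID_SPECIES = frozenset({HUMAN, MOUSE, CROSS})

UP = "up"
DOWN = "down"
VALID_DIRECTIONS = frozenset({UP, DOWN})

#: Allowed per-symbol annotation keys on curated lists and their vocabularies.
ANNOTATION_VOCAB: Mapping[str, Optional[frozenset]] = {
    "methylation_direction": frozenset({"hyper", "hypo"}),
    "expression_direction": frozenset({UP, DOWN}),
    "promoter_dm": None,  # boolean
}


class ValidationError(ValueError):
    """Raised when an input object violates a declared invariant."""


def signed_fc_from_log2(log2fc: float) -> float:
    """Signed linear fold change from a signed log2 fold change.

    The sign encodes direction (up/down); the magnitude is always >= 1, so
    log2fc = -1 maps to fc = -2 ("down two-fold").
    """
    return math.copysign(2.0 ** abs(log2fc), log2fc) if log2fc != 0 else 1.0


def log2_from_signed_fc(fc: float) -> float:
    return math.copysign(math.log2(abs(fc)), fc)


@dataclass(frozen=True)
class DEGRecord:
    """One differential-expression call in one dataset.

    Exactly one of ``fc`` / ``log2fc`` must be supplied (the other is
    derived), or -- for curated rows carrying direction only -- an explicit
    ``direction`` with both magnitudes missing.
    """

    symbol: str
    species: str
    dataset_id: str
    fc: Optional[float] = None
    log2fc: Optional[float] = None
    p_value: Optional[float] = None
    adj_p: Optional[float] = None
    direction: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.symbol or not self.symbol.strip():
            raise ValidationError("DEGRecord symbol must be non-empty")
        if self.species not in (HUMAN, MOUSE):
            raise ValidationError(f"unknown species {self.species!r}")
        if not self.dataset_id:
            raise ValidationError("dataset_id must be non-empty")
        fc, log2fc = self.fc, self.log2fc
        if fc is None and log2fc is None:
            if self.direction not in VALID_DIRECTIONS:
                raise ValidationError(
                    f"record {self.symbol!r}: needs fc, log2fc, or a direction"
                )
        else:
            if fc is None:
                fc = signed_fc_from_log2(log2fc)
                object.__setattr__(self, "fc", fc)
            elif log2fc is None:
                object.__setattr__(self, "log2fc", log2_from_signed_fc(fc))
            if abs(fc) < 1.0:
                raise ValidationError(
                    f"record {self.symbol!r}: |fc| must be >= 1, got {fc}"
                )
            derived = UP if fc > 0 else DOWN
            if self.direction is None:
                object.__setattr__(self, "direction", derived)
            elif self.direction != derived:
                raise ValidationError(
                    f"record {self.symbol!r}: direction {self.direction!r} "
                    f"contradicts fc sign {fc}"
                )
        for name in ("p_value", "adj_p"):
            p = getattr(self, name)
            if p is not None and not (0.0 <= p <= 1.0):
                raise ValidationError(
                    f"record {self.symbol!r}: {name}={p} outside [0, 1]"
                )

    @property
    def magnitude(self) -> Optional[float]:
        return None if self.fc is None else abs(self.fc)


@dataclass
class DEGTable:
    """All differential-expression calls of one dataset (one species)."""

    dataset_id: str
    species: str
    records: list[DEGRecord] = field(default_factory=list)
    #: free-form load/filter bookkeeping; excluded from equality
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.species not in (HUMAN, MOUSE):
            raise ValidationError(f"unknown species {self.species!r}")
        for rec in self.records:
            if rec.dataset_id != self.dataset_id:
                raise ValidationError(
                    f"record {rec.symbol!r} carries dataset {rec.dataset_id!r},"
                    f" table is {self.dataset_id!r}"
                )
            if rec.species != self.species:
                raise ValidationError(
                    f"record {rec.symbol!r} carries species {rec.species!r},"
                    f" table is {self.species!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[DEGRecord]:
        return iter(self.records)


@dataclass(frozen=True)
class GeneEntry:
    """Membership record of one gene in a :class:`RegulatedGeneSet`."""

    direction: Optional[str]
    avg_fc: Optional[float]
    sources: tuple[str, ...]
    #: (source, direction) pairs preserving each side's recorded direction
    source_directions: tuple[tuple[str, str], ...] = ()
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.direction is not None and self.direction not in VALID_DIRECTIONS:
            raise ValidationError(f"bad direction {self.direction!r}")
        if self.direction is None and not self.ambiguous:
            raise ValidationError("direction may be missing only when ambiguous")
        if not self.sources:
            raise ValidationError("sources must be non-empty")
        if self.avg_fc is not None and self.direction is not None:
            if abs(self.avg_fc) < 1.0:
                raise ValidationError(f"|avg_fc| must be >= 1, got {self.avg_fc}")
            sign_dir = UP if self.avg_fc > 0 else DOWN
            if sign_dir != self.direction:
                raise ValidationError(
                    f"avg_fc sign {self.avg_fc} inconsistent with "
                    f"direction {self.direction!r}"
                )


@dataclass
class RegulatedGeneSet:
    """Named map gene -> (direction, average FC, provenance)."""

    name: str
    species: str
    members: dict[str, GeneEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.species not in VALID_SPECIES:
            raise ValidationError(f"unknown species {self.species!r}")

    def symbols(self) -> frozenset[str]:
        return frozenset(self.members)

    def sorted_symbols(self) -> list[str]:
        return sorted(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.members

    def get(self, symbol: str) -> Optional[GeneEntry]:
        return self.members.get(symbol)

    def count(self, direction: str) -> int:
        return sum(1 for e in self.members.values() if e.direction == direction)

    @property
    def n_up(self) -> int:
        return self.count(UP)

    @property
    def n_down(self) -> int:
        return self.count(DOWN)

    def subset(self, symbols: Iterable[str], name: Optional[str] = None) -> "RegulatedGeneSet":
        keep = set(symbols)
        return RegulatedGeneSet(
            name=name or self.name,
            species=self.species,
            members={s: e for s, e in sorted(self.members.items()) if s in keep},
        )


@dataclass
class AnnotatedGeneList:
    """Direction-free curated gene list with optional per-symbol annotations."""

    name: str
    symbols: frozenset[str]
    annotations: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sym, ann in self.annotations.items():
            if sym not in self.symbols:
                raise ValidationError(f"annotation for non-member {sym!r}")
            for key, value in ann.items():
                if key not in ANNOTATION_VOCAB:
                    raise ValidationError(f"unknown annotation key {key!r}")
                vocab = ANNOTATION_VOCAB[key]
                if vocab is None:
                    if not isinstance(value, bool):
                        raise ValidationError(
                            f"{sym!r}: {key} must be boolean, got {value!r}"
                        )
                elif value not in vocab:
                    raise ValidationError(
                        f"{sym!r}: {key}={value!r} not in {sorted(vocab)}"
                    )

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def annotation(self, symbol: str) -> dict:
        return self.annotations.get(symbol, {})


@dataclass
class CascadeResult:
    """Tiered outputs of the full cascade plus run metadata."""

    tiers: dict[str, RegulatedGeneSet] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {name: len(tier) for name, tier in sorted(self.tiers.items())}

    def __getitem__(self, name: str) -> RegulatedGeneSet:
        return self.tiers[name]
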