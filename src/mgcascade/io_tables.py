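"""Readers and writers for every tabular artifact the cascade touches.

Supported inputs: per-dataset DEG tables as TSV/CSV/XLSX with a declared
header map; curated gene lists as plain text, GMT, or annotated TSV/CSV.
Outputs: one TSV per cascade tier plus a single JSON provenance document
that mirrors every membership decision; re-reading the provenance document
reconstructs the :class:`~mgcascade.model.CascadeResult` exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .harmonize import normalize_symbol
from .model import (
    ANNOTATION_VOCAB,
    AnnotatedGeneList,
    CascadeResult,
    DEGRecord,
    DEGTable,
    GeneEntry,
    RegulatedGeneSet,
    ValidationError,
)

PathLike = Union[str, Path]

#: logical record fields a column map may bind
LOGICAL_FIELDS = ("symbol", "fc", "log2fc", "p_value", "adj_p", "direction")
#: the column map used by this package's own table writers
DEFAULT_COLUMN_MAP = {f: f for f in LOGICAL_FIELDS}

_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f"}


class FormatError(ValueError):
    """A file does not match its declared format (e.g. missing column)."""


class EmptyInputError(ValueError):
    """An input table or list contained no usable rows."""


def _read_frame(path: PathLike, sheet: Optional[str] = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".xlsx", ".xlsm"):
        return pd.read_excel(path, sheet_name=sheet or 0, dtype=str)
    if suffix in (".tsv", ".tab"):
        sep: Optional[str] = "\t"
    elif suffix == ".csv":
        sep = ","
    else:
        sep = None  # sniffed by the python engine
    return pd.read_csv(path, sep=sep, engine="python", dtype=str)


def _parse_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    if not text or text.lower() in ("na", "nan", "none", "."):
        return None
    return float(text)  # ValueError propagates to the row handler


def read_deg_table(
    path: PathLike,
    column_map: Mapping[str, str],
    species: str,
    dataset_id: str,
    sheet: Optional[str] = None,
) -> DEGTable:
    """Load one dataset's DEG calls through a declared header map.

    ``column_map`` binds logical fields (``symbol`` mandatory; at least one
    of ``fc``/``log2fc``/``direction``) to the file's header names. Rows
    with unparseable numerics or invalid values are dropped and counted in
    the returned table's ``meta`` load report.
    """
    unknown = set(column_map) - set(LOGICAL_FIELDS)
    if unknown:
        raise FormatError(f"unknown logical fields in column map: {sorted(unknown)}")
    if "symbol" not in column_map:
        raise FormatError("column map must bind the mandatory field 'symbol'")
    if not ({"fc", "log2fc", "direction"} & set(column_map)):
        raise FormatError("column map must bind 'fc', 'log2fc', or 'direction'")

    frame = _read_frame(path, sheet=sheet)
    for logical, header in column_map.items():
        if header not in frame.columns:
            raise FormatError(
                f"{Path(path).name}: mandatory column {header!r} "
                f"(bound to {logical!r}) not found; headers are {list(frame.columns)}"
            )
    if frame.empty:
        raise EmptyInputError(f"{Path(path).name}: table has no data rows")

    records: list[DEGRecord] = []
    dropped: list[str] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        values = dict(zip(frame.columns, row))
        try:
            kwargs: dict = {"species": species, "dataset_id": dataset_id}
            raw_symbol = values[column_map["symbol"]]
            if raw_symbol is None or pd.isna(raw_symbol) or not str(raw_symbol).strip():
                raise ValidationError("missing symbol")
            kwargs["symbol"] = str(raw_symbol).strip()
            for numeric in ("fc", "log2fc", "p_value", "adj_p"):
                if numeric in column_map:
                    kwargs[numeric] = _parse_float(values[column_map[numeric]])
            if "direction" in column_map:
                raw_dir = values[column_map["direction"]]
                if raw_dir is not None and not pd.isna(raw_dir) and str(raw_dir).strip():
                    kwargs["direction"] = str(raw_dir).strip().lower()
            records.append(DEGRecord(**kwargs))
        except (ValueError, ValidationError) as exc:
            dropped.append(f"row {i + 2}: {exc}")  # +2: header + 1-based
    if not records:
        raise EmptyInputError(f"{Path(path).name}: no parseable rows")
    return DEGTable(
        dataset_id=dataset_id,
        species=species,
        records=records,
        meta={
            "path": str(path),
            "n_rows": len(frame),
            "n_parsed": len(records),
            "n_dropped": len(dropped),
            "dropped": dropped[:50],
        },
    )


def write_deg_table(table: DEGTable, path: PathLike) -> None:
    """Write a DEG table as TSV readable back with ``DEFAULT_COLUMN_MAP``."""
    rows = [
        {
            "symbol": rec.symbol,
            "fc": rec.fc,
            "log2fc": rec.log2fc,
            "p_value": rec.p_value,
            "adj_p": rec.adj_p,
            "direction": rec.direction,
        }
        for rec in table
    ]
    pd.DataFrame(rows, columns=list(LOGICAL_FIELDS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# curated gene lists


def _parse_bool(value) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValidationError(f"cannot parse boolean {value!r}")


def read_gene_list(
    path: PathLike,
    format: str = "plain",
    name: Optional[str] = None,
    gmt_set: Optional[str] = None,
) -> AnnotatedGeneList:
    """Read a curated gene list.

    ``format`` is one of ``plain`` (one symbol per line, ``#`` comments),
    ``gmt`` (tab-separated: name, description, members; ``gmt_set`` selects a
    line by set name, default the first), or ``annotated`` (TSV/CSV with a
    ``symbol`` column plus optional annotation columns). Duplicate symbols
    with conflicting annotations raise a validation error naming them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "plain":
        symbols = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                symbols.append(normalize_symbol(line))
        if not symbols:
            raise EmptyInputError(f"{path.name}: no symbols")
        return AnnotatedGeneList(name or path.stem, frozenset(symbols))
    if format == "gmt":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path.name}: GMT line has fewer than 3 fields")
            set_name, _desc, *members = fields
            if gmt_set is None or set_name == gmt_set:
                symbols = frozenset(normalize_symbol(m) for m in members if m.strip())
                if not symbols:
                    raise EmptyInputError(f"{path.name}: GMT set {set_name!r} empty")
                return AnnotatedGeneList(name or set_name, symbols)
        raise FormatError(f"{path.name}: GMT set {gmt_set!r} not found")
    if format == "annotated":
        frame = _read_frame(path)
        if "symbol" not in frame.columns:
            raise FormatError(f"{path.name}: mandatory column 'symbol' not found")
        if frame.empty:
            raise EmptyInputError(f"{path.name}: no data rows")
        ann_cols = [c for c in frame.columns if c in ANNOTATION_VOCAB]
        annotations: dict[str, dict] = {}
        conflicts: set[str] = set()
        for _, row in frame.iterrows():
            sym = normalize_symbol(row["symbol"])
            ann: dict = {}
            for col in ann_cols:
                value = row[col]
                if value is None or pd.isna(value) or not str(value).strip():
                    continue
                if col == "promoter_dm":
                    ann[col] = _parse_bool(value)
                else:
                    ann[col] = str(value).strip().lower()
            if sym in annotations and annotations[sym] != ann:
                conflicts.add(sym)
            annotations[sym] = ann
        if conflicts:
            raise ValidationError(
                f"{path.name}: conflicting annotations for {sorted(conflicts)}"
            )
        return AnnotatedGeneList(
            name or path.stem,
            frozenset(annotations),
            {s: a for s, a in annotations.items() if a},
        )
    raise FormatError(f"unknown gene-list format {format!r}")


def write_gene_list(l: AnnotatedGeneList, path: PathLike, format: str = "plain") -> None:
    path = Path(path)
    if format == "plain":
        path.write_text("".join(f"{s}\n" for s in sorted(l.symbols)))
        return
    if format == "gmt":
        path.write_text("\t".join([l.name, "na", *sorted(l.symbols)]) + "\n")
        return
    if format == "annotated":
        keys = sorted({k for a in l.annotations.values() for k in a})
        rows = []
        for sym in sorted(l.symbols):
            ann = l.annotation(sym)
            rows.append({"symbol": sym, **{k: ann.get(k, "") for k in keys}})
        pd.DataFrame(rows, columns=["symbol", *keys]).to_csv(path, sep="\t", index=False)
        return
    raise FormatError(f"unknown gene-list format {format!r}")


def read_ortholog_table(path: PathLike) -> dict[str, str]:
    """Two-column TSV/CSV (source symbol, target symbol) -> mapping."""
    frame = _read_frame(path)
    if frame.shape[1] < 2:
        raise FormatError(f"{Path(path).name}: ortholog table needs two columns")
    src, dst = frame.columns[:2]
    return {
        normalize_symbol(row[src]): normalize_symbol(row[dst])
        for _, row in frame.iterrows()
        if str(row[src]).strip() and str(row[dst]).strip()
    }


# ---------------------------------------------------------------------------
# tier outputs and provenance


def _entry_to_json(symbol: str, entry: GeneEntry) -> dict:
    return {
        "symbol": symbol,
        "direction": entry.direction,
        "avg_fc": entry.avg_fc,
        "sources": list(entry.sources),
        "source_directions": [list(sd) for sd in entry.source_directions],
        "ambiguous": entry.ambiguous,
    }


def _entry_from_json(data: Mapping) -> GeneEntry:
    return GeneEntry(
        direction=data["direction"],
        avg_fc=data["avg_fc"],
        sources=tuple(data["sources"]),
        source_directions=tuple((s, d) for s, d in data["source_directions"]),
        ambiguous=data["ambiguous"],
    )


def write_tier_outputs(result: CascadeResult, out_dir: PathLike) -> list[Path]:
    """Write one TSV per tier plus ``provenance.json``.

    TSVs carry (symbol, direction, avg_fc, sources); the JSON document
    mirrors every membership decision and is sufficient to reconstruct the
    result (:func:`read_tier_outputs`). Output is deterministic: identical
    results serialize byte-identically.
    """
    if result is None:
        raise ValidationError("result must not be None")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for tier_name in sorted(result.tiers):
        tier = result.tiers[tier_name]
        tsv = out / f"{tier_name}.tsv"
        with open(tsv, "w") as fh:
            fh.write("symbol\tdirection\tavg_fc\tsources\n")
            for sym in tier.sorted_symbols():
                e = tier.members[sym]
                fc = "" if e.avg_fc is None else repr(e.avg_fc)
                direction = e.direction if e.direction is not None else "ambiguous"
                fh.write(f"{sym}\t{direction}\t{fc}\t{';'.join(e.sources)}\n")
        written.append(tsv)
    provenance = {
        "metadata": result.metadata,
        "tiers": {
            name: {
                "species": tier.species,
                "members": [
                    _entry_to_json(sym, tier.members[sym])
                    for sym in tier.sorted_symbols()
                ],
            }
            for name, tier in sorted(result.tiers.items())
        },
    }
    pj = out / "provenance.json"
    pj.write_text(json.dumps(provenance, sort_keys=True, indent=2) + "\n")
    written.append(pj)
    return written


def read_tier_outputs(out_dir: PathLike) -> CascadeResult:
    """Reconstruct a :class:`CascadeResult` from ``provenance.json``."""
    data = json.loads((Path(out_dir) / "provenance.json").read_text())
    tiers = {
        name: RegulatedGeneSet(
            name=name,
            species=block["species"],
            members={
                m["symbol"]: _entry_from_json(m) for m in block["members"]
            },
        )
        for name, block in data["tiers"].items()
    }
    return CascadeResult(tiers=tiers, metadata=data["metadata"])
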