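"""Readers and writers for count tables, set definitions, and results.

Count tables are delimited text with sample IDs in the first column and
taxon IDs in the header (use ``transpose=True`` for taxa-in-rows dialects).
Set definitions come as GMT files (set name, description, then member taxon
IDs, tab-separated) or two-column long-format TSV (taxon_id, set_name).
Every run writes a JSON manifest capturing the resolved configuration,
seeds, and SHA-256 digests of the inputs so results can be reproduced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CompositionTable, InvalidInputError, SetCollection
from .null_model import EnrichmentResult

logger = logging.getLogger(__name__)

__all__ = [
    "read_counts", "write_counts", "read_sets", "write_sets_gmt",
    "write_result", "read_result_values", "RunManifest", "ParseError",
]


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending location."""


_DELIMS = {"tsv": "\t", "csv": ","}


def read_counts(path, dialect: str = "tsv", transpose: bool = False) -> CompositionTable:
    """Parse a delimited count/abundance table into samples x taxa form."""
    if dialect not in _DELIMS:
        raise ParseError(f"dialect must be one of {sorted(_DELIMS)}, got {dialect!r}")
    path = Path(path)
    # pandas mangles duplicate header fields (t1, t1.1); check them raw
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_DELIMS[dialect])[1:]
    if len(set(header)) != len(header):
        seen: set[str] = set()
        dup = next(h for h in header if h in seen or seen.add(h))
        kind = "sample" if transpose else "taxon"
        raise ParseError(f"{path}: duplicate {kind} id {dup!r} in header")
    try:
        df = pd.read_csv(path, sep=_DELIMS[dialect], index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if transpose:
        df = df.T
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate {'taxon' if transpose else 'sample'} id {dup!r}")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        raise ParseError(f"{path}: missing value in column {col!r}; "
                         "missing abundances are not accepted")
    bad = df.columns[~df.apply(lambda c: pd.api.types.is_numeric_dtype(c))]
    if len(bad):
        raise ParseError(f"{path}: non-numeric values in column {bad[0]!r}")
    return CompositionTable(df.to_numpy(dtype=float),
                            tuple(str(i) for i in df.index),
                            tuple(str(c) for c in df.columns))


def write_counts(table: CompositionTable, path, dialect: str = "tsv") -> None:
    table.to_frame().to_csv(Path(path), sep=_DELIMS[dialect],
                            index_label="sample_id")


def _read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs at least 3 tab-separated "
                    f"fields (name, description, members), got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [t for t in fields[2:] if t]
    return sets


def _read_long_tsv(path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: long format needs columns (taxon_id, set_name)")
    taxon_col, set_col = df.columns[:2]
    sets: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        sets.setdefault(str(row[set_col]), []).append(str(row[taxon_col]))
    return sets


def read_sets(path, taxon_ids, fmt: str = "gmt") -> SetCollection:
    """Parse set definitions and align them to a taxon universe.

    Members absent from ``taxon_ids`` are dropped (count logged); sets empty
    after intersection, or spanning the full universe, are dropped with a
    warning rather than failing the whole collection.
    """
    if fmt == "gmt":
        raw = _read_gmt(path)
    elif fmt == "long_tsv":
        raw = _read_long_tsv(path)
    else:
        raise ParseError(f"unknown set format {fmt!r}; use 'gmt' or 'long_tsv'")
    universe = set(taxon_ids)
    p = len(universe)
    kept: dict[str, list[str]] = {}
    n_dropped_taxa = 0
    for name, members in raw.items():
        members = list(dict.fromkeys(members))  # de-duplicate, keep order
        present = [t for t in members if t in universe]
        n_dropped_taxa += len(members) - len(present)
        if not present:
            logger.warning("set %r has no members in the taxon universe; dropped", name)
            continue
        if len(present) >= p:
            logger.warning("set %r covers the entire taxon universe; dropped "
                           "(balance against an empty complement is undefined)", name)
            continue
        kept[name] = present
    if n_dropped_taxa:
        logger.info("dropped %d set members absent from the taxon universe",
                    n_dropped_taxa)
    if not kept:
        raise ParseError(f"{path}: no usable sets after aligning to the taxon universe")
    return SetCollection.from_dict(kept, taxon_ids)


def write_sets_gmt(sets: SetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sets.set_names:
            members = [sets.taxon_ids[i] for i in sets.indices(name)]
            fh.write("\t".join([name, description, *members]) + "\n")


class RunManifest:
    """Provenance record serialized next to every output file."""

    def __init__(self, command: str, config: dict, seeds: dict,
                 input_paths: dict[str, str | Path] | None = None):
        try:
            tool_version = _pkg_version("cbea")
        except Exception:  # not installed, e.g. running from a checkout
            tool_version = "unknown"
        self.data = {
            "tool": "cbea",
            "version": tool_version,
            "command": command,
            "config": config,
            "seeds": seeds,
            "input_digests": {
                name: _sha256(p) for name, p in (input_paths or {}).items()
            },
            "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        }

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_result(result: EnrichmentResult, path, manifest: RunManifest | None = None) -> None:
    """Write an enrichment matrix as TSV at full float precision.

    Values are serialized with ``repr`` round-trip precision so a write/read
    cycle reproduces the matrix bit-for-bit.
    """
    path = Path(path)
    df = result.to_frame()
    df.to_csv(path, sep="\t", index_label="sample_id",
              float_format=lambda v: np.format_float_scientific(v, unique=True))
    if manifest is not None:
        manifest.data["output_type"] = result.output_type
        manifest.write(path.with_suffix(path.suffix + ".manifest.json"))


def read_result_values(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t", index_col=0)
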