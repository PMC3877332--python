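"""Loading marker lists and PPI edge lists, identifier normalisation, merging.

Disease-marker compendia and interaction databases use heterogeneous
identifier types (gene symbols, accessions).  To put markers and network nodes
in one namespace, every raw identifier is mapped through a user-supplied
two-column table to a canonical accession; unmapped identifiers are dropped
(and counted) rather than passed through, so the marker set and the graph node
set cannot silently diverge.  Mapping is case-insensitive on the raw side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .graph import Graph, GraphInputError, build_graph, read_edge_list

logger = logging.getLogger(__name__)


class IngestError(ValueError):
    """Malformed or empty ingest input."""


def _read_rows(path: Path, delimiter: str | None) -> list[list[str]]:
    rows: list[list[str]] = []
    sep = delimiter
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if sep is None:
                sep = "\t" if "\t" in line else ("," if "," in line else "\t")
            rows.append([f.strip() for f in line.split(sep)])
    return rows


@dataclass(frozen=True)
class IdMap:
    """Raw identifier -> canonical accession, case-insensitive on the raw side."""

    mapping: dict[str, str]

    @classmethod
    def from_pairs(cls, pairs: Iterable[Sequence[str]]) -> "IdMap":
        return cls({str(raw).strip().casefold(): str(canon).strip() for raw, canon in pairs})

    @classmethod
    def read(cls, path: str | Path, delimiter: str | None = None) -> "IdMap":
        rows = _read_rows(Path(path), delimiter)
        bad = [r for r in rows if len(r) < 2]
        if bad:
            raise IngestError(f"{path}: id-map rows need 2 columns, got {bad[0]!r}")
        return cls.from_pairs((r[0], r[1]) for r in rows)

    @classmethod
    def identity(cls) -> "IdMap":
        """Empty map used as a sentinel: every identifier maps to itself."""
        return cls({})

    def lookup(self, raw: str) -> str | None:
        key = raw.strip().casefold()
        if not self.mapping:
            return raw.strip()
        return self.mapping.get(key)


@dataclass
class MarkerList:
    """Normalised disease-marker identifiers from one source (or a merge).

    ``entries`` keeps (raw, normalised) pairs; ``provenance`` records which
    source list(s) each normalised identifier came from.
    """

    source_name: str
    entries: list[tuple[str, str]] = field(default_factory=list)
    provenance: dict[str, set[str]] = field(default_factory=dict)
    n_unmapped: int = 0

    @property
    def ids(self) -> set[str]:
        return {norm for _, norm in self.entries}

    def __len__(self) -> int:
        return len(self.entries)


def load_markers(
    path: str | Path,
    id_map: IdMap | None = None,
    delimiter: str | None = None,
    source_name: str | None = None,
) -> MarkerList:
    """Load a one-identifier-per-row marker list and normalise it.

    An optional second column names the source database per row; otherwise the
    file stem is used.  Rows whose identifier has no mapping are dropped and
    counted (warning if more than half drop).  Duplicates (after
    normalisation) collapse to one entry.
    """
    path = Path(path)
    rows = _read_rows(path, delimiter)
    if not rows:
        raise IngestError(f"{path}: empty marker list")
    id_map = id_map or IdMap.identity()
    name = source_name or path.stem
    seen: dict[str, str] = {}
    provenance: dict[str, set[str]] = {}
    n_unmapped = 0
    for row in rows:
        raw = row[0]
        src = row[1] if len(row) > 1 and row[1] else name
        norm = id_map.lookup(raw)
        if norm is None:
            n_unmapped += 1
            continue
        seen.setdefault(norm, raw)
        provenance.setdefault(norm, set()).add(src)
    if n_unmapped > len(rows) / 2:
        logger.warning(
            "%s: %d of %d identifiers unmapped (>50%%)", path, n_unmapped, len(rows)
        )
    elif n_unmapped:
        logger.info("%s: dropped %d unmapped identifier(s)", path, n_unmapped)
    entries = sorted(((seen[n], n) for n in seen), key=lambda e: e[1])
    return MarkerList(name, entries, provenance, n_unmapped)


def merge_marker_lists(lists: Sequence[MarkerList]) -> MarkerList:
    """De-redundant union of normalised identifiers, provenance retained.

    Idempotent and order-invariant on the identifier set.
    """
    provenance: dict[str, set[str]] = {}
    first_raw: dict[str, str] = {}
    total_unmapped = 0
    for ml in lists:
        total_unmapped += ml.n_unmapped
        for raw, norm in ml.entries:
            first_raw.setdefault(norm, raw)
            provenance.setdefault(norm, set()).update(
                ml.provenance.get(norm, {ml.source_name})
            )
    entries = sorted(((first_raw[n], n) for n in first_raw), key=lambda e: e[1])
    return MarkerList("merged", entries, provenance, total_unmapped)


def load_ppi(
    paths: Sequence[str | Path],
    id_map: IdMap | None = None,
    delimiter: str | None = None,
) -> Graph:
    """Union of several 2-column interaction files as one simple undirected graph.

    Equivalent to ``build_graph`` on the concatenation of all files' pairs.
    Endpoints are normalised through ``id_map`` when given; interactions with
    an unmapped endpoint are dropped (counted in the log).
    """
    if not paths:
        raise IngestError("load_ppi: no input files")
    id_map = id_map or IdMap.identity()
    pairs = []
    n_unmapped = 0
    for p in paths:
        try:
            raw_pairs = read_edge_list(p, delimiter=delimiter)
        except GraphInputError as exc:
            raise IngestError(str(exc)) from exc
        for u, v in raw_pairs:
            cu, cv = id_map.lookup(u), id_map.lookup(v)
            if cu is None or cv is None:
                n_unmapped += 1
                continue
            pairs.append((cu, cv))
    if n_unmapped:
        logger.info("load_ppi: dropped %d interaction(s) with unmapped endpoints", n_unmapped)
    return build_graph(pairs)
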