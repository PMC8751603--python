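"""Readers and writers for the external file dialects the pipeline consumes.

Supported inputs
----------------
* protein-protein interaction edge lists, either BioGRID TAB-like (official
  symbol columns, experimental system type, per-side organism taxonomy IDs)
  or a minimal five-column TSV;
* STITCH-like chemical-protein interaction tables with per-channel evidence
  scores and a combined confidence score (native 0-1000 or unit scale);
* GMT gene-set collections;
* TRRUST-like transcription-factor -> target tables;
* two-column ortholog maps with inparalog scores;
* plain one-symbol-per-line lists.

Parsing is strictly syntactic: no filtering beyond validation happens here
(cleaning rules live in :mod:`reprognet.interactome`), rows keep their file
order, and every rejection carries the 1-based line number of the offending
row.  All files are tab-separated UTF-8; lines starting with ``#`` are
ignored.  Protein symbols are upper-cased and stripped of surrounding
whitespace on load.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger(__name__)

SYSTEM_TYPES = ("physical", "genetic")
EVIDENCE_CHANNELS = ("experimental", "database", "textmining", "prediction")


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


def normalize_symbol(symbol: str) -> str:
    """Upper-case and strip a gene/protein symbol."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class EdgeRecord:
    """One raw interaction row, before any cleaning."""

    symbol_a: str
    symbol_b: str
    system_type: str
    organism_a: int
    organism_b: int

    def __post_init__(self) -> None:
        if not self.symbol_a or not self.symbol_b:
            raise ValueError("interactor symbols must be non-empty")
        if self.system_type not in SYSTEM_TYPES:
            raise ValueError(
                f"system_type must be one of {SYSTEM_TYPES}, got {self.system_type!r}"
            )


@dataclass(frozen=True)
class ChemTargetRecord:
    """One chemical-protein interaction with evidence scores on [0, 1]."""

    chemical_id: str
    protein: str
    channel_scores: Mapping[str, float]
    combined_score: float

    def __post_init__(self) -> None:
        if not self.chemical_id or not self.protein:
            raise ValueError("chemical_id and protein must be non-empty")
        for name, score in self.channel_scores.items():
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"channel {name!r} score {score} outside [0, 1]")
        if not 0.0 <= self.combined_score <= 1.0:
            raise ValueError(f"combined_score {self.combined_score} outside [0, 1]")


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets over an explicit background universe.

    The universe defaults to the union of all members; when supplied
    explicitly it must contain every member of every set.
    """

    sets: Mapping[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        union = frozenset().union(*self.sets.values()) if self.sets else frozenset()
        stray = union - self.universe
        if stray:
            raise ValueError(
                f"{len(stray)} set members missing from the declared universe "
                f"(e.g. {sorted(stray)[:5]})"
            )

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class TFTargetTable:
    """Transcription-factor -> regulated-target pairs (duplicates removed)."""

    pairs: tuple[tuple[str, str], ...]

    def targets_of(self, tfs: Iterable[str]) -> frozenset[str]:
        wanted = {normalize_symbol(t) for t in tfs}
        return frozenset(target for tf, target in self.pairs if tf in wanted)

    @property
    def tfs(self) -> frozenset[str]:
        return frozenset(tf for tf, _ in self.pairs)

    @property
    def all_targets(self) -> frozenset[str]:
        return frozenset(target for _, target in self.pairs)


@dataclass(frozen=True)
class OrthologMap:
    """(source gene, target gene, inparalog score) rows; scores on [0, 1]."""

    rows: tuple[tuple[str, str, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for src, dst, score in self.rows:
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"inparalog score {score} for {src}->{dst} outside [0, 1]")


def _data_rows(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for non-comment, non-blank lines."""
    with open(path, encoding="utf-8", newline="") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if all(not cell.strip() for cell in row):
                continue
            yield lineno, row


_BIOGRID_COLUMNS = {
    "symbol_a": "Official Symbol Interactor A",
    "symbol_b": "Official Symbol Interactor B",
    "system_type": "Experimental System Type",
    "organism_a": "Organism Interactor A",
    "organism_b": "Organism Interactor B",
}
_SIMPLE_COLUMNS = {
    "symbol_a": "symbol_a",
    "symbol_b": "symbol_b",
    "system_type": "system_type",
    "organism_a": "organism_a",
    "organism_b": "organism_b",
}


def read_edge_list(
    path: str | Path, dialect: str = "simple_tsv"
) -> list[EdgeRecord]:
    """Parse a PPI edge list into raw :class:`EdgeRecord` rows.

    ``dialect`` is ``"biogrid_tab"`` (BioGRID TAB column headers) or
    ``"simple_tsv"`` (columns symbol_a, symbol_b, system_type, organism_a,
    organism_b).  Self-loops, duplicates and off-species rows are *kept*;
    cleaning is a separate, accounted step.
    """
    if dialect == "biogrid_tab":
        colmap = _BIOGRID_COLUMNS
    elif dialect == "simple_tsv":
        colmap = _SIMPLE_COLUMNS
    else:
        raise ValueError(f"unknown edge-list dialect {dialect!r}")

    rows = _data_rows(path)
    try:
        header_lineno, header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: empty file, expected a header row") from None
    index: dict[str, int] = {}
    for key, column in colmap.items():
        try:
            index[key] = header.index(column)
        except ValueError:
            raise FormatError(
                f"{path}: missing required column {column!r} in header (line {header_lineno})"
            ) from None

    records: list[EdgeRecord] = []
    for lineno, row in rows:
        if len(row) <= max(index.values()):
            raise FormatError(f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}")
        system_type = row[index["system_type"]].strip().lower()
        if system_type not in SYSTEM_TYPES:
            raise FormatError(
                f"{path}:{lineno}: unknown system_type {row[index['system_type']]!r}"
            )
        try:
            organism_a = int(row[index["organism_a"]])
            organism_b = int(row[index["organism_b"]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer organism ID") from exc
        records.append(
            EdgeRecord(
                symbol_a=normalize_symbol(row[index["symbol_a"]]),
                symbol_b=normalize_symbol(row[index["symbol_b"]]),
                system_type=system_type,
                organism_a=organism_a,
                organism_b=organism_b,
            )
        )
    return records


def write_edge_list(records: Sequence[EdgeRecord], path: str | Path) -> None:
    """Write records in the ``simple_tsv`` dialect (round-trips with reading)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("symbol_a\tsymbol_b\tsystem_type\torganism_a\torganism_b\n")
        for r in records:
            handle.write(
                f"{r.symbol_a}\t{r.symbol_b}\t{r.system_type}\t{r.organism_a}\t{r.organism_b}\n"
            )


_CHEM_COLUMNS = ["chemical", "protein", *EVIDENCE_CHANNELS, "combined_score"]


def read_chem_targets(
    path: str | Path, score_scale: str = "thousandths"
) -> list[ChemTargetRecord]:
    """Parse a STITCH-like chemical-protein table.

    ``score_scale`` declares how scores are stored in the file: STITCH's
    native integer 0-1000 scale (``"thousandths"``) or already on the unit
    interval (``"unit"``).  Scores are stored internally on [0, 1] so that
    the medium-stringency confidence cut-off 0.4 is literal.
    """
    if score_scale not in ("unit", "thousandths"):
        raise ValueError(f"unknown score_scale {score_scale!r}")
    divisor = 1000.0 if score_scale == "thousandths" else 1.0
    limit = 1000.0 if score_scale == "thousandths" else 1.0

    rows = _data_rows(path)
    try:
        header_lineno, header = next(rows)
    except StopIteration:
        logger.warning("%s: empty chemical-target file", path)
        return []
    index: dict[str, int] = {}
    for column in _CHEM_COLUMNS:
        try:
            index[column] = header.index(column)
        except ValueError:
            raise FormatError(
                f"{path}: missing required column {column!r} in header (line {header_lineno})"
            ) from None

    records: list[ChemTargetRecord] = []
    for lineno, row in rows:
        scores: dict[str, float] = {}
        for column in (*EVIDENCE_CHANNELS, "combined_score"):
            try:
                raw = float(row[index[column]])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: bad score in column {column!r}") from exc
            if not 0.0 <= raw <= limit:
                raise FormatError(
                    f"{path}:{lineno}: score {raw} in column {column!r} outside the "
                    f"declared {score_scale} scale [0, {limit:g}]"
                )
            scores[column] = raw / divisor
        combined = scores.pop("combined_score")
        records.append(
            ChemTargetRecord(
                chemical_id=row[index["chemical"]].strip(),
                protein=normalize_symbol(row[index["protein"]]),
                channel_scores=scores,
                combined_score=combined,
            )
        )
    if not records:
        logger.warning("%s: chemical-target file has a header but no rows", path)
    return records


def write_chem_targets(records: Sequence[ChemTargetRecord], path: str | Path) -> None:
    """Write records on the unit scale (round-trips with ``score_scale='unit'``)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(_CHEM_COLUMNS) + "\n")
        for r in records:
            channels = "\t".join(repr(r.channel_scores[c]) for c in EVIDENCE_CHANNELS)
            handle.write(f"{r.chemical_id}\t{r.protein}\t{channels}\t{r.combined_score!r}\n")


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file: per line, set name, description, then members."""
    sets: dict[str, frozenset[str]] = {}
    for lineno, row in _data_rows(path):
        if len(row) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has {len(row)} fields, expected >= 3")
        name = row[0].strip()
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        members = frozenset(normalize_symbol(s) for s in row[2:] if s.strip())
        sets[name] = members
    union = frozenset().union(*sets.values()) if sets else frozenset()
    if universe is None:
        uni = union
    else:
        uni = frozenset(normalize_symbol(s) for s in universe) | union
    return GeneSetCollection(sets=sets, universe=uni)


def read_tf_targets(path: str | Path) -> TFTargetTable:
    """Parse a two-or-more-column TF -> target TSV; duplicate pairs dropped."""
    seen: set[tuple[str, str]] = set()
    pairs: list[tuple[str, str]] = []
    for lineno, row in _data_rows(path):
        if len(row) < 2:
            raise FormatError(f"{path}:{lineno}: expected >= 2 fields")
        pair = (normalize_symbol(row[0]), normalize_symbol(row[1]))
        if pair in seen:
            continue
        seen.add(pair)
        pairs.append(pair)
    return TFTargetTable(pairs=tuple(pairs))


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Parse (source gene, target gene, inparalog score) rows; no filtering."""
    rows: list[tuple[str, str, float]] = []
    for lineno, row in _data_rows(path):
        if len(row) < 3:
            raise FormatError(f"{path}:{lineno}: expected >= 3 fields")
        try:
            score = float(row[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric inparalog score") from exc
        if not 0.0 <= score <= 1.0:
            raise FormatError(f"{path}:{lineno}: inparalog score {score} outside [0, 1]")
        rows.append((normalize_symbol(row[0]), normalize_symbol(row[1]), score))
    return OrthologMap(rows=tuple(rows))


def read_symbol_list(path: str | Path) -> list[str]:
    """One symbol per line; order kept, duplicates kept (callers de-duplicate)."""
    return [normalize_symbol(row[0]) for _, row in _data_rows(path) if row[0].strip()]


def write_symbol_list(symbols: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for s in symbols:
            handle.write(f"{s}\n")
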