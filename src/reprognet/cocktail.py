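"""Reprogramming-cocktail combinatorics and per-cocktail target aggregation.

A *cocktail* is a named combination of small molecules (SMs) reported to
reprogram somatic cells without transcription-factor transgenes.  This
module resolves variant SM spellings against a catalog, computes union /
frequency / category-coverage summaries across cocktails, pools each
cocktail's protein targets from a chemical-target table, and compares
target sets against transcription-factor target sets (e.g. OSKM) with
Fisher's exact test.

The packaged fixtures (``data/``) carry the ten published cocktail
compositions, the 22 non-redundant SMs with their functional categories
(epigenetic / signaling / metabolic / other), and the 28 SMs found in the
human metabolome.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io import ChemTargetRecord, FormatError, TFTargetTable, _data_rows
from .set_statistics import OverlapResult, fisher_overlap

logger = logging.getLogger(__name__)

CATEGORIES = ("epigenetic", "signaling", "metabolic", "other")
CORE_CATEGORIES = ("epigenetic", "signaling", "metabolic")


@dataclass(frozen=True)
class SMRecord:
    """One catalog entry: canonical name, synonyms, categories, bioactivity."""

    canonical_name: str
    synonyms: frozenset[str]
    category: frozenset[str]
    bioactivity: str = ""

    def __post_init__(self) -> None:
        if not self.canonical_name:
            raise ValueError("canonical_name must be non-empty")
        if not self.category or not set(self.category) <= set(CATEGORIES):
            raise ValueError(
                f"{self.canonical_name}: category must be a non-empty subset of {CATEGORIES}"
            )


@dataclass(frozen=True)
class CocktailDefinition:
    """A named, canonicalized, de-duplicated list of SM names."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"cocktail {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"cocktail {self.name!r} has duplicate members")


def _validate_catalog(catalog: Sequence[SMRecord]) -> dict[str, str]:
    """Build the case-folded lookup (name-or-synonym -> canonical name)."""
    lookup: dict[str, str] = {}
    for sm in catalog:
        for name in (sm.canonical_name, *sm.synonyms):
            key = name.strip().casefold()
            if key in lookup and lookup[key] != sm.canonical_name:
                raise ValueError(
                    f"catalog synonym sets are not disjoint: {name!r} maps to both "
                    f"{lookup[key]!r} and {sm.canonical_name!r}"
                )
            lookup[key] = sm.canonical_name
    return lookup


def canonicalize(name: str, catalog: Sequence[SMRecord]) -> str:
    """Resolve a (possibly variant) SM name to its canonical catalog name.

    Matching is case-insensitive over canonical names and synonyms; an
    unknown name raises with the nearest matches listed.
    """
    lookup = _validate_catalog(catalog)
    key = name.strip().casefold()
    if key in lookup:
        return lookup[key]
    near = difflib.get_close_matches(key, lookup.keys(), n=3, cutoff=0.6)
    suggestion = f"; nearest matches: {', '.join(sorted({lookup[m] for m in near}))}" if near else ""
    raise KeyError(f"unknown small molecule {name!r}{suggestion}")


def catalog_record(name: str, catalog: Sequence[SMRecord]) -> SMRecord:
    canonical = canonicalize(name, catalog)
    return next(sm for sm in catalog if sm.canonical_name == canonical)


def cocktail_union(cocktails: Sequence[CocktailDefinition]) -> frozenset[str]:
    """The non-redundant set of SMs used across the given cocktails."""
    out: set[str] = set()
    for c in cocktails:
        out.update(c.members)
    return frozenset(out)


def sm_frequency(cocktails: Sequence[CocktailDefinition]) -> dict[str, int]:
    """How many cocktails contain each SM, sorted by count desc then name."""
    counts: dict[str, int] = {}
    for c in cocktails:
        for m in c.members:
            counts[m] = counts.get(m, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


def category_coverage(
    cocktail: CocktailDefinition, catalog: Sequence[SMRecord]
) -> dict[str, int]:
    """Count cocktail members per functional category.

    A member contributes to every category it is annotated with, so counts
    can sum to more than the cocktail size.
    """
    counts = {cat: 0 for cat in CATEGORIES}
    for member in cocktail.members:
        for cat in catalog_record(member, catalog).category:
            counts[cat] += 1
    return {cat: n for cat, n in counts.items() if n}


def covers_core_categories(
    cocktail: CocktailDefinition, catalog: Sequence[SMRecord]
) -> bool:
    """True when the cocktail has >= 1 epigenetic, signaling and metabolic SM."""
    counts = category_coverage(cocktail, catalog)
    return all(counts.get(cat, 0) >= 1 for cat in CORE_CATEGORIES)


def aggregate_targets(
    cocktail: CocktailDefinition,
    table: Sequence[ChemTargetRecord],
    threshold: float = 0.4,
    id_map: Mapping[str, str] | None = None,
) -> frozenset[str]:
    """Pooled protein targets of a cocktail at a confidence threshold.

    Union over members of targets with combined score >= ``threshold``
    (default 0.4, medium stringency).  ``id_map`` translates canonical SM
    names into the chemical IDs used by the table; by default the table is
    assumed to key on canonical names.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be on [0, 1]")
    ids = {id_map.get(m, m) if id_map else m for m in cocktail.members}
    targets = frozenset(
        r.protein for r in table if r.chemical_id in ids and r.combined_score >= threshold
    )
    if not targets:
        logger.warning(
            "cocktail %r has no targets at threshold %.2f", cocktail.name, threshold
        )
    return targets


def compare_to_tf_targets(
    cocktail_targets: Iterable[str],
    tf_table: TFTargetTable,
    tfs: Iterable[str],
    universe: Iterable[str],
) -> OverlapResult:
    """Fisher test of a cocktail's targets against TF targets.

    ``universe`` should be the symbols present in both the chemical-target
    and the TF-target source.  The TF target set is restricted to that
    universe before testing; an empty restricted TF set is an error.
    """
    uni = set(universe)
    tf_targets = tf_table.targets_of(tfs) & uni
    if not tf_targets:
        raise ValueError("TF target set is empty after restriction to the universe")
    return fisher_overlap(set(cocktail_targets), tf_targets, uni, side="greater")


# -- fixture loading -----------------------------------------------------

def _packaged(name: str) -> Path:
    return Path(str(resources.files("reprognet.data").joinpath(name)))


def load_catalog(path: str | Path | None = None) -> list[SMRecord]:
    """Load an SM catalog TSV (packaged 22-SM catalog by default)."""
    path = _packaged("sm_catalog.tsv") if path is None else path
    rows = _data_rows(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: empty catalog") from None
    if header[:4] != ["canonical_name", "synonyms", "categories", "bioactivity"]:
        raise FormatError(f"{path}: unexpected catalog header {header!r}")
    catalog: list[SMRecord] = []
    for lineno, row in rows:
        if len(row) < 4:
            raise FormatError(f"{path}:{lineno}: expected 4 fields")
        synonyms = frozenset(s.strip() for s in row[1].split(";") if s.strip())
        categories = frozenset(c.strip() for c in row[2].split(";") if c.strip())
        catalog.append(
            SMRecord(
                canonical_name=row[0].strip(),
                synonyms=synonyms,
                category=categories,
                bioactivity=row[3].strip(),
            )
        )
    _validate_catalog(catalog)
    return catalog


def load_cocktails(
    path: str | Path | None = None, catalog: Sequence[SMRecord] | None = None
) -> list[CocktailDefinition]:
    """Load cocktail definitions (packaged ten cocktails by default).

    Format: ``[name]`` headers, one member per line, ``#`` comments.  Members
    are canonicalized against ``catalog`` (packaged catalog by default) and
    de-duplicated, keeping first occurrence order.
    """
    path = _packaged("cocktails.txt") if path is None else path
    catalog = load_catalog() if catalog is None else catalog
    cocktails: list[CocktailDefinition] = []
    name: str | None = None
    members: list[str] = []

    def flush() -> None:
        if name is not None:
            seen: list[str] = []
            for m in members:
                if m not in seen:
                    seen.append(m)
            cocktails.append(CocktailDefinition(name=name, members=tuple(seen)))

    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                flush()
                name = line[1:-1].strip()
                members = []
            elif name is None:
                raise FormatError(f"{path}:{lineno}: member line before any [cocktail] header")
            else:
                members.append(canonicalize(line, catalog))
    flush()
    if not cocktails:
        logger.warning("%s: no cocktail definitions found", path)
    return cocktails


def load_human_metabolome_sms(path: str | Path | None = None) -> list[str]:
    """The SMs also found in the human metabolome (packaged 28-compound list)."""
    path = _packaged("human_metabolome_sms.txt") if path is None else path
    out: list[str] = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
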