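"""Fisher-exact overlap tests and gene-set enrichment with BH correction.

Every test runs against an *explicit* background universe: members of the
compared sets that fall outside the universe are dropped (with a logged
count), never silently added, mirroring analyses restricted to identifiers
present in both source databases.  Enrichment p-values are one-sided
hypergeometric (upper tail); an EASE-style conservative variant (scoring
k-1 hits) is available as a toggle.  "Benjamini correction" means
Benjamini-Hochberg step-up FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection, OrthologMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapResult:
    """Fisher exact test of the overlap of two sets in a universe."""

    n_a: int
    n_b: int
    n_overlap: int
    n_universe: int
    odds_ratio: float
    p_value: float
    test_side: str

    def __post_init__(self) -> None:
        if self.n_overlap > min(self.n_a, self.n_b) or max(self.n_a, self.n_b) > self.n_universe:
            raise ValueError("inconsistent overlap table counts")


def fisher_overlap(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str],
    side: str = "greater",
) -> OverlapResult:
    """Fisher's exact test on the 2x2 table (overlap, a-only, b-only, neither).

    ``side`` is ``"greater"`` (enrichment, the default) or ``"two_sided"``.
    """
    if side not in ("greater", "two_sided"):
        raise ValueError(f"unknown test side {side!r}")
    uni = set(universe)
    if not uni:
        raise ValueError("universe must be non-empty")
    a, b = set(set_a), set(set_b)
    dropped = len(a - uni) + len(b - uni)
    if dropped:
        logger.info("dropping %d set members outside the declared universe", dropped)
    a &= uni
    b &= uni
    k = len(a & b)
    table = [[k, len(a) - k], [len(b) - k, len(uni) - len(a) - len(b) + k]]
    odds, p = stats.fisher_exact(table, alternative=side.replace("_sided", "-sided"))
    return OverlapResult(
        n_a=len(a),
        n_b=len(b),
        n_overlap=k,
        n_universe=len(uni),
        odds_ratio=float(odds),
        p_value=float(p),
        test_side=side,
    )


@dataclass(frozen=True)
class EnrichmentRow:
    """One gene set scored against a query.

    ``fold_enrichment`` is (k/n) / (K/N): query hit rate over universe rate.
    """

    set_name: str
    k: int
    n: int
    K: int
    N: int
    fold_enrichment: float
    p_value: float
    adjusted_p: float


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    if len(p_values) == 0:
        raise ValueError("p_values must be non-empty")
    return list(multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1])


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    ease: bool = False,
) -> list[EnrichmentRow]:
    """Hypergeometric enrichment of every set in ``collection`` for ``query``.

    Query symbols outside the collection's universe are dropped with a
    logged count.  With ``ease=True`` the upper-tail p is computed on k-1
    hits (the conservative jackknifed variant); the default is the plain
    one-sided test.  Rows come back in collection order with BH-adjusted
    p-values; use :func:`significant` for the high-confidence reporting view.
    """
    q = set(query)
    dropped = q - collection.universe
    if dropped:
        logger.info("dropping %d query symbols outside the universe", len(dropped))
    q &= collection.universe
    if not q:
        logger.warning("query does not intersect the collection universe")
        return []
    N, n = len(collection.universe), len(q)
    names, pvals, rows = [], [], []
    for name, members in collection.sets.items():
        K = len(members)
        k = len(q & members)
        fold = (k / n) / (K / N) if K else 0.0
        score_k = max(k - 1, 0) if ease else k
        p = float(stats.hypergeom.sf(score_k - 1, N, K, n)) if K else 1.0
        names.append(name)
        pvals.append(p)
        rows.append((name, k, K, fold, p))
    adjusted = bh_adjust(pvals)
    return [
        EnrichmentRow(
            set_name=name, k=k, n=n, K=K, N=N,
            fold_enrichment=fold, p_value=p, adjusted_p=float(adj),
        )
        for (name, k, K, fold, p), adj in zip(rows, adjusted)
    ]


def significant(
    rows: Iterable[EnrichmentRow],
    max_adjusted_p: float = 0.001,
    min_fold: float = 2.0,
) -> list[EnrichmentRow]:
    """High-confidence reporting filter: adjusted p below the threshold and
    at least the given fold enrichment, sorted by adjusted p then name."""
    kept = [r for r in rows if r.adjusted_p < max_adjusted_p and r.fold_enrichment >= min_fold]
    return sorted(kept, key=lambda r: (r.adjusted_p, r.set_name))


def filter_ortholog_map(
    ortholog_map: OrthologMap, min_score: float = 1.0
) -> dict[str, frozenset[str]]:
    """Source -> target-set map keeping rows with inparalog score >= min_score.

    One-to-many mappings survive as sets; duplicate rows collapse.
    """
    if not 0.0 <= min_score <= 1.0:
        raise ValueError("min_score must be on [0, 1]")
    out: dict[str, set[str]] = {}
    for src, dst, score in ortholog_map.rows:
        if score >= min_score:
            out.setdefault(src, set()).add(dst)
    return {src: frozenset(dsts) for src, dsts in out.items()}
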