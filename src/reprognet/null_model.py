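"""Empirical resampling null for the interconnectivity statistic.

The null distribution of interconnectivity for a query of size ``s`` is
estimated by repeatedly drawing ``s`` distinct nodes uniformly at random
(without replacement, no degree matching) from the cleaned interactome and
computing the observed statistic on each draw.  Three surfaces:

* :func:`sample_null_fraction` — one (size, reps) point: mean and SD;
* :func:`null_curve` — the expectation curve over a size grid, the
  size-stratified picture of how interconnectivity grows with sample size;
* :func:`z_for_observed` / :class:`InterconnectivityModel` — the z-score of
  an observed query against equal-size random draws.

Replicate seeds derive from the master seed through ``numpy``'s
SeedSequence spawning, so results are reproducible and independent of
execution order.  SDs use the unbiased (n-1) denominator; the z-score is
``(observed - mean) / sd`` with no continuity correction and is reported
missing when the null SD is zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .connectivity import (
    InterconnectivityResult,
    largest_component_size,
    largest_connected_fraction,
)
from .interactome import Interactome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NullCurvePoint:
    """Null mean and SD of interconnectivity at one sample size."""

    sample_size: int
    reps: int
    mean_fraction: float
    sd_fraction: float

    def __post_init__(self) -> None:
        if self.reps < 2:
            raise ValueError("reps must be >= 2 to estimate an SD")
        if not 0.0 <= self.mean_fraction <= 1.0 or self.sd_fraction < 0.0:
            raise ValueError("mean_fraction on [0,1] and sd_fraction >= 0 required")


@dataclass(frozen=True)
class NullSummary:
    """An observed interconnectivity against its equal-size null.

    ``z_score`` is ``None`` when the null SD is zero (degenerate null).
    """

    sample_size: int
    reps: int
    mean_fraction: float
    sd_fraction: float
    observed_fraction: float
    z_score: float | None


def _null_fractions(
    g: Interactome, size: int, reps: int, seed: int | np.random.SeedSequence
) -> np.ndarray:
    labels, _, adjacency = g.indexed()
    n = len(labels)
    if size > n:
        raise ValueError(f"sample size {size} exceeds the {n} interactome nodes")
    if size < 2:
        raise ValueError("sample size must be >= 2")
    if reps < 2:
        raise ValueError("reps must be >= 2")
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    fractions = np.empty(reps, dtype=float)
    for i, child in enumerate(master.spawn(reps)):
        rng = np.random.default_rng(child)
        members = set(map(int, rng.choice(n, size=size, replace=False)))
        fractions[i] = largest_component_size(adjacency, members) / size
    return fractions


def sample_null_fraction(
    g: Interactome, size: int, reps: int, seed: int | np.random.SeedSequence
) -> NullCurvePoint:
    """Estimate the null interconnectivity at one sample size."""
    fractions = _null_fractions(g, size, reps, seed)
    return NullCurvePoint(
        sample_size=size,
        reps=reps,
        mean_fraction=float(fractions.mean()),
        sd_fraction=float(fractions.std(ddof=1)),
    )


def null_curve(
    g: Interactome,
    min_size: int = 50,
    max_size: int | None = None,
    step: int = 50,
    reps: int = 100,
    seed: int = 0,
) -> list[NullCurvePoint]:
    """Null expectation curve on the arithmetic size grid min, min+step, ...

    The default floor of 50 nodes avoids the high sampling variability of
    very small node sets.  Per-point seeds spawn deterministically from the
    master seed, so extending the grid never changes earlier points.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if max_size is None:
        max_size = g.number_of_nodes()
    sizes = list(range(min_size, max_size + 1, step))
    if not sizes:
        logger.warning("empty null-curve grid (max_size %d < min_size %d)", max_size, min_size)
        return []
    children = np.random.SeedSequence(seed).spawn(len(sizes))
    return [
        sample_null_fraction(g, size, reps, child)
        for size, child in zip(sizes, children)
    ]


def z_for_observed(
    g: Interactome,
    query: Iterable[str],
    reps: int = 1000,
    seed: int = 0,
) -> NullSummary:
    """z-score of the observed interconnectivity of ``query``.

    The null sample size equals the number of query symbols mapped into the
    interactome, so observed and null fractions share a denominator
    convention.
    """
    observed = largest_connected_fraction(g, query)
    if observed.n_mapped < 2:
        raise ValueError("query must map to at least 2 interactome nodes")
    point = sample_null_fraction(g, observed.n_mapped, reps, seed)
    if point.sd_fraction == 0.0:
        logger.warning("null SD is zero at size %d; z-score undefined", point.sample_size)
        z = None
    else:
        z = (observed.fraction - point.mean_fraction) / point.sd_fraction
    return NullSummary(
        sample_size=point.sample_size,
        reps=reps,
        mean_fraction=point.mean_fraction,
        sd_fraction=point.sd_fraction,
        observed_fraction=observed.fraction,
        z_score=z,
    )


class InterconnectivityModel:
    """Interconnectivity of a query set judged against the resampling null.

    Parameters
    ----------
    interactome : Interactome
        The cleaned control network.
    query : iterable of str
        Protein symbols whose wiring is being evaluated (e.g. the pooled
        targets of a reprogramming cocktail).

    ``fit(reps, seed)`` estimates the equal-size null and returns an
    :class:`InterconnectivityResults` with the observed statistic, the null
    mean/SD and the z-score.
    """

    def __init__(self, interactome: Interactome, query: Iterable[str]):
        self.interactome = interactome
        self.query = frozenset(str(s) for s in query)
        if not self.query:
            raise ValueError("query must be non-empty")
        self.observed: InterconnectivityResult = largest_connected_fraction(
            interactome, self.query
        )

    def fit(self, reps: int = 1000, seed: int = 0) -> "InterconnectivityResults":
        summary = z_for_observed(self.interactome, self.query, reps=reps, seed=seed)
        return InterconnectivityResults(self, summary)


class InterconnectivityResults:
    """Fitted null and z-score for one query set."""

    def __init__(self, model: InterconnectivityModel, null: NullSummary):
        self.model = model
        self.observed = model.observed
        self.null = null
        self.z_score = null.z_score

    @property
    def fraction(self) -> float:
        return self.observed.fraction

    def pvalue_normal(self) -> float | None:
        """One-sided upper-tail p under a normal approximation of the null."""
        if self.z_score is None:
            return None
        return 0.5 * math.erfc(self.z_score / math.sqrt(2.0))

    def summary(self) -> str:
        obs, null = self.observed, self.null
        z = "NA" if self.z_score is None else f"{self.z_score:10.3f}"
        lines = [
            "        Interconnectivity vs. random-sampling null",
            "=" * 58,
            f"query symbols (deduplicated)   {obs.n_input:10d}",
            f"mapped into interactome        {obs.n_mapped:10d}",
            f"largest connected component    {obs.n_lcc:10d}",
            f"observed fraction              {obs.fraction:10.4f}",
            "-" * 58,
            f"null replicates                {null.reps:10d}",
            f"null mean fraction             {null.mean_fraction:10.4f}",
            f"null SD                        {null.sd_fraction:10.4f}",
            f"z-score                        {z}",
            "=" * 58,
        ]
        return "\n".join(lines)
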