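"""Power-law fit to a degree distribution, Cytoscape-regression style.

P(k) here is the *raw count* of nodes with degree exactly k, not a
normalised probability, and the fit is ordinary least squares on
(log10 k, log10 P(k)) over every degree k >= 1 with a positive count —
the plain "degree distribution regression" a network viewer reports, not a
maximum-likelihood tail estimator.  The fitted line log10 P = intercept +
slope * log10 k is reported as P(k) = coefficient * k**exponent with
coefficient = 10**intercept and exponent = slope (typically negative for
heavy-tailed networks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .interactome import Interactome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PowerLawFit:
    """Results of the log-log degree-distribution regression."""

    coefficient: float
    exponent: float
    r_squared: float
    k_range: tuple[int, int]
    n_points: int

    def predict(self, k: float) -> float:
        """Model count at degree k."""
        return self.coefficient * k ** self.exponent

    def summary(self) -> str:
        lines = [
            "     Degree-distribution power-law regression",
            "=" * 50,
            f"model           P(k) = {self.coefficient:.4g} * k^{self.exponent:.4g}",
            f"r-squared       {self.r_squared:10.4f}",
            f"degree range    [{self.k_range[0]}, {self.k_range[1]}]",
            f"fitted points   {self.n_points:10d}",
            "=" * 50,
        ]
        return "\n".join(lines)


def fit_power_law(hist: Mapping[int, int]) -> PowerLawFit:
    """OLS fit of log10 count against log10 degree.

    Degree-0 entries are excluded (their log is undefined) with a logged
    note; at least 3 distinct positive degrees with positive counts are
    required.
    """
    if any(k == 0 for k in hist):
        logger.info("excluding %d nodes of degree 0 from the power-law fit", hist.get(0, 0))
    ks = np.array(sorted(k for k, c in hist.items() if k >= 1 and c > 0), dtype=float)
    if ks.size < 3:
        raise ValueError(
            f"degenerate degree distribution: {ks.size} usable degrees, need >= 3"
        )
    counts = np.array([hist[int(k)] for k in ks], dtype=float)
    reg = stats.linregress(np.log10(ks), np.log10(counts))
    return PowerLawFit(
        coefficient=float(10.0 ** reg.intercept),
        exponent=float(reg.slope),
        r_squared=float(reg.rvalue ** 2),
        k_range=(int(ks[0]), int(ks[-1])),
        n_points=int(ks.size),
    )


class DegreePowerLawModel:
    """Scale-free-topology check for an interactome's degree distribution.

    Built from an :class:`Interactome` (or a precomputed degree histogram);
    ``fit()`` returns a :class:`PowerLawFit`.
    """

    def __init__(self, data: Interactome | Mapping[int, int]):
        if isinstance(data, Interactome):
            self.hist: dict[int, int] = data.degree_histogram()
        else:
            self.hist = dict(data)
        if any(c < 0 for c in self.hist.values()):
            raise ValueError("degree counts must be non-negative")

    def fit(self) -> PowerLawFit:
        return fit_power_law(self.hist)
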