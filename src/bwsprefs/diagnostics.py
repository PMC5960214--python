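"""Consistency and agreement diagnostics for best-worst responses.

Two main tools:

* the implied-pairwise win matrix behind the published heat maps — for a
  response with best b and worst w on block S, the implied dominances are
  b ≻ x for every other x in S and x ≻ w for every x other than b and w;
  cell (i, j) is the proportion of informative responses in which i
  dominated j (cells with no informative responses are flagged as "no
  data", the white patches of the heat map);
* Lin's concordance correlation coefficient (CCC), the agreement-with-the-
  identity-line statistic used to compare preference scales across sites
  and methods (it penalizes location/scale shifts that Pearson's r
  ignores).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalogue import OutcomeCatalogue
from .cohort import ResponseTable
from .design import BlockDesign
from .expansion import _check_rows

__all__ = [
    "PairwiseWinMatrix",
    "CCCResult",
    "win_matrix",
    "lin_ccc",
    "method_agreement",
]

_Z95 = 1.959963984540054


@dataclass
class PairwiseWinMatrix:
    """Implied-dominance proportions for every ordered outcome pair.

    ``proportions``: entry (i, j) = wins(i over j) / support(i, j), NaN on
    the diagonal and wherever no response was informative about the pair.
    On every supported cell, (i, j) + (j, i) = 1.
    """

    catalogue: OutcomeCatalogue
    proportions: pd.DataFrame
    wins: pd.DataFrame
    support: pd.DataFrame

    def supported(self) -> pd.DataFrame:
        """Boolean mask of off-diagonal cells with at least one informative response."""
        return self.support > 0

    def ordered(self, order: Sequence[str]) -> "PairwiseWinMatrix":
        """Reindex rows/columns (e.g. by descending pooled preference)."""
        order = list(order)
        return PairwiseWinMatrix(
            catalogue=self.catalogue,
            proportions=self.proportions.loc[order, order],
            wins=self.wins.loc[order, order],
            support=self.support.loc[order, order],
        )


def win_matrix(
    responses: ResponseTable,
    design: BlockDesign,
    catalogue: OutcomeCatalogue,
    include_worst_losses: bool = True,
) -> PairwiseWinMatrix:
    """Implied-dominance win matrix of a response table.

    With ``include_worst_losses=False`` only the best-choice dominances
    b ≻ x are counted (sensitivity analysis); by default the worst-choice
    dominances x ≻ w are included as well, matching the implied
    paired-comparison coding.
    """
    _check_rows(responses, design, catalogue)
    frame = responses.responses
    a = len(catalogue)
    idx_of = {o: i for i, o in enumerate(catalogue.outcomes)}
    blocks = design.sorted_blocks()
    W = np.zeros((a, a), dtype=np.int64)
    for row in frame.itertuples():
        block = blocks[int(row.scenario_id) - 1]
        b = idx_of[row.best_outcome]
        w = idx_of[row.worst_outcome]
        for x in block:
            if x != b:
                W[b, x] += 1
            if include_worst_losses and x != b and x != w:
                W[x, w] += 1
    support = W + W.T
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(support > 0, W / np.where(support > 0, support, 1), np.nan)
    np.fill_diagonal(P, np.nan)
    names = list(catalogue.outcomes)
    return PairwiseWinMatrix(
        catalogue=catalogue,
        proportions=pd.DataFrame(P, index=names, columns=names),
        wins=pd.DataFrame(W, index=names, columns=names),
        support=pd.DataFrame(support, index=names, columns=names),
    )


@dataclass(frozen=True)
class CCCResult:
    ccc: float
    ci_low: float
    ci_high: float
    n: int

    def __float__(self) -> float:
        return self.ccc


def lin_ccc(x: Sequence[float], y: Sequence[float]) -> CCCResult:
    """Lin's concordance correlation coefficient with a 95% CI.

    CCC = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²) with population (1/n)
    moments. The CI uses Lin's variance of the Fisher-z transform with
    n − 2 degrees of freedom; at |CCC| = 1 the interval degenerates to the
    point.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    sx2 = x.var()
    sy2 = y.var()
    if sx2 == 0 or sy2 == 0:
        raise ValueError("zero variance input: concordance is undefined")
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    shift = x.mean() - y.mean()
    ccc = 2 * sxy / (sx2 + sy2 + shift**2)
    r = sxy / np.sqrt(sx2 * sy2)
    if abs(ccc) >= 1.0 - 1e-12:  # atanh diverges: interval degenerates
        c = float(np.clip(ccc, -1, 1))
        return CCCResult(c, c, c, n)
    u2 = shift**2 / np.sqrt(sx2 * sy2)
    c2 = ccc**2
    var_z = (
        (1 - r**2) * c2 / ((1 - c2) * r**2)
        + 2 * ccc**3 * (1 - ccc) * u2 / (r * (1 - c2) ** 2)
        - ccc**4 * u2**2 / (2 * r**2 * (1 - c2) ** 2)
    ) / (n - 2)
    var_z = max(var_z, 0.0)
    z = np.arctanh(ccc)
    half = _Z95 * np.sqrt(var_z)
    return CCCResult(float(ccc), float(np.tanh(z - half)), float(np.tanh(z + half)), n)


def method_agreement(
    series_by_method: Mapping[str, Mapping[str, pd.Series]],
) -> pd.DataFrame:
    """Pairwise agreement (Lin's CCC) across methods and strata.

    ``series_by_method`` maps method name → {stratum → per-outcome
    series}, e.g. ``{"weight": {...}, "normalized_coefficient": {...},
    "vas": {...}}``. Every pair of (method, stratum) series over a common
    outcome index is compared; rows give the CCC with its 95% CI.
    """
    labelled: list[tuple[str, str, pd.Series]] = []
    for method, strata in series_by_method.items():
        for stratum, series in strata.items():
            labelled.append((method, stratum, series))
    if len(labelled) < 2:
        raise ValueError("need at least two series to compare")
    rows = []
    for (m1, s1, v1), (m2, s2, v2) in itertools.combinations(labelled, 2):
        common = v1.index.intersection(v2.index)
        res = lin_ccc(v1.loc[common].to_numpy(), v2.loc[common].to_numpy())
        rows.append(
            {
                "method_a": m1,
                "stratum_a": s1,
                "method_b": m2,
                "stratum_b": s2,
                "ccc": res.ccc,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "n_outcomes": res.n,
            }
        )
    return pd.DataFrame(rows)
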