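"""Preference weights on the 0–1 probability scale.

The pipeline mirrors treatment-ranking practice from network
meta-analysis:

1. Per respondent, each outcome's B–W score (times chosen most worrisome
   minus times chosen least worrisome) is divided by the number of times
   it was shown, giving a rate in [−1, 1].
2. Each outcome's effect is the standardized mean difference (SMD) of its
   rate against the reference outcome, standardized by the SD of the
   paired per-respondent differences; the SMD vector's covariance is
   estimated from the empirical per-respondent score covariance
   (respondents are the replication units).
3. With a flat prior the posterior of the effect vector is normal at the
   frequentist SMDs with the frequentist covariance. Monte Carlo draws
   from it are ranked (rank 1 = most worrisome) to give the
   rank-probability matrix, and each outcome's preference weight is its
   SUCRA — the surface under the cumulative ranking curve,
   SUCRA_i = (1/(a−1)) Σ_{k=1}^{a−1} P(rank_i ≤ k) ∈ [0, 1]; a weight of
   1 means the outcome is certain to be the most worrisome.
4. Uncertainty: normal variates are simulated around each weight with the
   between-survey variance, resampled with replacement, and the 2.5th /
   97.5th percentiles of the resample means are reported, clipped to
   [0, 1]. A weight at the ceiling 1 is reported one-sided with its upper
   bound fixed at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalogue import OutcomeCatalogue
from .expansion import score_matrix
from .model import UtilityEstimate

__all__ = [
    "BWSummary",
    "RankResult",
    "DegenerateVarianceError",
    "NotPositiveSemiDefiniteError",
    "summarize_bw",
    "rank_probabilities",
    "sucra_from_matrix",
    "sample_ranks",
    "bootstrap_ci",
    "between_stratum_variance",
    "preference_table",
]


class DegenerateVarianceError(ValueError):
    """All respondents identical: paired-difference SD is zero."""


class NotPositiveSemiDefiniteError(ValueError):
    """Covariance passed to the rank sampler is not PSD."""


@dataclass
class BWSummary:
    """Standardized B–W score summary for one stratum.

    ``smd`` is the per-outcome SMD versus the reference (reference exactly
    0); ``cov`` the covariance of the SMD vector (reference row/column 0).
    """

    catalogue: OutcomeCatalogue
    n: int
    mean_rate: pd.Series
    sd_rate: pd.Series
    smd: pd.Series
    se: pd.Series
    cov: pd.DataFrame
    stratum: str = "pooled"


@dataclass
class RankResult:
    """Rank probabilities and SUCRA preference weights for one stratum.

    ``rank_probs``: outcomes × ranks (1 = most worrisome), doubly
    stochastic. ``sucra``: per-outcome weight in [0, 1]; its mean over
    outcomes is exactly 0.5.
    """

    catalogue: OutcomeCatalogue
    rank_probs: pd.DataFrame
    sucra: pd.Series
    n_draws: int
    seed: int
    stratum: str = "pooled"
    ci: pd.DataFrame | None = None

    def write(self, rank_path: str | Path, weights_path: str | Path | None = None) -> None:
        self.rank_probs.to_csv(rank_path)
        if weights_path is not None:
            out = self.sucra.rename("preference_weight").to_frame()
            if self.ci is not None:
                out = out.join(self.ci)
            out.to_csv(weights_path, index_label="outcome")


def summarize_bw(tally: pd.DataFrame, catalogue: OutcomeCatalogue, stratum: str = "pooled") -> BWSummary:
    """Standardized B–W summary from per-respondent tallies.

    The SMD of outcome i versus the reference is mean(d_i)/sd(d_i) where
    d_i is the per-respondent difference of score rates; its SE and the
    cross-outcome covariance follow from the empirical covariance of the
    d vectors divided by n (the reference entry is structurally 0).
    """
    R = score_matrix(tally, catalogue)
    n = len(R)
    if n < 2:
        raise ValueError("need at least two respondents per stratum")
    X = R.to_numpy(dtype=float)
    ref = catalogue.reference_index
    D = X - X[:, [ref]]
    mean_d = D.mean(axis=0)
    sd_d = D.std(axis=0, ddof=1)
    nonref = [i for i in range(len(catalogue)) if i != ref]
    zero_sd = [catalogue.outcomes[i] for i in nonref if sd_d[i] == 0]
    if zero_sd:
        raise DegenerateVarianceError(
            f"zero paired-difference SD (all respondents identical) for: {zero_sd}"
        )
    smd = np.zeros(len(catalogue))
    smd[nonref] = mean_d[nonref] / sd_d[nonref]
    scale = sd_d.copy()
    scale[ref] = 1.0  # reference column of cov is zero anyway
    C = np.cov(D, rowvar=False, ddof=1) / (np.outer(scale, scale) * n)
    C[ref, :] = 0.0
    C[:, ref] = 0.0
    se = np.sqrt(np.diag(C))
    names = list(catalogue.outcomes)
    return BWSummary(
        catalogue=catalogue,
        n=n,
        mean_rate=pd.Series(X.mean(axis=0), index=names, name="mean_rate"),
        sd_rate=pd.Series(X.std(axis=0, ddof=1), index=names, name="sd_rate"),
        smd=pd.Series(smd, index=names, name="smd"),
        se=pd.Series(se, index=names, name="se"),
        cov=pd.DataFrame(C, index=names, columns=names),
        stratum=stratum,
    )


def rank_probabilities(
    means: Sequence[float],
    cov: np.ndarray,
    n_draws: int = 100_000,
    seed: int = 0,
    repair: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte Carlo rank-probability matrix and SUCRA from a normal posterior.

    Draws the effect vector from N(means, cov), ranks each draw descending
    (rank 1 = largest = most worrisome; exact ties broken by a uniformly
    random order within the draw), and returns (rank_probs, sucra).

    ``repair=True`` clips negative covariance eigenvalues at zero instead
    of raising :class:`NotPositiveSemiDefiniteError`.
    """
    mu = np.asarray(means, dtype=float)
    C = np.asarray(cov, dtype=float)
    a = mu.size
    if C.shape != (a, a):
        raise ValueError("cov shape must match means")
    eig = np.linalg.eigvalsh(C)
    tol = 1e-10 * max(1.0, float(np.abs(eig).max()))
    if eig.min() < -tol:
        if not repair:
            raise NotPositiveSemiDefiniteError(
                f"covariance has negative eigenvalue {eig.min():.3g}; pass "
                f"repair=True to project onto the nearest PSD matrix"
            )
        w, Q = np.linalg.eigh(C)
        C = (Q * np.clip(w, 0.0, None)) @ Q.T
    rng = np.random.default_rng(seed)
    X = rng.multivariate_normal(mu, C, size=n_draws, method="eigh")
    # random tie-break: jitter far below the resolution of distinct values
    span = max(1.0, float(np.ptp(mu)) + float(np.sqrt(max(np.diag(C).max(), 0.0))))
    X = X + rng.uniform(0.0, 1e-9 * span, size=X.shape)
    order = np.argsort(-X, axis=1)
    counts = np.empty((a, a), dtype=np.int64)
    for rank in range(a):
        counts[:, rank] = np.bincount(order[:, rank], minlength=a)
    P = counts / float(n_draws)
    return P, sucra_from_matrix(P)


def sucra_from_matrix(rank_probs: np.ndarray | pd.DataFrame) -> np.ndarray:
    """SUCRA_i = (1/(a−1)) Σ_{k<a} P(rank_i ≤ k) from a rank-probability matrix."""
    P = np.asarray(rank_probs, dtype=float)
    a = P.shape[1]
    cum = np.cumsum(P, axis=1)
    return cum[:, : a - 1].sum(axis=1) / (a - 1)


def sample_ranks(
    summary: BWSummary, n_draws: int = 100_000, seed: int = 0, repair: bool = False
) -> RankResult:
    """Rank the posterior of the SMD vector (flat prior ⇒ normal posterior
    centered at the frequentist SMDs with the frequentist covariance)."""
    if n_draws < 1000:
        raise ValueError("n_draws must be at least 1000")
    P, sucra = rank_probabilities(
        summary.smd.to_numpy(), summary.cov.to_numpy(), n_draws=n_draws, seed=seed, repair=repair
    )
    names = list(summary.catalogue.outcomes)
    a = len(names)
    return RankResult(
        catalogue=summary.catalogue,
        rank_probs=pd.DataFrame(P, index=names, columns=[f"rank_{r}" for r in range(1, a + 1)]),
        sucra=pd.Series(sucra, index=names, name="preference_weight"),
        n_draws=n_draws,
        seed=seed,
        stratum=summary.stratum,
    )


def bootstrap_ci(
    weights: pd.Series | Sequence[float],
    between_var: pd.Series | Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
    n_variates: int | None = None,
) -> pd.DataFrame:
    """Percentile-bootstrap 95% CIs for preference weights.

    Per outcome: simulate normal variates with mean the weight and
    variance the between-survey variance, draw ``n_boot`` resamples with
    replacement, take the mean of each, and report the 2.5th/97.5th
    percentiles clipped to [0, 1]. A point weight at the ceiling 1 is
    reported one-sided: its upper bound is the ceiling itself.
    """
    w = np.asarray(weights, dtype=float)
    v = np.asarray(between_var, dtype=float)
    if w.shape != v.shape:
        raise ValueError("weights and between_var must align")
    if np.any(v < 0):
        raise ValueError("between-stratum variances must be non-negative")
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    m = n_boot if n_variates is None else int(n_variates)
    rng = np.random.default_rng(seed)
    lower = np.empty_like(w)
    upper = np.empty_like(w)
    for i in range(w.size):
        variates = rng.normal(w[i], np.sqrt(v[i]), size=m)
        idx = rng.integers(0, m, size=(n_boot, m))
        means = variates[idx].mean(axis=1)
        lower[i], upper[i] = np.percentile(means, [2.5, 97.5])
    lower = np.clip(lower, 0.0, 1.0)
    upper = np.clip(upper, 0.0, 1.0)
    one_sided = w >= 1.0 - 1e-12
    upper[one_sided] = 1.0
    index = weights.index if isinstance(weights, pd.Series) else pd.RangeIndex(w.size)
    return pd.DataFrame(
        {"ci_low": lower, "ci_high": upper, "one_sided": one_sided}, index=index
    )


def between_stratum_variance(
    pooled: pd.Series, strata: Mapping[str, pd.Series]
) -> pd.Series:
    """Per-outcome between-survey variance of the preference weights.

    The mean squared deviation of each stratum's weight from the pooled
    weight — the only between-survey dispersion a two-site design
    supports. User-supplied variances can be passed straight to
    :func:`bootstrap_ci` instead.
    """
    if not strata:
        raise ValueError("need at least one stratum")
    dev2 = sum((s.reindex(pooled.index) - pooled) ** 2 for s in strata.values())
    return (dev2 / len(strata)).rename("between_var")


def preference_table(
    estimates: Mapping[str, UtilityEstimate],
    ranks: Mapping[str, RankResult],
    order_by: str = "pooled",
) -> pd.DataFrame:
    """Merged preference table: log-odds (95% CI) and weights (95% CI) per stratum.

    Rows are outcomes ordered by the ``order_by`` stratum's coefficient,
    descending (most worrisome first), mirroring the published layout.
    """
    if set(estimates) != set(ranks):
        raise ValueError("estimates and ranks must cover the same strata")
    first = next(iter(estimates.values())).catalogue
    for e in estimates.values():
        if e.catalogue.outcomes != first.outcomes:
            raise ValueError("strata use different catalogues")
    for r in ranks.values():
        if r.catalogue.outcomes != first.outcomes:
            raise ValueError("strata use different catalogues")
    key = order_by if order_by in estimates else next(iter(estimates))
    order = estimates[key].coefficients.sort_values(ascending=False).index

    out = pd.DataFrame(
        {
            "outcome": order,
            "harm": [first.is_harm(o) for o in order],
        }
    )
    for stratum in estimates:
        est = estimates[stratum]
        rk = ranks[stratum]
        out[f"coefficient_{stratum}"] = est.coefficients.reindex(order).to_numpy()
        out[f"coef_ci_low_{stratum}"] = est.ci_low.reindex(order).to_numpy()
        out[f"coef_ci_high_{stratum}"] = est.ci_high.reindex(order).to_numpy()
        out[f"weight_{stratum}"] = rk.sucra.reindex(order).to_numpy()
        if rk.ci is not None:
            out[f"weight_ci_low_{stratum}"] = rk.ci["ci_low"].reindex(order).to_numpy()
            out[f"weight_ci_high_{stratum}"] = rk.ci["ci_high"].reindex(order).to_numpy()
    return out
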