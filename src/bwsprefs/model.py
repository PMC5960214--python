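"""Conditional-logit (maxdiff) estimation of relative preferences.

The model: each best-worst answer is a choice among the k(k−1) ordered
(best, worst) candidate pairs of its scenario block, and pair (i, j) has
utility u_i − u_j. With the reference outcome's utility fixed at 0, the
log-likelihood over choice sets c with candidates m is

    ℓ(β) = Σ_c [ (u_best(c) − u_worst(c)) − log Σ_m exp(u_i(m) − u_j(m)) ].

This is a conditional logit on preference *differences*: the chosen 1/−1/0
coded row wins against the other candidate rows of its set. ℓ is concave,
so the Newton iteration with the analytic gradient and observed
information converges to the unique maximizer from any start.

Standard errors come from the inverse observed information; by default
they are replaced by one-way cluster-robust (sandwich) standard errors
clustered on respondent, the standard correction for repeated choices by
the same person. Coefficients are log-odds versus the reference outcome,
the scale of the published preference tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import chi2

from .catalogue import OutcomeCatalogue
from .expansion import PairedChoiceData

__all__ = [
    "UtilityEstimate",
    "SeparationError",
    "ConvergenceError",
    "DegenerateScaleError",
    "loglik",
    "fit",
    "normalize",
    "normalize_coefficients",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


class SeparationError(RuntimeError):
    """Quasi-complete separation: the MLE diverges along one coefficient."""


class ConvergenceError(RuntimeError):
    """Newton iteration failed to reach the gradient tolerance."""


class DegenerateScaleError(ValueError):
    """Min-max normalization of a constant coefficient vector."""


@dataclass
class UtilityEstimate:
    """MLE of the relative preferences (log-odds vs the reference outcome).

    ``coefficients`` spans the full catalogue with the reference fixed at
    exactly 0; ``se``/``ci_low``/``ci_high`` are NaN for the reference (no
    interval is defined for a constrained value). ``vcov`` covers the
    non-reference outcomes.
    """

    catalogue: OutcomeCatalogue
    coefficients: pd.Series
    se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    vcov: pd.DataFrame
    loglik: float
    n_choice_sets: int
    n_candidate_pairs: int
    converged: bool
    n_iter: int
    grad_norm: float
    cluster_by: str
    stratum: str = "pooled"

    def to_frame(self) -> pd.DataFrame:
        """Preference-table columns: outcome, coefficient, se, 95% CI."""
        return pd.DataFrame(
            {
                "stratum": self.stratum,
                "outcome": list(self.catalogue.outcomes),
                "coefficient": self.coefficients.to_numpy(),
                "se": self.se.to_numpy(),
                "ci_low": self.ci_low.to_numpy(),
                "ci_high": self.ci_high.to_numpy(),
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def wald_all_zero(self) -> tuple[float, int, float]:
        """Wald test that all non-reference log-odds are zero.

        Returns (statistic, df, p-value) using the estimate's vcov (robust
        if the fit was clustered).
        """
        beta = self.coefficients[list(self.catalogue.non_reference)].to_numpy()
        V = self.vcov.to_numpy()
        stat = float(beta @ np.linalg.solve(V, beta))
        df = beta.size
        return stat, df, float(chi2.sf(stat, df))


def _full_u(beta: np.ndarray, catalogue: OutcomeCatalogue) -> np.ndarray:
    """Embed the non-reference coefficient vector into the full utility vector."""
    u = np.zeros(len(catalogue))
    j = 0
    for i in range(len(catalogue)):
        if i != catalogue.reference_index:
            u[i] = beta[j]
            j += 1
    return u


def _nonref_indices(catalogue: OutcomeCatalogue) -> np.ndarray:
    return np.array([i for i in range(len(catalogue)) if i != catalogue.reference_index])


def loglik(beta: Sequence[float], data: PairedChoiceData) -> float:
    """Conditional-logit log-likelihood at ``beta`` (non-reference order)."""
    beta = np.asarray(beta, dtype=float)
    p = len(data.catalogue) - 1
    if beta.shape != (p,):
        raise ValueError(f"beta must have length {p}, got shape {beta.shape}")
    u = _full_u(beta, data.catalogue)
    V = u[data.cand_best] - u[data.cand_worst]
    chosen_val = V[np.arange(data.n_choice_sets), data.chosen]
    return float(np.sum(chosen_val - logsumexp(V, axis=1)))


def _choice_probs(u: np.ndarray, data: PairedChoiceData) -> np.ndarray:
    """(n_sets, m) candidate-pair probabilities under full utilities ``u``."""
    V = u[data.cand_best] - u[data.cand_worst]
    V -= V.max(axis=1, keepdims=True)
    E = np.exp(V)
    return E / E.sum(axis=1, keepdims=True)


def _grad_full(u: np.ndarray, data: PairedChoiceData) -> tuple[np.ndarray, np.ndarray]:
    """Gradient of ℓ w.r.t. the *full* utility vector, and per-set fitted means.

    Returns (grad over a outcomes, M) where M[s, o] = E[z_o | set s] under
    the model, z being the ±1 difference coding of a candidate pair.
    """
    a = len(data.catalogue)
    n, m = data.cand_best.shape
    P = _choice_probs(u, data)
    rows = np.repeat(np.arange(n), m)
    M = np.zeros((n, a))
    np.add.at(M, (rows, data.cand_best.ravel()), P.ravel())
    np.subtract.at(M, (rows, data.cand_worst.ravel()), P.ravel())
    obs = np.zeros((n, a))
    sel = np.arange(n)
    np.add.at(obs, (sel, data.cand_best[sel, data.chosen]), 1.0)
    np.subtract.at(obs, (sel, data.cand_worst[sel, data.chosen]), 1.0)
    return (obs - M).sum(axis=0), obs - M


def _information_full(u: np.ndarray, data: PairedChoiceData) -> np.ndarray:
    """Observed information (= expected, for logit) over the full utilities."""
    a = len(data.catalogue)
    n, m = data.cand_best.shape
    P = _choice_probs(u, data)
    cb, cw, pr = data.cand_best.ravel(), data.cand_worst.ravel(), P.ravel()
    # Σ_s Σ_m P_m z_m z_m' accumulated cellwise: z z' has +1 at (b,b),(w,w), −1 off-diagonal
    A = np.zeros((a, a))
    np.add.at(A, (cb, cb), pr)
    np.add.at(A, (cw, cw), pr)
    np.subtract.at(A, (cb, cw), pr)
    np.subtract.at(A, (cw, cb), pr)
    rows = np.repeat(np.arange(n), m)
    M = np.zeros((n, a))
    np.add.at(M, (rows, cb), pr)
    np.subtract.at(M, (rows, cw), pr)
    return A - M.T @ M


def _check_separation(data: PairedChoiceData) -> None:
    """Raise if some outcome is chosen best (or worst) on *every* appearance.

    In that case the likelihood is monotone in that outcome's utility and
    the MLE diverges (quasi-complete separation).
    """
    a = len(data.catalogue)
    n = data.n_choice_sets
    sel = np.arange(n)
    best_o = data.cand_best[sel, data.chosen]
    worst_o = data.cand_worst[sel, data.chosen]
    shown = np.zeros(a, dtype=int)
    for s in range(n):
        # candidate pairs cover the block; each block member appears as some cand_best
        shown_members = np.unique(data.cand_best[s])
        shown[shown_members] += 1
    nbest = np.bincount(best_o, minlength=a)
    nworst = np.bincount(worst_o, minlength=a)
    for o in range(a):
        if shown[o] == 0:
            raise SeparationError(
                f"outcome {data.catalogue.outcomes[o]!r} never appears in any choice set"
            )
        if nbest[o] == shown[o]:
            raise SeparationError(
                f"quasi-complete separation: outcome {data.catalogue.outcomes[o]!r} "
                f"was chosen most worrisome in all {shown[o]} of its appearances; "
                f"its log-odds is unbounded above"
            )
        if nworst[o] == shown[o]:
            raise SeparationError(
                f"quasi-complete separation: outcome {data.catalogue.outcomes[o]!r} "
                f"was chosen least worrisome in all {shown[o]} of its appearances; "
                f"its log-odds is unbounded below"
            )


def fit(
    data: PairedChoiceData,
    cluster_by: str = "respondent",
    start: Sequence[float] | None = None,
    gtol: float = 1e-6,
    maxiter: int = 500,
    stratum: str = "pooled",
) -> UtilityEstimate:
    """Maximum-likelihood fit of the maxdiff conditional logit.

    Parameters
    ----------
    cluster_by
        ``"respondent"`` (default) for one-way cluster-robust sandwich
        standard errors, ``"none"`` for inverse-information standard errors.
    start
        Optional starting coefficient vector; the likelihood is concave so
        the optimum does not depend on it.
    """
    if cluster_by not in {"respondent", "none"}:
        raise ValueError("cluster_by must be 'respondent' or 'none'")
    catalogue = data.catalogue
    _check_separation(data)
    nonref = _nonref_indices(catalogue)
    p = nonref.size
    beta = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()
    if beta.shape != (p,):
        raise ValueError(f"start must have length {p}")

    ll = loglik(beta, data)
    grad_norm = np.inf
    n_iter = 0
    for n_iter in range(1, maxiter + 1):
        u = _full_u(beta, catalogue)
        g_full, _ = _grad_full(u, data)
        g = g_full[nonref]
        grad_norm = float(np.max(np.abs(g)))
        if grad_norm < gtol:
            break
        H = _information_full(u, data)[np.ix_(nonref, nonref)]
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-8 * np.eye(p), g)
        # damped Newton: halve until the (concave) log-likelihood improves
        t = 1.0
        for _ in range(60):
            cand = beta + t * step
            ll_new = loglik(cand, data)
            if ll_new >= ll - 1e-12:
                break
            t /= 2
        beta, ll = beta + t * step, ll_new
    else:
        raise ConvergenceError(
            f"no convergence after {maxiter} Newton iterations "
            f"(max |gradient| = {grad_norm:.3g}, loglik = {ll:.6f})"
        )

    u = _full_u(beta, catalogue)
    H = _information_full(u, data)[np.ix_(nonref, nonref)]
    bread = np.linalg.inv(H)
    if cluster_by == "respondent":
        _, scores_full = _grad_full(u, data)
        scores = scores_full[:, nonref]
        groups = pd.factorize(data.respondent_id)[0]
        n_c = groups.max() + 1
        G = np.zeros((n_c, p))
        np.add.at(G, groups, scores)
        meat = G.T @ G
        V = bread @ meat @ bread * (n_c / max(n_c - 1, 1))
    else:
        V = bread

    a = len(catalogue)
    coef = np.zeros(a)
    coef[nonref] = beta
    se = np.full(a, np.nan)
    se[nonref] = np.sqrt(np.diag(V))
    lo = coef - _Z95 * se
    hi = coef + _Z95 * se
    names = list(catalogue.outcomes)
    nonref_names = [names[i] for i in nonref]
    return UtilityEstimate(
        catalogue=catalogue,
        coefficients=pd.Series(coef, index=names, name="coefficient"),
        se=pd.Series(se, index=names, name="se"),
        ci_low=pd.Series(lo, index=names, name="ci_low"),
        ci_high=pd.Series(hi, index=names, name="ci_high"),
        vcov=pd.DataFrame(V, index=nonref_names, columns=nonref_names),
        loglik=ll,
        n_choice_sets=data.n_choice_sets,
        n_candidate_pairs=data.n_candidate_pairs,
        converged=True,
        n_iter=n_iter,
        grad_norm=grad_norm,
        cluster_by=cluster_by,
        stratum=stratum,
    )


def normalize_coefficients(values: Sequence[float]) -> np.ndarray:
    """Min-max rescale a coefficient vector to [0, 1] (order preserved)."""
    v = np.asarray(values, dtype=float)
    span = v.max() - v.min()
    if span <= 0:
        raise DegenerateScaleError("cannot min-max normalize a constant vector")
    return (v - v.min()) / span


def normalize(estimates: Sequence[UtilityEstimate]) -> list[pd.Series]:
    """Min-max rescale each estimate's full coefficient vector to [0, 1].

    Relative (log-odds) scales are not directly comparable across strata;
    normalization puts them on a common 0–1 scale for agreement checks.
    """
    if len(estimates) < 1:
        raise ValueError("need at least one estimate")
    out = []
    for est in estimates:
        vals = normalize_coefficients(est.coefficients.to_numpy())
        out.append(pd.Series(vals, index=est.coefficients.index, name=f"normalized_{est.stratum}"))
    return out
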