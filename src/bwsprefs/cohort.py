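"""Synthetic best-worst-scaling cohorts.

No respondent-level data were deposited for the two-site statin preference
study, so this module generates survey tables with the statistical
structure the downstream analysis assumes. Each simulated respondent
answers every scenario of the block design; within a scenario with block
S, the (best, worst) = (most, least worrisome) ordered pair (i, j), i ≠ j,
is drawn with probability

    P(i, j) = exp(s·(u_i − u_j)) / Σ_{(p,q) ∈ S×S, p≠q} exp(s·(u_p − u_q)),

the maxdiff pair logit on latent utilities u with a choice-determinism
scale s (s = 0: uniform random answering; s large: deterministic argmax /
argmin). This is exactly the likelihood the estimator maximizes, so
parameter recovery is well-posed. An alternative sequential
best-then-worst rule is available behind ``choice_rule`` for robustness
experiments.

Visual-analogue-scale (VAS) ratings are an affine min–max map of the
utilities onto [0, 100] plus Gaussian noise, clipped to the scale.
Covariates (age, sex, education) are decorative — they do not enter the
choice likelihood — but are generated so cohort summary tables can be
produced and tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .catalogue import OutcomeCatalogue, statin_catalogue
from .design import BlockDesign

__all__ = [
    "CohortSpec",
    "ResponseTable",
    "simulate_cohort",
    "pooled_study_spec",
    "STUDY_UTILITIES",
    "validate_responses",
]

#: Latent utilities used as the default simulation truth: the pooled
#: log-odds of the 13 statin outcomes versus treatment discontinuation,
#: in catalogue order (most to least worrisome, reference last at 0).
_STUDY_COEFFICIENTS = (6.1, 4.6, 3.9, 3.1, 2.6, 2.3, 1.7, 1.4, 1.0, 0.9, 0.6, 0.2, 0.0)

STUDY_UTILITIES: dict[str, float] = {
    name: coef
    for name, coef in zip(statin_catalogue().outcomes, _STUDY_COEFFICIENTS)
}


@dataclass(frozen=True)
class CovariateModel:
    """Site-level covariate distributions (decorative; not in the likelihood)."""

    age_mean: float = 52.9
    age_sd: float = 8.0
    age_range: tuple[float, float] = (40.0, 81.0)
    prop_female: float = 0.5
    education_mean: float = 10.1
    education_sd: float = 4.0


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to simulate one survey site reproducibly."""

    site: str
    n_respondents: int
    true_utilities: Mapping[str, float]
    scale: float = 1.0
    vas_noise_sd: float = 10.0
    covariates: CovariateModel = field(default_factory=CovariateModel)
    choice_rule: str = "maxdiff"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "true_utilities", dict(self.true_utilities))
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")
        if self.scale < 0:
            raise ValueError(f"scale must be non-negative, got {self.scale}")
        if self.vas_noise_sd < 0:
            raise ValueError("vas_noise_sd must be non-negative")
        if self.choice_rule not in {"maxdiff", "sequential"}:
            raise ValueError("choice_rule must be 'maxdiff' or 'sequential'")


@dataclass
class ResponseTable:
    """Best-worst responses plus covariates and optional VAS ratings.

    ``responses`` columns: respondent_id, site, scenario_id (1-based),
    best_outcome, worst_outcome. ``covariates`` is keyed by respondent_id.
    ``vas`` is wide: one ``vas_<outcome>`` column per outcome, in [0, 100].
    """

    responses: pd.DataFrame
    covariates: pd.DataFrame
    vas: pd.DataFrame | None = None

    @property
    def respondents(self) -> pd.Index:
        return pd.Index(self.responses["respondent_id"].unique())

    def concat(self, other: "ResponseTable") -> "ResponseTable":
        """Pool two sites into one table."""
        vas = None
        if self.vas is not None and other.vas is not None:
            vas = pd.concat([self.vas, other.vas], ignore_index=True)
        return ResponseTable(
            responses=pd.concat([self.responses, other.responses], ignore_index=True),
            covariates=pd.concat([self.covariates, other.covariates], ignore_index=True),
            vas=vas,
        )

    def write(self, responses_path: str | Path, covariates_path: str | Path | None = None) -> None:
        frame = self.responses
        if self.vas is not None:
            frame = frame.merge(self.vas, on="respondent_id", how="left")
        frame.to_csv(responses_path, index=False)
        if covariates_path is not None:
            self.covariates.to_csv(covariates_path, index=False)

    @classmethod
    def read(
        cls, responses_path: str | Path, covariates_path: str | Path | None = None
    ) -> "ResponseTable":
        frame = pd.read_csv(responses_path)
        vas_cols = [c for c in frame.columns if c.startswith("vas_")]
        vas = None
        if vas_cols:
            vas = frame[["respondent_id", *vas_cols]].drop_duplicates("respondent_id")
            vas = vas.reset_index(drop=True)
        base_cols = ["respondent_id", "site", "scenario_id", "best_outcome", "worst_outcome"]
        responses = frame[base_cols].copy()
        covariates = (
            pd.read_csv(covariates_path)
            if covariates_path is not None
            else frame[["respondent_id", "site"]].drop_duplicates().reset_index(drop=True)
        )
        return cls(responses=responses, covariates=covariates, vas=vas)


def validate_responses(
    table: ResponseTable, design: BlockDesign, catalogue: OutcomeCatalogue
) -> pd.DataFrame:
    """Row-level validation; returns a frame of offending rows (empty if clean).

    Checks: scenario id in range, best/worst are members of the scenario's
    block, best ≠ worst.
    """
    blocks = design.sorted_blocks()
    idx_of = {o: i for i, o in enumerate(catalogue.outcomes)}
    problems = []
    for row in table.responses.itertuples():
        sid = int(row.scenario_id)
        if not 1 <= sid <= design.b:
            problems.append((row.Index, "scenario_id out of range"))
            continue
        block = set(blocks[sid - 1])
        bi = idx_of.get(row.best_outcome)
        wi = idx_of.get(row.worst_outcome)
        if bi is None or bi not in block:
            problems.append((row.Index, "best_outcome not in scenario block"))
        if wi is None or wi not in block:
            problems.append((row.Index, "worst_outcome not in scenario block"))
        if row.best_outcome == row.worst_outcome:
            problems.append((row.Index, "best_outcome equals worst_outcome"))
    return pd.DataFrame(problems, columns=["row", "problem"])


def _utilities_vector(spec: CohortSpec, catalogue: OutcomeCatalogue) -> np.ndarray:
    missing = [o for o in catalogue.outcomes if o not in spec.true_utilities]
    if missing:
        raise ValueError(f"true_utilities missing catalogue outcomes: {missing}")
    extra = [o for o in spec.true_utilities if o not in catalogue.outcomes]
    if extra:
        raise ValueError(f"true_utilities has outcomes not in catalogue: {extra}")
    u = np.array([float(spec.true_utilities[o]) for o in catalogue.outcomes])
    ref = u[catalogue.reference_index]
    if abs(ref) > 1e-12:
        raise ValueError(
            f"reference outcome {catalogue.reference!r} must have utility 0, got {ref}"
        )
    return u


def _ordered_pairs(block: tuple[int, ...]) -> list[tuple[int, int]]:
    """All k(k−1) ordered (best, worst) pairs, lexicographic in outcome index."""
    return [(i, j) for i in block for j in block if i != j]


def simulate_cohort(
    spec: CohortSpec, design: BlockDesign, catalogue: OutcomeCatalogue
) -> ResponseTable:
    """Simulate one site's complete survey; byte-reproducible from the seed.

    Every respondent answers all ``design.b`` scenarios. Under the default
    maxdiff rule the choice probabilities over the k(k−1) ordered pairs are
    identical across respondents, so choices are drawn scenario-by-scenario
    in a vectorized pass (respondent order fixed by the seed).
    """
    u = _utilities_vector(spec, catalogue)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_respondents
    blocks = design.sorted_blocks()

    width = max(4, len(str(n)))
    resp_ids = [f"{spec.site}-{i + 1:0{width}d}" for i in range(n)]

    # choices[scenario, respondent] = index into the scenario's ordered pairs
    best = np.empty((design.b, n), dtype=int)
    worst = np.empty((design.b, n), dtype=int)
    for s, block in enumerate(blocks):
        pairs = _ordered_pairs(block)
        if spec.choice_rule == "maxdiff":
            diffs = np.array([u[i] - u[j] for i, j in pairs])
            w = np.exp(spec.scale * (diffs - diffs.max()))
            p = w / w.sum()
            draws = rng.choice(len(pairs), size=n, p=p)
            pair_arr = np.array(pairs)
            best[s] = pair_arr[draws, 0]
            worst[s] = pair_arr[draws, 1]
        else:  # sequential: best ∝ exp(s·u), then worst from the rest ∝ exp(−s·u)
            barr = np.array(block)
            wb = np.exp(spec.scale * (u[barr] - u[barr].max()))
            pb = wb / wb.sum()
            bidx = rng.choice(len(barr), size=n, p=pb)
            best[s] = barr[bidx]
            for resp in range(n):
                rest = np.array([t for t in block if t != best[s, resp]])
                ww = np.exp(-spec.scale * (u[rest] - u[rest].min()))
                worst[s, resp] = rng.choice(rest, p=ww / ww.sum())

    rows = {
        "respondent_id": np.repeat(resp_ids, design.b),
        "site": spec.site,
        "scenario_id": np.tile(np.arange(1, design.b + 1), n),
        "best_outcome": [
            catalogue.outcomes[best[s, resp]]
            for resp in range(n)
            for s in range(design.b)
        ],
        "worst_outcome": [
            catalogue.outcomes[worst[s, resp]]
            for resp in range(n)
            for s in range(design.b)
        ],
    }
    responses = pd.DataFrame(rows)

    cov = spec.covariates
    age = np.clip(
        rng.normal(cov.age_mean, cov.age_sd, size=n), cov.age_range[0], cov.age_range[1]
    )
    sex = np.where(rng.random(n) < cov.prop_female, "female", "male")
    edu = np.clip(rng.normal(cov.education_mean, cov.education_sd, size=n), 0.0, 25.0)
    covariates = pd.DataFrame(
        {
            "respondent_id": resp_ids,
            "site": spec.site,
            "age": np.round(age, 1),
            "sex": sex,
            "education_years": np.round(edu, 1),
        }
    )

    lo, hi = u.min(), u.max()
    span = hi - lo
    base = (u - lo) / span * 100.0 if span > 0 else np.full_like(u, 50.0)
    vas_vals = np.clip(
        base[None, :] + rng.normal(0.0, spec.vas_noise_sd, size=(n, len(u))), 0.0, 100.0
    )
    vas = pd.DataFrame(
        np.round(vas_vals, 1),
        columns=[f"vas_{o}" for o in catalogue.outcomes],
    )
    vas.insert(0, "respondent_id", resp_ids)

    return ResponseTable(responses=responses, covariates=covariates, vas=vas)


def pooled_study_spec(
    seed: int = 0, scale: float = 1.0, vas_noise_sd: float = 10.0
) -> tuple[CohortSpec, CohortSpec]:
    """Default two-site specs emulating the statin preference study.

    Sites "Ethiopia" (n = 100) and "Switzerland" (n = 120), totalling the
    study's 220 respondents; the simulation truth is the pooled log-odds
    vector (reference fixed at 0). Covariate distributions follow the
    published cohort summaries (Ethiopian respondents younger, fewer years
    of schooling).
    """
    ethiopia = CohortSpec(
        site="Ethiopia",
        n_respondents=100,
        true_utilities=STUDY_UTILITIES,
        scale=scale,
        vas_noise_sd=vas_noise_sd,
        covariates=CovariateModel(
            age_mean=49.7, age_sd=7.0, prop_female=0.46, education_mean=6.6, education_sd=5.0
        ),
        seed=seed,
    )
    switzerland = CohortSpec(
        site="Switzerland",
        n_respondents=120,
        true_utilities=STUDY_UTILITIES,
        scale=scale,
        vas_noise_sd=vas_noise_sd,
        covariates=CovariateModel(
            age_mean=55.6, age_sd=9.0, prop_female=0.525, education_mean=13.1, education_sd=3.5
        ),
        seed=seed + 1,
    )
    return ethiopia, switzerland
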