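"""Expansion of best-worst responses into implied paired comparisons.

Each best-worst answer on a block of k outcomes is treated as a choice
among the k·(k−1) ordered (best, worst) candidate pairs of that block —
12 candidates per scenario when k = 4. This candidate-set coding is the
unit of the conditional-logit likelihood: a complete two-site study of
100 + 120 respondents on the 13-scenario design yields 2,860 choice sets
and 34,320 candidate pairs pooled (1,300 / 15,600 and 1,560 / 18,720 per
site).

The long-format export uses difference coding: for candidate pair (i, j),
d_o = [o = i] − [o = j] over non-reference outcomes, i.e. the 1 / −1 / 0
coding of best, worst, and unselected outcomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .catalogue import OutcomeCatalogue
from .cohort import ResponseTable, validate_responses
from .design import BlockDesign

__all__ = ["PairedChoiceData", "ExpansionError", "expand", "bw_tally", "collapse", "score_matrix"]


class ExpansionError(ValueError):
    """Raised when responses are inconsistent with the design/catalogue."""


@dataclass
class PairedChoiceData:
    """Candidate-set representation of best-worst responses.

    Arrays are aligned on choice sets (one per respondent × scenario):
    ``cand_best``/``cand_worst`` hold the outcome indices of the k(k−1)
    candidate ordered pairs (lexicographic by (best, worst) index), and
    ``chosen`` the position of the observed pair among them.
    """

    catalogue: OutcomeCatalogue
    design: BlockDesign
    cand_best: np.ndarray  # (n_sets, m) int
    cand_worst: np.ndarray  # (n_sets, m) int
    chosen: np.ndarray  # (n_sets,) int
    respondent_id: np.ndarray  # (n_sets,) object
    site: np.ndarray  # (n_sets,) object
    scenario_id: np.ndarray  # (n_sets,) int

    @property
    def n_choice_sets(self) -> int:
        return self.cand_best.shape[0]

    @property
    def n_candidate_pairs(self) -> int:
        return int(self.cand_best.size)

    @property
    def m(self) -> int:
        """Candidates per choice set, k·(k−1)."""
        return self.cand_best.shape[1]

    def summary(self) -> dict[str, int]:
        return {
            "n_responses": self.n_choice_sets,
            "n_candidate_pairs": self.n_candidate_pairs,
            "n_respondents": len(np.unique(self.respondent_id)),
        }

    def subset(self, mask: np.ndarray) -> "PairedChoiceData":
        """Row-subset of choice sets (e.g. one site's stratum)."""
        return PairedChoiceData(
            catalogue=self.catalogue,
            design=self.design,
            cand_best=self.cand_best[mask],
            cand_worst=self.cand_worst[mask],
            chosen=self.chosen[mask],
            respondent_id=self.respondent_id[mask],
            site=self.site[mask],
            scenario_id=self.scenario_id[mask],
        )

    def by_site(self) -> dict[str, "PairedChoiceData"]:
        return {
            str(s): self.subset(self.site == s) for s in pd.unique(self.site)
        }

    def to_frame(self) -> pd.DataFrame:
        """Long-format estimator input with the 1/−1/0 difference coding."""
        n, m = self.cand_best.shape
        names = self.catalogue.outcomes
        out = pd.DataFrame(
            {
                "response_id": np.repeat(np.arange(n), m),
                "respondent_id": np.repeat(self.respondent_id, m),
                "site": np.repeat(self.site, m),
                "scenario_id": np.repeat(self.scenario_id, m),
                "cand_best": [names[i] for i in self.cand_best.ravel()],
                "cand_worst": [names[j] for j in self.cand_worst.ravel()],
                "chosen": (
                    np.arange(m)[None, :] == self.chosen[:, None]
                ).astype(int).ravel(),
            }
        )
        for o in self.catalogue.non_reference:
            oi = self.catalogue.index(o)
            out[f"d_{o}"] = (
                (self.cand_best.ravel() == oi).astype(int)
                - (self.cand_worst.ravel() == oi).astype(int)
            )
        return out

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _check_rows(
    responses: ResponseTable, design: BlockDesign, catalogue: OutcomeCatalogue
) -> None:
    problems = validate_responses(responses, design, catalogue)
    if not problems.empty:
        head = problems.head(20).to_string(index=False)
        raise ExpansionError(
            f"{len(problems)} invalid response rows (showing up to 20):\n{head}"
        )


def _apply_completeness(
    responses: pd.DataFrame, design: BlockDesign, drop_incomplete: bool
) -> pd.DataFrame:
    counts = responses.groupby("respondent_id", sort=False)["scenario_id"].nunique()
    incomplete = counts[counts < design.b].index
    if len(incomplete) and drop_incomplete:
        warnings.warn(
            f"dropping {len(incomplete)} incomplete respondent(s) "
            f"(answered fewer than {design.b} scenarios): "
            f"{sorted(map(str, incomplete[:10]))}",
            stacklevel=3,
        )
        responses = responses[~responses["respondent_id"].isin(incomplete)]
    return responses.reset_index(drop=True)


def expand(
    responses: ResponseTable,
    design: BlockDesign,
    catalogue: OutcomeCatalogue,
    drop_incomplete: bool = True,
) -> PairedChoiceData:
    """Build the candidate-set data for the conditional-logit estimator.

    Incomplete respondents (fewer than b scenarios) are dropped listwise
    with a warning unless ``drop_incomplete=False``.
    """
    _check_rows(responses, design, catalogue)
    frame = _apply_completeness(responses.responses, design, drop_incomplete)
    n = len(frame)
    k = design.k
    m = k * (k - 1)
    blocks = design.sorted_blocks()
    pair_index: dict[int, dict[tuple[int, int], int]] = {}
    cand_b = np.empty((design.b, m), dtype=int)
    cand_w = np.empty((design.b, m), dtype=int)
    for s, block in enumerate(blocks):
        pairs = [(i, j) for i in block for j in block if i != j]
        pair_index[s] = {p: c for c, p in enumerate(pairs)}
        cand_b[s] = [p[0] for p in pairs]
        cand_w[s] = [p[1] for p in pairs]

    sid = frame["scenario_id"].to_numpy(dtype=int) - 1
    idx_of = {o: i for i, o in enumerate(catalogue.outcomes)}
    best_idx = frame["best_outcome"].map(idx_of).to_numpy(dtype=int)
    worst_idx = frame["worst_outcome"].map(idx_of).to_numpy(dtype=int)
    chosen = np.array(
        [pair_index[s][(b, w)] for s, b, w in zip(sid, best_idx, worst_idx)], dtype=int
    )
    return PairedChoiceData(
        catalogue=catalogue,
        design=design,
        cand_best=cand_b[sid],
        cand_worst=cand_w[sid],
        chosen=chosen,
        respondent_id=frame["respondent_id"].to_numpy(dtype=object),
        site=frame["site"].to_numpy(dtype=object),
        scenario_id=frame["scenario_id"].to_numpy(dtype=int),
    )


def collapse(data: PairedChoiceData) -> pd.DataFrame:
    """Inverse of :func:`expand`: recover the (best, worst) response rows."""
    n = data.n_choice_sets
    rows = np.arange(n)
    names = data.catalogue.outcomes
    return pd.DataFrame(
        {
            "respondent_id": data.respondent_id,
            "site": data.site,
            "scenario_id": data.scenario_id,
            "best_outcome": [names[i] for i in data.cand_best[rows, data.chosen]],
            "worst_outcome": [names[j] for j in data.cand_worst[rows, data.chosen]],
        }
    )


def bw_tally(
    responses: ResponseTable,
    design: BlockDesign,
    catalogue: OutcomeCatalogue,
    drop_incomplete: bool = True,
) -> pd.DataFrame:
    """Per-respondent per-outcome best/worst tallies and B–W scores.

    Returns a long frame with columns respondent_id, site, outcome,
    times_shown, times_best, times_worst, score (= best − worst). For a
    complete respondent times_shown = r and the scores sum to 0.
    """
    _check_rows(responses, design, catalogue)
    frame = _apply_completeness(responses.responses, design, drop_incomplete)
    blocks = design.sorted_blocks()
    a = len(catalogue)
    idx_of = {o: i for i, o in enumerate(catalogue.outcomes)}

    records = []
    for (rid,), grp in frame.groupby(["respondent_id"], sort=False):
        shown = np.zeros(a, dtype=int)
        nbest = np.zeros(a, dtype=int)
        nworst = np.zeros(a, dtype=int)
        for row in grp.itertuples():
            for t in blocks[int(row.scenario_id) - 1]:
                shown[t] += 1
            nbest[idx_of[row.best_outcome]] += 1
            nworst[idx_of[row.worst_outcome]] += 1
        site = grp["site"].iloc[0]
        for t, name in enumerate(catalogue.outcomes):
            records.append(
                (rid, site, name, shown[t], nbest[t], nworst[t], nbest[t] - nworst[t])
            )
    return pd.DataFrame(
        records,
        columns=[
            "respondent_id",
            "site",
            "outcome",
            "times_shown",
            "times_best",
            "times_worst",
            "score",
        ],
    )


def score_matrix(tally: pd.DataFrame, catalogue: OutcomeCatalogue) -> pd.DataFrame:
    """Respondent × outcome matrix of score rates (score / times_shown ∈ [−1, 1])."""
    t = tally.copy()
    t["rate"] = t["score"] / t["times_shown"]
    wide = t.pivot(index="respondent_id", columns="outcome", values="rate")
    return wide[list(catalogue.outcomes)]
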