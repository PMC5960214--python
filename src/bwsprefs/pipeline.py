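"""End-to-end study pipeline: design → simulate/load → expand → fit →
weights → diagnostics → report.

A :class:`StudyConfig` (constructible from a YAML file) fixes the
catalogue, design, cohorts (simulated or loaded from CSV), draw counts and
seeds; :func:`run_pipeline` executes the stages, writes every tabular
artifact as CSV plus heat-map/agreement plots, and returns a
:class:`RunResult`. Identical config and seeds give byte-identical numeric
outputs.
"""

from __future__ import annotations

import platform
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .catalogue import OutcomeCatalogue, statin_catalogue
from .cohort import (
    CohortSpec,
    ResponseTable,
    STUDY_UTILITIES,
    pooled_study_spec,
    simulate_cohort,
)
from .design import BlockDesign, build_bibd, validate_design, write_design
from .diagnostics import method_agreement, win_matrix
from .expansion import PairedChoiceData, bw_tally, expand
from .model import UtilityEstimate, fit, normalize_coefficients
from .ranking import (
    RankResult,
    between_stratum_variance,
    bootstrap_ci,
    preference_table,
    sample_ranks,
    summarize_bw,
)

__all__ = ["StudyConfig", "RunResult", "run_pipeline", "derive_seed"]


def derive_seed(base: int, tag: str) -> int:
    """Deterministic per-stage sub-seed (stable across runs and platforms)."""
    return (int(base) * 1_000_003 + zlib.crc32(tag.encode())) % (2**31)


@dataclass
class StudyConfig:
    """Configuration for one pipeline run.

    Either ``cohorts`` (simulation specs) or ``response_files`` (site →
    responses CSV path) supplies the data; covariates are optional for
    loaded data.
    """

    output_dir: Path
    catalogue: OutcomeCatalogue = field(default_factory=statin_catalogue)
    design_v: int = 13
    design_k: int = 4
    cohorts: tuple[CohortSpec, ...] = ()
    response_files: Mapping[str, str] = field(default_factory=dict)
    n_draws: int = 100_000
    n_boot: int = 1000
    seed: int = 0
    make_plots: bool = True

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if not self.cohorts and not self.response_files:
            raise ValueError("config needs cohorts (simulation) or response_files")
        if self.cohorts and self.response_files:
            raise ValueError("give either cohorts or response_files, not both")

    @classmethod
    def default(cls, output_dir: str | Path, seed: int = 0, **kw) -> "StudyConfig":
        """The two-site study default: Ethiopia n=100, Switzerland n=120."""
        return cls(output_dir=Path(output_dir), cohorts=pooled_study_spec(seed=seed), seed=seed, **kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cohorts = tuple(
            CohortSpec(
                site=c["site"],
                n_respondents=int(c["n_respondents"]),
                true_utilities=c.get("true_utilities", STUDY_UTILITIES),
                scale=float(c.get("scale", 1.0)),
                vas_noise_sd=float(c.get("vas_noise_sd", 10.0)),
                seed=int(c.get("seed", 0)),
            )
            for c in raw.get("cohorts", [])
        )
        return cls(
            output_dir=Path(raw["output_dir"]),
            design_v=int(raw.get("design_v", 13)),
            design_k=int(raw.get("design_k", 4)),
            cohorts=cohorts,
            response_files=raw.get("response_files", {}),
            n_draws=int(raw.get("n_draws", 100_000)),
            n_boot=int(raw.get("n_boot", 1000)),
            seed=int(raw.get("seed", 0)),
            make_plots=bool(raw.get("make_plots", True)),
        )


@dataclass
class RunResult:
    output_dir: Path
    design: BlockDesign
    responses: ResponseTable
    paired: PairedChoiceData
    estimates: dict[str, UtilityEstimate]
    ranks: dict[str, RankResult]
    table: pd.DataFrame
    agreement: pd.DataFrame


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage label
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


def _cohort_summary(responses: ResponseTable) -> pd.DataFrame:
    """Per-site covariate summary in the style of a study Table 1."""
    cov = responses.covariates
    rows = []
    for site, grp in cov.groupby("site", sort=True):
        row: dict[str, object] = {"site": site, "n": len(grp)}
        if "sex" in grp:
            row["female_n"] = int((grp["sex"] == "female").sum())
        for col, label in (("age", "age"), ("education_years", "education")):
            if col in grp:
                row[f"{label}_mean"] = round(float(grp[col].mean()), 1)
                row[f"{label}_sd"] = round(float(grp[col].std(ddof=1)), 1)
        rows.append(row)
    return pd.DataFrame(rows)


def _plot_heatmap(wm, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    data = wm.proportions.to_numpy()
    im = ax.imshow(data, cmap="YlOrBr", vmin=0, vmax=1)
    names = list(wm.proportions.index)
    ax.set_xticks(range(len(names)), names, rotation=90, fontsize=7)
    ax.set_yticks(range(len(names)), names, fontsize=7)
    ax.set_title("P(row outcome judged more worrisome than column)")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_cumulative_ranking(rank: RankResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    P = rank.rank_probs.to_numpy()
    a = P.shape[0]
    cum = np.cumsum(P, axis=1)
    ncol = 4
    nrow = int(np.ceil(a / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.2 * nrow), sharex=True, sharey=True)
    for i, name in enumerate(rank.rank_probs.index):
        ax = axes.ravel()[i]
        ax.step(range(1, a + 1), cum[i], where="post")
        ax.set_ylim(0, 1.02)
        ax.set_title(f"{name}\nSUCRA={rank.sucra.iloc[i]:.2f}", fontsize=7)
    for j in range(a, nrow * ncol):
        axes.ravel()[j].axis("off")
    fig.suptitle(f"Cumulative ranking curves ({rank.stratum})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_agreement(series_a: pd.Series, series_b: pd.Series, labels: tuple[str, str], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    common = series_a.index.intersection(series_b.index)
    ax.scatter(series_a.loc[common], series_b.loc[common])
    lim = [0, max(1.0, series_a.max(), series_b.max()) * 1.05]
    ax.plot(lim, lim, ls="--", c="grey", lw=1)
    ax.set_xlabel(labels[0])
    ax.set_ylabel(labels[1])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: StudyConfig) -> RunResult:
    """Execute the full study pipeline and write all artifacts.

    Stages: design construction and validation; cohort simulation (or
    response loading); paired-comparison expansion; conditional-logit fits
    (pooled and per site); B–W summaries, rank sampling and SUCRA weights
    with bootstrap CIs; win-matrix and agreement diagnostics; Table-1- and
    Table-2-style report.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cat = config.catalogue

    design = _stage("design")(build_bibd)(config.design_v, config.design_k)
    report = validate_design(design)
    if not report.passed:
        raise PipelineError(f"stage 'design' failed validation: {report.failures()}")
    write_design(design, cat, out / "design.csv")

    @_stage("simulate")
    def _get_responses() -> ResponseTable:
        if config.cohorts:
            tables = [simulate_cohort(spec, design, cat) for spec in config.cohorts]
            table = tables[0]
            for t in tables[1:]:
                table = table.concat(t)
            return table
        tables = [ResponseTable.read(p) for p in config.response_files.values()]
        table = tables[0]
        for t in tables[1:]:
            table = table.concat(t)
        return table

    responses = _get_responses()
    responses.write(out / "responses.csv", out / "covariates.csv")

    paired = _stage("expand")(expand)(responses, design, cat)
    paired.write(out / "pairs.csv")
    strata: dict[str, PairedChoiceData] = {"pooled": paired, **paired.by_site()}

    estimates: dict[str, UtilityEstimate] = {}
    for name, data in strata.items():
        estimates[name] = _stage("fit")(fit)(data, stratum=name)
    pd.concat([e.to_frame() for e in estimates.values()]).to_csv(
        out / "estimates.csv", index=False
    )

    @_stage("weights")
    def _weights() -> dict[str, RankResult]:
        ranks: dict[str, RankResult] = {}
        frame = responses.responses
        for name in strata:
            sub = responses if name == "pooled" else ResponseTable(
                responses=frame[frame["site"] == name].reset_index(drop=True),
                covariates=responses.covariates[responses.covariates["site"] == name],
                vas=responses.vas,
            )
            tally = bw_tally(sub, design, cat)
            summary = summarize_bw(tally, cat, stratum=name)
            ranks[name] = sample_ranks(
                summary, n_draws=config.n_draws, seed=derive_seed(config.seed, f"ranks:{name}")
            )
        site_weights = {n: r.sucra for n, r in ranks.items() if n != "pooled"}
        if site_weights:
            bvar = between_stratum_variance(ranks["pooled"].sucra, site_weights)
        else:
            bvar = pd.Series(0.0, index=ranks["pooled"].sucra.index)
        for name, rank in ranks.items():
            rank.ci = bootstrap_ci(
                rank.sucra,
                bvar,
                n_boot=config.n_boot,
                seed=derive_seed(config.seed, f"boot:{name}"),
            )
        return ranks

    ranks = _weights()
    for name, rank in ranks.items():
        rank.write(out / f"rank_probabilities_{name}.csv", out / f"weights_{name}.csv")

    table = _stage("report")(preference_table)(estimates, ranks)
    table.to_csv(out / "preference_table.csv", index=False)

    @_stage("diagnostics")
    def _diagnostics() -> pd.DataFrame:
        order = table["outcome"].tolist()
        frame = responses.responses
        for name in strata:
            sub = responses if name == "pooled" else ResponseTable(
                responses=frame[frame["site"] == name].reset_index(drop=True),
                covariates=responses.covariates,
                vas=responses.vas,
            )
            wm = win_matrix(sub, design, cat).ordered(order)
            wm.proportions.to_csv(out / f"win_matrix_{name}.csv")
            if config.make_plots:
                _plot_heatmap(wm, out / f"heatmap_{name}.png")
        series: dict[str, dict[str, pd.Series]] = {
            "weight": {n: r.sucra for n, r in ranks.items()},
            "normalized_coefficient": {
                n: pd.Series(
                    normalize_coefficients(e.coefficients.to_numpy()),
                    index=e.coefficients.index,
                )
                for n, e in estimates.items()
            },
        }
        if responses.vas is not None:
            vas_cols = {c: c[len("vas_"):] for c in responses.vas.columns if c.startswith("vas_")}
            merged = responses.covariates[["respondent_id", "site"]].merge(
                responses.vas, on="respondent_id"
            )
            vas_series: dict[str, pd.Series] = {}
            vas_series["pooled"] = (
                merged[list(vas_cols)].mean().rename(index=vas_cols) / 100.0
            )
            for site, grp in merged.groupby("site"):
                vas_series[str(site)] = grp[list(vas_cols)].mean().rename(index=vas_cols) / 100.0
            series["vas"] = vas_series
        agreement = method_agreement(series)
        agreement.to_csv(out / "agreement.csv", index=False)
        if config.make_plots:
            site_names = [n for n in ranks if n != "pooled"]
            if len(site_names) == 2:
                _plot_agreement(
                    ranks[site_names[0]].sucra,
                    ranks[site_names[1]].sucra,
                    (f"weight ({site_names[0]})", f"weight ({site_names[1]})"),
                    out / "agreement_weights.png",
                )
            _plot_cumulative_ranking(ranks["pooled"], out / "cumulative_ranking_pooled.png")
        return agreement

    agreement = _diagnostics()

    summary = _cohort_summary(responses)
    summary.to_csv(out / "cohort_summary.csv", index=False)
    _write_report(out, config, design, paired, summary, table, agreement)
    return RunResult(
        output_dir=out,
        design=design,
        responses=responses,
        paired=paired,
        estimates=estimates,
        ranks=ranks,
        table=table,
        agreement=agreement,
    )


def _write_report(
    out: Path,
    config: StudyConfig,
    design: BlockDesign,
    paired: PairedChoiceData,
    summary: pd.DataFrame,
    table: pd.DataFrame,
    agreement: pd.DataFrame,
) -> None:
    lines = [
        "# Best-worst scaling preference analysis — run report",
        "",
        f"- bwsprefs version: {_pkg_version}; numpy {np.__version__}; pandas {pd.__version__}; python {platform.python_version()}",
        f"- master seed: {config.seed}; rank draws: {config.n_draws}; bootstrap samples: {config.n_boot}",
        f"- design: BIBD (v={design.v}, b={design.b}, r={design.r}, k={design.k}, lambda={design.lam})",
        f"- choice sets: {paired.n_choice_sets}; candidate pairs: {paired.n_candidate_pairs}",
        "",
        "## Cohort summary",
        "",
        "```",
        summary.to_string(index=False),
        "```",
        "",
        "## Preference table (most to least worrisome)",
        "",
        "```",
        table.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        "```",
        "",
        "## Method/stratum agreement (Lin's CCC)",
        "",
        "```",
        agreement.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        "```",
        "",
    ]
    (out / "report.md").write_text("\n".join(lines))
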