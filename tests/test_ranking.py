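"""B-W summaries, rank sampling, SUCRA and bootstrap intervals."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from bwsprefs import (
    DegenerateVarianceError,
    bootstrap_ci,
    between_stratum_variance,
    bw_tally,
    fit,
    preference_table,
    rank_probabilities,
    sample_ranks,
    sucra_from_matrix,
    summarize_bw,
)
from bwsprefs.catalogue import OutcomeCatalogue
from bwsprefs.ranking import NotPositiveSemiDefiniteError


@pytest.fixture(scope="module")
def toy_catalogue():
    return OutcomeCatalogue(outcomes=("A", "B", "R"), harm_flags=(True, False, False), reference="R")


def toy_tally(rates, catalogue, times_shown=4):
    """Build a tally frame from a respondents × outcomes matrix of score rates."""
    rows = []
    for r, rates_r in enumerate(rates):
        for o, rate in zip(catalogue.outcomes, rates_r):
            score = int(round(rate * times_shown))
            rows.append((f"r{r}", "toy", o, times_shown, max(score, 0), max(-score, 0), score))
    return pd.DataFrame(
        rows,
        columns=["respondent_id", "site", "outcome", "times_shown", "times_best", "times_worst", "score"],
    )


def test_summarize_bw_hand_computed(toy_catalogue):
    """Four hand-entered respondents: SMDs equal the frozen hand calculation.

    Score-rate matrix (A, B, R):
        (1, 0, −1), (0.5, 0.5, −1), (1, −0.5, −0.5), (0.5, 0, −0.5)
    Paired differences vs R: d_A = (2, 1.5, 1.5, 1), d_B = (1, 1.5, 0, 0.5);
    SMD = mean/sd(ddof=1): 1.5/sqrt(1/6) = 3.67423, 0.75/sqrt(5/12) = 1.16190.
    """
    rates = [(1, 0, -1), (0.5, 0.5, -1), (1, -0.5, -0.5), (0.5, 0, -0.5)]
    summ = summarize_bw(toy_tally(rates, toy_catalogue), toy_catalogue)
    assert summ.smd["R"] == 0.0
    assert summ.smd["A"] == pytest.approx(1.5 / np.sqrt(1 / 6), abs=1e-9)
    assert summ.smd["B"] == pytest.approx(0.75 / np.sqrt(5 / 12), abs=1e-9)
    assert summ.smd["A"] == pytest.approx(3.67423, abs=1e-5)
    assert summ.smd["B"] == pytest.approx(1.16190, abs=1e-5)
    # SE of a paired-difference SMD with the SD treated as fixed: 1/sqrt(n)
    assert summ.se["A"] == pytest.approx(0.5, abs=1e-12)
    assert summ.cov.loc["R"].abs().sum() == 0.0


def test_identical_outcomes_get_equal_smds(toy_catalogue):
    rates = [(0.5, 0.5, -1), (0.25, 0.25, -0.5), (0.75, 0.75, -1), (0.0, 0.0, 0.5)]
    summ = summarize_bw(toy_tally(rates, toy_catalogue), toy_catalogue)
    assert summ.smd["A"] == pytest.approx(summ.smd["B"], abs=1e-12)


def test_identical_respondents_degenerate(toy_catalogue):
    rates = [(1, 0, -1)] * 4
    with pytest.raises(DegenerateVarianceError):
        summarize_bw(toy_tally(rates, toy_catalogue), toy_catalogue)


def test_rank_matrix_doubly_stochastic_and_mean_sucra():
    rng = np.random.default_rng(42)
    means = rng.normal(size=8)
    A = rng.normal(size=(8, 8))
    cov = 0.01 * A @ A.T
    P, sucra = rank_probabilities(means, cov, n_draws=20_000, seed=1)
    np.testing.assert_allclose(P.sum(axis=0), 1.0, atol=1e-9)
    np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)
    assert np.mean(sucra) == pytest.approx(0.5, abs=1e-12)
    assert np.all((sucra >= 0) & (sucra <= 1))


def test_certain_leader_and_uniform_cases():
    P, sucra = rank_probabilities([0.0, 10.0], np.diag([0.01, 0.01]), n_draws=100_000, seed=2)
    assert sucra[1] == pytest.approx(1.0, abs=1e-3)
    assert sucra[0] == pytest.approx(0.0, abs=1e-3)
    # identical posteriors: every SUCRA ~ 0.5, rank probabilities ~ 1/a
    a = 5
    P, sucra = rank_probabilities(np.zeros(a), np.eye(a), n_draws=100_000, seed=3)
    np.testing.assert_allclose(sucra, 0.5, atol=0.01)
    np.testing.assert_allclose(P, 1.0 / a, atol=0.01)


def test_sucra_cumulative_formula_direct():
    P = np.array([[0.6, 0.3, 0.1], [0.3, 0.4, 0.3], [0.1, 0.3, 0.6]])
    s = sucra_from_matrix(P)
    assert s[0] == pytest.approx((0.6 + 0.9) / 2, abs=1e-12)  # = 0.75


def test_three_outcome_sampling_matches_numerical_integration():
    """MC rank probabilities vs exact quadrature for independent normals."""
    mu = np.array([0.8, 0.3, 0.0])
    sd = np.array([0.5, 0.4, 0.6])

    def p_rank1(i):
        others = [j for j in range(3) if j != i]
        f = lambda x: norm.pdf(x, mu[i], sd[i]) * np.prod(
            [norm.cdf(x, mu[j], sd[j]) for j in others]
        )
        return quad(f, -10, 10, limit=200)[0]

    def p_rank3(i):
        others = [j for j in range(3) if j != i]
        f = lambda x: norm.pdf(x, mu[i], sd[i]) * np.prod(
            [norm.sf(x, mu[j], sd[j]) for j in others]
        )
        return quad(f, -10, 10, limit=200)[0]

    P, _ = rank_probabilities(mu, np.diag(sd**2), n_draws=200_000, seed=11)
    for i in range(3):
        assert P[i, 0] == pytest.approx(p_rank1(i), abs=0.01)
        assert P[i, 2] == pytest.approx(p_rank3(i), abs=0.01)
        assert P[i, 1] == pytest.approx(1 - p_rank1(i) - p_rank3(i), abs=0.01)


def test_sucra_shift_invariance_and_sign_equivariance():
    rng = np.random.default_rng(7)
    mu = rng.normal(size=6)
    cov = np.diag(rng.uniform(0.05, 0.2, size=6))
    _, s1 = rank_probabilities(mu, cov, n_draws=100_000, seed=5)
    _, s2 = rank_probabilities(mu + 3.3, cov, n_draws=100_000, seed=5)
    np.testing.assert_allclose(s1, s2, atol=1e-12)  # same seed: identical draws shifted
    _, s3 = rank_probabilities(-mu, cov, n_draws=100_000, seed=6)
    np.testing.assert_allclose(s3, 1 - s1, atol=0.01)


def test_sucra_monotone_in_own_mean():
    """Common random numbers: raising one mean never lowers its SUCRA."""
    base = np.array([0.5, 0.2, -0.1, -0.4])
    cov = 0.09 * np.eye(4)
    prev = -np.inf
    for delta in (0.0, 0.2, 0.4, 0.8):
        mu = base.copy()
        mu[2] += delta
        _, s = rank_probabilities(mu, cov, n_draws=100_000, seed=9)
        assert s[2] >= prev
        prev = s[2]


def test_non_psd_covariance_raises_and_repairs():
    C = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, −1
    with pytest.raises(NotPositiveSemiDefiniteError, match="repair"):
        rank_probabilities([0.0, 0.0], C, n_draws=1000, seed=0)
    P, s = rank_probabilities([0.0, 0.0], C, n_draws=2000, seed=0, repair=True)
    np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)


def test_sample_ranks_reproducible(small_cohort, design13, catalogue):
    tally = bw_tally(small_cohort, design13, catalogue)
    summ = summarize_bw(tally, catalogue)
    r1 = sample_ranks(summ, n_draws=10_000, seed=31)
    r2 = sample_ranks(summ, n_draws=10_000, seed=31)
    pd.testing.assert_frame_equal(r1.rank_probs, r2.rank_probs)
    with pytest.raises(ValueError, match="n_draws"):
        sample_ranks(summ, n_draws=500, seed=1)


def test_bootstrap_zero_variance_gives_point_interval():
    ci = bootstrap_ci(np.array([0.4, 0.7]), np.array([0.0, 0.0]), n_boot=200, seed=1)
    assert ci["ci_low"].tolist() == [0.4, 0.7]
    assert ci["ci_high"].tolist() == [0.4, 0.7]
    assert not ci["one_sided"].any()


def test_bootstrap_ceiling_one_sided():
    ci = bootstrap_ci(np.array([1.0, 0.5]), np.array([0.002, 0.002]), n_boot=500, seed=2)
    assert ci["ci_high"].iloc[0] == 1.0
    assert ci["ci_low"].iloc[0] < 1.0
    assert bool(ci["one_sided"].iloc[0])
    assert not bool(ci["one_sided"].iloc[1])
    assert ((ci[["ci_low", "ci_high"]] >= 0) & (ci[["ci_low", "ci_high"]] <= 1)).all().all()


def test_bootstrap_nominal_coverage():
    """CI for a N(0.5, 0.05) mean covers the truth in about 95% of replications."""
    hits = 0
    n_rep = 500
    for rep in range(n_rep):
        ci = bootstrap_ci(
            np.array([0.5]), np.array([0.05**2]), n_boot=400, seed=rep, n_variates=200
        )
        hits += ci["ci_low"].iloc[0] <= 0.5 <= ci["ci_high"].iloc[0]
    assert 0.91 <= hits / n_rep <= 0.98


def test_bootstrap_rejects_negative_variance():
    with pytest.raises(ValueError, match="non-negative"):
        bootstrap_ci(np.array([0.5]), np.array([-0.01]), n_boot=100, seed=0)


def test_between_stratum_variance_two_sites():
    pooled = pd.Series({"A": 0.8, "B": 0.4})
    s1 = pd.Series({"A": 0.9, "B": 0.35})
    s2 = pd.Series({"A": 0.7, "B": 0.5})
    v = between_stratum_variance(pooled, {"s1": s1, "s2": s2})
    assert v["A"] == pytest.approx((0.01 + 0.01) / 2)
    assert v["B"] == pytest.approx((0.0025 + 0.01) / 2)


def test_preference_table_end_to_end(design13, catalogue):
    from bwsprefs import CohortSpec, expand, simulate_cohort

    u = {o: 0.7 * i for i, o in enumerate(reversed(catalogue.outcomes))}
    spec = CohortSpec(site="pt", n_respondents=250, true_utilities=u, seed=19)
    cohort = simulate_cohort(spec, design13, catalogue)
    est = fit(expand(cohort, design13, catalogue))
    tally = bw_tally(cohort, design13, catalogue)
    summ = summarize_bw(tally, catalogue)
    rank = sample_ranks(summ, n_draws=20_000, seed=3)
    rank.ci = bootstrap_ci(rank.sucra, pd.Series(0.001, index=rank.sucra.index), seed=4)
    table = preference_table({"pooled": est}, {"pooled": rank})
    assert len(table) == 13
    # well-separated truths: the largest-utility outcome leads on both scales
    assert table.iloc[0]["outcome"] == "severe stroke"
    assert table["weight_pooled"].between(0, 1).all()
    assert table.iloc[0]["weight_pooled"] == table["weight_pooled"].max()
    # coefficients and weights agree in rank order
    rho = pd.Series(table["coefficient_pooled"].to_numpy()).corr(
        pd.Series(table["weight_pooled"].to_numpy()), method="spearman"
    )
    assert rho == 1.0
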