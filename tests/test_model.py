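"""Conditional-logit estimation: likelihood oracle, recovery, inference."""

import numpy as np
import pytest
from scipy.optimize import minimize

from bwsprefs import (
    CohortSpec,
    DegenerateScaleError,
    SeparationError,
    expand,
    fit,
    loglik,
    normalize,
    normalize_coefficients,
    simulate_cohort,
)
from bwsprefs.catalogue import OutcomeCatalogue
from bwsprefs.model import _choice_probs

from conftest import manual_response_table


@pytest.fixture(scope="module")
def fano_catalogue():
    return OutcomeCatalogue(
        outcomes=tuple("ABCDEFG"), harm_flags=(False,) * 7, reference="G"
    )


@pytest.fixture(scope="module")
def fano_paired(fano_catalogue, fano):
    u = {o: v for o, v in zip("ABCDEFG", (1.2, 0.8, 0.5, 0.2, -0.3, -0.6, 0.0))}
    spec = CohortSpec(site="fano", n_respondents=2, true_utilities=u, scale=1.0, seed=0)
    table = simulate_cohort(spec, fano, fano_catalogue)
    return expand(table, fano, fano_catalogue)


def brute_force_loglik(beta, paired):
    """Independent re-implementation: explicit loop over candidate pairs."""
    cat = paired.catalogue
    u = {o: 0.0 for o in cat.outcomes}
    for o, b in zip(cat.non_reference, beta):
        u[o] = b
    total = 0.0
    names = cat.outcomes
    for s in range(paired.n_choice_sets):
        vals = [
            u[names[i]] - u[names[j]]
            for i, j in zip(paired.cand_best[s], paired.cand_worst[s])
        ]
        total += vals[paired.chosen[s]] - np.log(sum(np.exp(v) for v in vals))
    return total


def test_loglik_at_zero_is_uniform(small_paired):
    n = small_paired.n_choice_sets
    assert loglik(np.zeros(12), small_paired) == pytest.approx(-n * np.log(12))


def test_loglik_hand_enumerated_single_set(abcd_catalogue, single_block_design):
    table = manual_response_table([("r1", 1, "A", "D")])
    paired = expand(table, single_block_design, abcd_catalogue)
    u = {"A": 1.0, "B": 0.0, "C": 0.0, "D": 0.0}
    denom = sum(
        np.exp(u[i] - u[j]) for i in "ABCD" for j in "ABCD" if i != j
    )
    expected = np.log(np.exp(1.0) / denom)
    beta = np.array([1.0, 0.0, 0.0])  # non-reference order A, B, C
    assert loglik(beta, paired) == pytest.approx(expected, abs=1e-12)
    assert brute_force_loglik(beta, paired) == pytest.approx(expected, abs=1e-12)


def test_probabilities_invariant_to_utility_shift(small_paired):
    u = np.linspace(-1, 2, 13)
    p1 = _choice_probs(u, small_paired)
    p2 = _choice_probs(u + 5.7, small_paired)
    np.testing.assert_allclose(p1, p2, atol=1e-12)


def test_fit_matches_brute_force_on_fano(fano_paired):
    """MLE equals an independent numerical maximization to 1e-3 per coefficient."""
    est = fit(fano_paired, cluster_by="none")
    res = minimize(
        lambda b: -brute_force_loglik(b, fano_paired),
        np.zeros(6),
        method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 20_000, "maxfev": 20_000},
    )
    assert res.success
    ours = est.coefficients[list(fano_paired.catalogue.non_reference)].to_numpy()
    np.testing.assert_allclose(ours, res.x, atol=1e-3)
    assert est.loglik == pytest.approx(-res.fun, abs=1e-6)


def test_optimum_independent_of_start(fano_paired):
    """Concave likelihood: identical optimum from 5 random starts."""
    rng = np.random.default_rng(0)
    ref = fit(fano_paired, cluster_by="none").coefficients.to_numpy()
    for _ in range(5):
        est = fit(fano_paired, cluster_by="none", start=rng.normal(0, 2, size=6))
        np.testing.assert_allclose(est.coefficients.to_numpy(), ref, atol=1e-6)


def test_matches_statsmodels_conditional_logit(small_paired):
    """Cross-check against statsmodels' conditional (fixed-effects) logit."""
    sm = pytest.importorskip("statsmodels.api")
    from statsmodels.discrete.conditional_models import ConditionalLogit

    frame = small_paired.to_frame()
    d_cols = [f"d_{o}" for o in small_paired.catalogue.non_reference]
    model = ConditionalLogit(
        frame["chosen"].to_numpy(),
        frame[d_cols].to_numpy(),
        groups=frame["response_id"].to_numpy(),
    )
    res = model.fit(method="newton", tol=1e-10, maxiter=500, disp=False)
    est = fit(small_paired, cluster_by="none")
    ours = est.coefficients[list(small_paired.catalogue.non_reference)].to_numpy()
    np.testing.assert_allclose(ours, res.params, atol=1e-4)


def test_parameter_recovery_large_n(catalogue, design13):
    """At n=1000 every true utility lies well inside the estimate's interval."""
    u = {o: 0.5 * i for i, o in enumerate(reversed(catalogue.outcomes))}
    spec = CohortSpec(site="big", n_respondents=1000, true_utilities=u, seed=17)
    paired = expand(simulate_cohort(spec, design13, catalogue), design13, catalogue)
    est = fit(paired)
    for o in catalogue.non_reference:
        assert abs(est.coefficients[o] - u[o]) < 4 * est.se[o]
    fitted_order = est.coefficients.sort_values(ascending=False).index.tolist()
    true_order = sorted(u, key=u.get, reverse=True)
    assert fitted_order == true_order


def test_scale_absorbed_into_coefficients(catalogue, design13):
    """Simulating at scale s recovers s·u (scale is not separately identified)."""
    u = {o: 0.4 * i for i, o in enumerate(reversed(catalogue.outcomes))}
    spec = CohortSpec(site="s2", n_respondents=1500, true_utilities=u, scale=2.0, seed=23)
    paired = expand(simulate_cohort(spec, design13, catalogue), design13, catalogue)
    est = fit(paired)
    for o in catalogue.non_reference:
        assert abs(est.coefficients[o] - 2.0 * u[o]) < 4 * est.se[o]


def test_wald_all_zero_calibrated_under_null(catalogue, design13):
    """Uniform answering (scale 0): the all-zero Wald test rarely rejects."""
    not_rejected = 0
    for s in range(20):
        spec = CohortSpec(
            site="null",
            n_respondents=500,
            true_utilities={o: 0.0 for o in catalogue.outcomes},
            scale=0.0,
            seed=100 + s,
        )
        paired = expand(simulate_cohort(spec, design13, catalogue), design13, catalogue)
        est = fit(paired)
        _, _, p = est.wald_all_zero()
        not_rejected += p > 0.05
        assert np.max(np.abs(est.coefficients)) < 0.5
    assert not_rejected >= 18


def test_cluster_robust_and_naive_ses_finite_positive(small_paired):
    robust = fit(small_paired, cluster_by="respondent")
    naive = fit(small_paired, cluster_by="none")
    for est in (robust, naive):
        se = est.se[list(est.catalogue.non_reference)]
        assert np.isfinite(se).all() and (se > 0).all()
        assert np.isnan(est.se[est.catalogue.reference])
        assert est.coefficients[est.catalogue.reference] == 0.0
        V = est.vcov.to_numpy()
        np.testing.assert_allclose(V, V.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(V) > -1e-10)
        lo = est.ci_low[list(est.catalogue.non_reference)]
        hi = est.ci_high[list(est.catalogue.non_reference)]
        coef = est.coefficients[list(est.catalogue.non_reference)]
        assert ((lo <= coef) & (coef <= hi)).all()


def test_separation_raises_named_outcome(catalogue, design13):
    """A deterministic cohort makes the top outcome always-best: MLE diverges."""
    u = {o: (0.0 if o == catalogue.reference else float(i + 1)) for i, o in enumerate(catalogue.outcomes)}
    spec = CohortSpec(site="sep", n_respondents=4, true_utilities=u, scale=1e6, seed=5)
    paired = expand(simulate_cohort(spec, design13, catalogue), design13, catalogue)
    top = max(u, key=u.get)
    with pytest.raises(SeparationError, match=top):
        fit(paired)


def test_normalize_hand_example():
    np.testing.assert_allclose(
        normalize_coefficients([0.0, 2.0, 6.1]), [0.0, 2.0 / 6.1, 1.0], atol=5e-4
    )
    assert normalize_coefficients([0.0, 2.0, 6.1]).round(3).tolist() == [0.0, 0.328, 1.0]


def test_normalize_properties(small_paired):
    est = fit(small_paired)
    (norm,) = normalize([est])
    assert norm.min() == 0.0 and norm.max() == 1.0
    # min-max is invariant to affine maps of the coefficient vector
    v = est.coefficients.to_numpy()
    np.testing.assert_allclose(
        normalize_coefficients(v), normalize_coefficients(3.0 * v + 2.0), atol=1e-12
    )
    order_before = est.coefficients.sort_values().index
    order_after = norm.sort_values().index
    assert list(order_before) == list(order_after)
    with pytest.raises(DegenerateScaleError):
        normalize_coefficients([1.0, 1.0, 1.0])


def test_loglik_dimension_mismatch(small_paired):
    with pytest.raises(ValueError, match="length"):
        loglik(np.zeros(5), small_paired)
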