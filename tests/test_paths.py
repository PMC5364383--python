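"""Path-analysis mechanics: the decomposition identity, exact-fit recovery,
invariances and the quantile summary."""

import numpy as np
import pytest

from fullcycle.paths import (
    VITAL_ORDER,
    PathInputs,
    assemble_path_inputs,
    default_roster,
    fit_all_path_models,
    fit_path_models,
    indirect_effects,
    run_path_analysis,
    summarize_effects,
)


def _synthetic_inputs(D=40, n=24, seed=0, b=None, c=None, noise=0.1):
    """A linear-Gaussian system with known covariate->rate and rate->lambda
    coefficients; every draw is an independent replicate."""
    rng = np.random.default_rng(seed)
    b = {"winter_temp": 0.6, "breeding_density": -0.5} if b is None else b
    roster = {r: list(b) for r in VITAL_ORDER}
    c = dict(zip(VITAL_ORDER, [0.3, 0.3, 0.4, 0.4, 0.25, 0.35])) if c is None else c
    covs = {k: rng.standard_normal(n) for k in b}
    series = {}
    for r in VITAL_ORDER:
        series[r] = sum(b[k] * covs[k] for k in b) + noise * rng.standard_normal((D, n))
    lam = sum(c[r] * series[r] for r in VITAL_ORDER) + noise * rng.standard_normal((D, n))
    series["lam"] = lam

    def std(a):
        return (a - a.mean(axis=-1, keepdims=True)) / a.std(axis=-1, keepdims=True)

    return PathInputs(
        series={k: std(v) for k, v in series.items()},
        covariates={k: std(v[None, :])[0] for k, v in covs.items()},
        years=np.arange(n),
        roster=roster,
    )


def test_decomposition_identity_is_exact():
    inputs = _synthetic_inputs()
    coeffs = fit_all_path_models(inputs)
    eff = indirect_effects(coeffs, inputs.roster)
    for cov in inputs.covariates:
        total = np.zeros(inputs.n_draws)
        for r in VITAL_ORDER:
            ci = inputs.roster[r].index(cov)
            total += coeffs[r][:, ci] * coeffs["lambda"][:, list(VITAL_ORDER).index(r)]
        assert np.array_equal(total, eff["cumulative"][cov])


def test_exact_linear_combination_recovered_to_machine_precision():
    # independent rate series; lambda built as an exact linear combination
    rng = np.random.default_rng(3)
    D, n = 3, 20
    c = np.array([0.3, 0.3, 0.4, 0.4, 0.25, 0.35])
    series = {r: rng.standard_normal((D, n)) for r in VITAL_ORDER}
    for r in series:
        series[r] = (series[r] - series[r].mean(axis=1, keepdims=True)) / series[r].std(
            axis=1, keepdims=True
        )
    lam = sum(ci * series[r] for ci, r in zip(c, VITAL_ORDER))
    sd = lam.std(axis=1, keepdims=True)
    series["lam"] = lam / sd
    cov = rng.standard_normal(n)
    inputs = PathInputs(
        series=series,
        covariates={"winter_temp": (cov - cov.mean()) / cov.std()},
        years=np.arange(n),
        roster={r: ["winter_temp"] for r in VITAL_ORDER},
    )
    coeffs = fit_all_path_models(inputs)
    assert np.allclose(coeffs["lambda"], c / sd, atol=1e-12)
    resid = inputs.series["lam"] - sum(
        coeffs["lambda"][:, i][:, None] * inputs.series[r] for i, r in enumerate(VITAL_ORDER)
    )
    assert np.abs(resid).max() < 1e-10


def test_batched_fit_matches_per_draw_lstsq():
    inputs = _synthetic_inputs(D=7)
    batched = fit_all_path_models(inputs)
    for d in (0, 3, 6):
        single = fit_path_models(inputs, d)
        assert np.allclose(single["lambda"], batched["lambda"][d])
        for r in VITAL_ORDER:
            assert np.allclose(single[r], batched[r][d])


def test_predictor_order_invariance():
    inputs = _synthetic_inputs(D=5)
    coeffs = fit_all_path_models(inputs)
    flipped = PathInputs(
        series=inputs.series, covariates=inputs.covariates, years=inputs.years,
        roster={r: list(reversed(c)) for r, c in inputs.roster.items()},
    )
    coeffs2 = fit_all_path_models(flipped)
    for r in VITAL_ORDER:
        assert np.allclose(coeffs[r], coeffs2[r][:, ::-1])


def test_cumulative_effect_matches_reduced_form_regression():
    """In a fully linear-Gaussian system with no unmodelled paths the
    cumulative indirect effect equals the reduced-form lambda ~ X slope."""
    inputs = _synthetic_inputs(D=300, n=400, noise=0.05, seed=5)
    coeffs = fit_all_path_models(inputs)
    eff = indirect_effects(coeffs, inputs.roster)
    for cov in inputs.covariates:
        x = inputs.covariates[cov]
        reduced = (inputs.series["lam"] * x).sum(axis=1) / (x**2).sum()
        # partial out the other covariate: with 2 correlated-by-chance
        # covariates the reduced form uses the joint regression
        X = np.stack([inputs.covariates[c] for c in inputs.covariates], axis=1)
        G = X.T @ X
        joint = np.linalg.solve(G, X.T @ inputs.series["lam"].T).T
        j = list(inputs.covariates).index(cov)
        assert eff["cumulative"][cov].mean() == pytest.approx(joint[:, j].mean(), abs=0.03)


def test_summary_quantiles_match_sort_oracle():
    inputs = _synthetic_inputs(D=120)
    coeffs = fit_all_path_models(inputs)
    table = summarize_effects(coeffs, inputs.roster)
    row = table[(table.effect_type == "direct") & (table.source == "rho")].iloc[0]
    draws = np.sort(coeffs["lambda"][:, VITAL_ORDER.index("rho")])
    assert row["ci_lo"] == pytest.approx(np.quantile(draws, 0.025))
    assert row["ci_hi"] == pytest.approx(np.quantile(draws, 0.975))
    # identical draws give zero-width intervals
    const = {k: np.ones_like(v) if k == "lambda" else v for k, v in coeffs.items()}
    t2 = summarize_effects({**coeffs, "lambda": np.ones_like(coeffs["lambda"])}, inputs.roster)
    d = t2[(t2.effect_type == "direct") & (t2.target == "lambda")]
    assert (d["ci_hi"] - d["ci_lo"] == 0).all()


def test_assemble_inputs_excludes_gap_years_and_standardizes(study_fit):
    inputs = assemble_path_inputs(study_fit)
    gap = study_fit.data.gap_years
    for t in inputs.years:
        assert t not in gap and (t + 1) not in gap
    T = study_fit.data.n_years
    assert len(inputs.years) == (T - 1) - (len(gap) + 1)
    for name, s in inputs.series.items():
        assert np.allclose(s.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(s.std(axis=1), 1.0, atol=1e-12)


def test_run_path_analysis_end_to_end(study_fit):
    table = run_path_analysis(study_fit)
    assert set(table["effect_type"]) == {"direct", "indirect", "cumulative"}
    cum = table[table.effect_type == "cumulative"].set_index("source")
    roster = default_roster()
    for cov in {c for covs in roster.values() for c in covs}:
        assert cov in cum.index
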