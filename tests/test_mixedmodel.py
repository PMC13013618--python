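"""Laplace logistic GLMM: recovery, reference agreement, bootstrap machinery."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from knowmap.mixedmodel import (
    ConvergenceError,
    GLMMResult,
    GLMMSpec,
    RandomTerm,
    bootstrap_lrt,
    fit_glmm,
    odds_ratio_ci,
)

INTERCEPTS = GLMMSpec(
    random=(RandomTerm("participant", slope=False), RandomTerm("qid", slope=False))
)


def simulate_glmm(
    seed, n_part=30, n_q=12, beta=(-0.5, 1.5), sd_part=0.8, sd_q=0.5
):
    rng = np.random.default_rng(seed)
    part = np.repeat(np.arange(n_part), n_q)
    quest = np.tile(np.arange(n_q), n_part)
    x = rng.uniform(0, 1, n_part * n_q)
    eta = beta[0] + beta[1] * x
    eta += rng.normal(0, sd_part, n_part)[part] + rng.normal(0, sd_q, n_q)[quest]
    y = (rng.random(len(x)) < 1 / (1 + np.exp(-eta))).astype(int)
    return pd.DataFrame(
        {"participant": part, "qid": quest, "knowledge": x, "accuracy": y}
    )


def test_plain_logistic_recovers_slope():
    """No random effects, true log-odds slope 2 at n = 2000."""
    rng = np.random.default_rng(5)
    x = rng.uniform(0, 1, 2000)
    y = (rng.random(2000) < 1 / (1 + np.exp(-(-1 + 2 * x)))).astype(int)
    table = pd.DataFrame({"knowledge": x, "accuracy": y})
    fit = fit_glmm(table, GLMMSpec(random=()))
    assert abs(fit.beta[1] - 2.0) < 0.3
    assert fit.odds_ratio == pytest.approx(np.exp(fit.beta[1]))


def test_plain_logistic_matches_statsmodels():
    import statsmodels.api as sm

    table = simulate_glmm(0, sd_part=0.0, sd_q=0.0)
    fit = fit_glmm(table, GLMMSpec(random=()))
    X = sm.add_constant(table["knowledge"].to_numpy())
    ref = sm.GLM(table["accuracy"].to_numpy(), X,
                 family=sm.families.Binomial()).fit()
    assert np.allclose(fit.beta, ref.params, atol=1e-8)
    assert fit.loglik == pytest.approx(ref.llf, abs=1e-8)


def test_constant_predictor_rejected():
    table = simulate_glmm(1)
    table["knowledge"] = 0.7
    with pytest.raises(ValueError, match="constant"):
        fit_glmm(table, INTERCEPTS)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_laplace_loglik_matches_lme4(tmp_path):
    """Shared fixture: log-likelihood within 1e-3 of glmer (nAGQ = 1)."""
    table = simulate_glmm(42)
    fit = fit_glmm(table, INTERCEPTS, simplify=False,
                   xatol=1e-6, fatol=1e-9, maxfev=4000)
    csv = tmp_path / "fixture.csv"
    table.to_csv(csv, index=False)
    script = tmp_path / "ref.R"
    script.write_text(
        "suppressMessages(library(lme4))\n"
        f"d <- read.csv('{csv}')\n"
        "m <- glmer(accuracy ~ knowledge + (1|participant) + (1|qid),\n"
        "           data=d, family=binomial, nAGQ=1,\n"
        "           control=glmerControl(optimizer='bobyqa'))\n"
        "cat(as.numeric(logLik(m)), fixef(m), '\\n')\n"
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, check=True
    )
    ref_ll, ref_b0, ref_b1 = map(float, out.stdout.split())
    assert fit.loglik == pytest.approx(ref_ll, abs=1e-3)
    assert fit.beta[0] == pytest.approx(ref_b0, abs=5e-3)
    assert fit.beta[1] == pytest.approx(ref_b1, abs=5e-3)


def test_random_intercepts_recovered_and_slopes_dropped():
    """Intercepts-only data: slope variance is ~0 or the slope term dropped."""
    table = simulate_glmm(3, n_part=60, n_q=15, sd_part=1.0, sd_q=0.6)
    fit = fit_glmm(table, GLMMSpec())  # maximal: correlated slopes
    groups = {t.group for t in fit.spec.random}
    assert "participant" in groups
    for term, cov in zip(fit.spec.random, fit.covariances().values()):
        if term.slope:
            assert cov[1, 1] < 0.5  # slope variance shrunk toward zero
    # variance estimates in a plausible range of the generating values
    cov = fit.covariances()
    assert 0.3 < np.sqrt(cov["participant"][0, 0]) < 2.0


def test_simplification_reaches_glm_on_iid_data():
    rng = np.random.default_rng(9)
    table = simulate_glmm(9, sd_part=0.0, sd_q=0.0)
    fit = fit_glmm(table, INTERCEPTS)
    assert fit.simplified_from is not None or not fit.is_singular()


def test_odds_ratio_ci_definition_and_determinism():
    table = simulate_glmm(11, n_part=20, n_q=8)
    or1, ci1 = odds_ratio_ci(table, INTERCEPTS, n_boot=30, seed=5)
    or2, ci2 = odds_ratio_ci(table, INTERCEPTS, n_boot=30, seed=5)
    assert (or1, ci1) == (or2, ci2)
    fit = fit_glmm(table, INTERCEPTS)
    assert or1 == pytest.approx(np.exp(fit.beta[1]))
    assert ci1[0] <= ci1[1]


def test_odds_ratio_ci_covers_null():
    """beta = 0 truth: the CI contains 1 in most replicate datasets."""
    hits = 0
    for seed in range(12):
        table = simulate_glmm(100 + seed, n_part=25, n_q=10,
                              beta=(-0.2, 0.0), sd_part=0.4, sd_q=0.3)
        _, (lo, hi) = odds_ratio_ci(table, INTERCEPTS, n_boot=60, seed=seed)
        hits += lo <= 1.0 <= hi
    assert hits >= 10  # >= ~90% coverage at this resolution


def test_glmm_result_invariants():
    res = GLMMResult(
        beta_knowledge=0.5, OR=float(np.exp(0.5)), OR_CI=(1.0, 3.0),
        lambda_LR=2.0, p_boot=(3 + 1) / (99 + 1), boot_counts=(3, 99),
        converged_structure=(),
    )
    assert res.p_boot == pytest.approx(0.04)
    with pytest.raises(ValueError):
        GLMMResult(0.5, np.exp(0.5), None, 2.0, 0.5, (3, 99), ())
    with pytest.raises(ValueError):
        GLMMResult(0.5, np.exp(0.5), None, -1.0, 0.04, (3, 99), ())


def test_bootstrap_lrt_strong_effect_and_lambda_floor():
    table = simulate_glmm(21, n_part=40, n_q=12, beta=(-1.0, 3.0),
                          sd_part=0.3, sd_q=0.3)
    res = bootstrap_lrt(table, INTERCEPTS, n_sim=49, seed=2)
    assert res.lambda_LR >= 0
    assert res.OR > 1
    assert res.p_boot == pytest.approx(1 / 50)  # no exceedances
    assert res.boot_counts[0] == 0


def test_bootstrap_lrt_null_p_not_extreme():
    table = simulate_glmm(31, n_part=30, n_q=10, beta=(-0.3, 0.0),
                          sd_part=0.4, sd_q=0.3)
    res = bootstrap_lrt(table, INTERCEPTS, n_sim=49, seed=3)
    assert res.p_boot > 0.05
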