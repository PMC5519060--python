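import numpy as np
import pandas as pd
import pytest

from swiddenscape.mixedlm import _neg2ll, _profile, build_design, fit_lmm, select_model


def _grouped_data(rng, n_groups=12, per_group=30, s_u=1.0, s_e=2.0,
                  beta=(5.0, 0.9)):
    rows = []
    for g in range(n_groups):
        u = rng.normal(0, s_u)
        d = rng.uniform(0, 4, per_group)
        y = beta[0] + beta[1] * d + u + rng.normal(0, s_e, per_group)
        for di, yi in zip(d, y):
            rows.append({"community": g, "distance_km": di, "y": yi})
    return pd.DataFrame(rows)


def test_zero_group_variance_matches_ols(rng):
    df = _grouped_data(rng, s_u=0.0, n_groups=10, per_group=60)
    fit = fit_lmm(df, "y", ["distance_km"], "community", "ML")
    X = np.column_stack([np.ones(len(df)), df["distance_km"]])
    beta_ols = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)[0]
    assert np.allclose(fit.beta, beta_ols, atol=1e-6)
    assert fit.sigma2_group < 0.05


def test_balanced_reml_equals_anova_moments(rng):
    # intercept-only balanced one-way layout: REML variance components must
    # equal the classical ANOVA method-of-moments estimators
    g, m = 15, 8
    y = (rng.normal(0, 2.0, size=(g, 1)) + rng.normal(0, 1.5, size=(g, m)) + 10.0)
    df = pd.DataFrame({"community": np.repeat(np.arange(g), m), "y": y.ravel()})
    fit = fit_lmm(df, "y", [], "community", "REML")
    gm = y.mean(axis=1)
    msb = m * np.sum((gm - gm.mean()) ** 2) / (g - 1)
    msw = np.sum((y - gm[:, None]) ** 2) / (g * (m - 1))
    assert fit.sigma2_resid == pytest.approx(msw, rel=1e-4)
    assert fit.sigma2_group == pytest.approx((msb - msw) / m, rel=1e-3)


def test_matches_statsmodels_mixedlm(rng):
    import statsmodels.formula.api as smf

    df = _grouped_data(rng)
    fit = fit_lmm(df, "y", ["distance_km"], "community", "REML")
    sm_fit = smf.mixedlm("y ~ distance_km", df, groups=df["community"]).fit(reml=True)
    assert fit.beta == pytest.approx(sm_fit.fe_params.to_numpy(), abs=1e-4)
    assert fit.se == pytest.approx(sm_fit.bse_fe.to_numpy(), abs=1e-3)
    assert fit.sigma2_resid == pytest.approx(sm_fit.scale, rel=1e-3)
    assert fit.sigma2_group == pytest.approx(
        float(sm_fit.cov_re.iloc[0, 0]), rel=1e-2)


def test_profile_optimality_grid(rng):
    df = _grouped_data(rng)
    groups = df["community"].to_numpy()
    order = np.argsort(groups, kind="stable")
    dfs = df.iloc[order]
    X, _ = build_design(dfs.reset_index(drop=True), ["distance_km"])
    y = dfs["y"].to_numpy()
    _, starts, counts = np.unique(dfs["community"].to_numpy(),
                                  return_index=True, return_counts=True)
    fit = fit_lmm(df, "y", ["distance_km"], "community", "ML")
    theta_hat = fit.sigma2_group / fit.sigma2_resid
    f_hat = _neg2ll(theta_hat, X, y, starts, counts, reml=False)
    for theta in [0.0, 0.01, 0.1, 0.3, 1.0, 3.0, 10.0]:
        assert f_hat <= _neg2ll(theta, X, y, starts, counts, reml=False) + 1e-6


def test_ml_loglik_never_drops_with_extra_covariate(rng):
    df = _grouped_data(rng)
    df["noise"] = rng.normal(size=len(df))
    base = fit_lmm(df, "y", ["distance_km"], "community", "ML")
    bigger = fit_lmm(df, "y", ["distance_km", "noise"], "community", "ML")
    assert bigger.loglik >= base.loglik - 1e-6


def test_categorical_design_and_containment_df(rng):
    rows = []
    classes = ["isolated", "small", "medium", "large"]
    for g in range(31):
        vc = classes[g % 4]
        for _ in range(10):
            rows.append({"community": g, "village_class": vc,
                         "distance_km": rng.uniform(0, 3), "y": rng.normal()})
    df = pd.DataFrame(rows)
    df["village_class"] = pd.Categorical(df["village_class"], categories=classes)
    fit = fit_lmm(df, "y", ["distance_km", "village_class"], "community", "REML")
    assert fit.terms == ["(Intercept)", "distance_km", "village_class[small]",
                        "village_class[medium]", "village_class[large]"]
    by_term = dict(zip(fit.terms, fit.df))
    # village dummies are between-community: df = 31 - 1 - 4 (intercept included)
    assert by_term["village_class[small]"] == 26
    # distance varies within: df = 310 - 31 - 1
    assert by_term["distance_km"] == 278


def test_error_paths(rng):
    df = _grouped_data(rng, n_groups=1)
    with pytest.raises(ValueError, match="2 groups"):
        fit_lmm(df, "y", ["distance_km"], "community")
    df2 = _grouped_data(rng)
    df2["dup"] = df2["distance_km"]
    with pytest.raises(ValueError, match="singular|collinear"):
        fit_lmm(df2, "y", ["distance_km", "dup"], "community")


def test_select_model_rules(rng):
    df = _grouped_data(rng)
    df["noise"] = rng.normal(size=len(df))
    m1 = fit_lmm(df, "y", ["distance_km"], "community", "ML")
    m2 = fit_lmm(df, "y", ["noise"], "community", "ML")
    best = select_model([m1, m2])
    assert best.method == "REML"
    assert best.terms == m1.terms          # distance explains far more
    # ties break toward parsimony
    m1b = fit_lmm(df, "y", ["distance_km"], "community", "ML")
    m3 = fit_lmm(df, "y", ["distance_km", "noise"], "community", "ML")
    m3.aic = m1b.aic                       # force an exact tie
    assert len(select_model([m3, m1b]).terms) == len(m1b.terms)
    # REML refit stays close to ML estimates on well-conditioned data
    assert np.all(np.abs(best.beta - m1.beta) < m1.se / 2)
    with pytest.raises(ValueError, match="ML"):
        select_model([best])


def test_select_model_rejects_differing_data(rng):
    a = fit_lmm(_grouped_data(rng), "y", ["distance_km"], "community", "ML")
    b = fit_lmm(_grouped_data(rng), "y", ["distance_km"], "community", "ML")
    with pytest.raises(ValueError, match="differing data"):
        select_model([a, b])
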