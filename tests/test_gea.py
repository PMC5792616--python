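import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from ridgescan import gea
from ridgescan.grid_io import Grid
from ridgescan.pyramid import build_pyramid, ResolutionLadder


def _simulate(seed=0, n_groups=150, per=5, beta0=0.5, beta1=1.0, sigma=0.8):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, sigma, n_groups)
    gid = np.repeat(np.arange(n_groups), per)
    x = rng.normal(size=n_groups * per)
    p = 1 / (1 + np.exp(-(beta0 + beta1 * x + u[gid])))
    y = (rng.uniform(size=n_groups * per) < p).astype(float)
    return y, x, gid


def test_lrt_pvalue_basics():
    stat, p = gea.lrt_pvalue(-100.0, -100.0)
    assert stat == 0.0 and p == 1.0
    stat, p = gea.lrt_pvalue(-95.0, -100.0)
    assert stat == pytest.approx(10.0)
    assert p == pytest.approx(stats.chi2.sf(10.0, 1))
    # numerically negative differences clip to zero
    assert gea.lrt_pvalue(-100.0000001, -100.0)[0] == 0.0


def test_constant_covariate_is_flagged_not_fatal():
    y = np.r_[np.ones(20), np.zeros(20)]
    fit = gea.fit_binomial_glmm(y, np.full(40, 3.0), np.arange(40) % 8)
    assert not fit.converged
    assert "constant covariate" in fit.message


def test_constant_response_raises():
    with pytest.raises(ValueError, match="constant"):
        gea.fit_binomial_glmm(np.ones(20), None, np.arange(20) % 4)


def test_parameter_recovery_on_simulated_mixed_data():
    y, x, gid = _simulate(seed=1, n_groups=200, per=5)
    fit = gea.fit_binomial_glmm(y, x, gid)
    assert fit.converged
    # generous 3-SE-scale envelopes at n = 1000, 200 groups
    assert fit.beta0 == pytest.approx(0.5, abs=0.35)
    assert fit.beta1 == pytest.approx(1.0, abs=0.35)
    assert fit.sigma_u == pytest.approx(0.8, abs=0.4)
    assert fit.aic == pytest.approx(2 * 3 - 2 * fit.loglik)


def test_sigma_zero_reduction_equals_plain_logistic_regression():
    """The sigma_u -> 0 limit must reproduce ordinary logistic regression
    (statsmodels as the independent oracle), including the LRT statistic."""
    y, x, gid = _simulate(seed=2, sigma=0.0)
    full = gea.fit_binomial_glmm(y, x, gid, sigma_fixed=0.0)
    null = gea.fit_binomial_glmm(y, None, gid, sigma_fixed=0.0)
    sm_full = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
    sm_null = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0)
    assert full.loglik == pytest.approx(sm_full.llf, abs=1e-6)
    assert null.loglik == pytest.approx(sm_null.llf, abs=1e-6)
    stat, _ = gea.lrt_pvalue(full.loglik, null.loglik)
    stat_sm = 2 * (sm_full.llf - sm_null.llf)
    assert stat == pytest.approx(stat_sm, abs=1e-6)
    # the freely-estimated fit can only improve on the sigma = 0 limit
    free = gea.fit_binomial_glmm(y, x, gid)
    assert free.loglik >= full.loglik - 1e-6


def test_laplace_equals_one_node_adaptive_quadrature():
    y, x, gid = _simulate(seed=3, n_groups=60)
    fit = gea.fit_binomial_glmm(y, x, gid)
    lap = gea.agq_loglik(y, x, gid, fit.beta0, fit.beta1, fit.sigma_u, n_nodes=1)
    assert lap == pytest.approx(fit.loglik, abs=1e-6)
    # more nodes refine the approximation but stay in the same neighborhood
    agq9 = gea.agq_loglik(y, x, gid, fit.beta0, fit.beta1, fit.sigma_u, n_nodes=9)
    assert abs(agq9 - fit.loglik) < 0.05 * abs(fit.loglik)


def test_loglik_matches_lme4_glmer_laplace(tmp_path):
    """Independent oracle: R's lme4 with nAGQ = 1 maximizes the same Laplace
    marginal likelihood."""
    y, x, gid = _simulate(seed=42, n_groups=40, per=6, beta0=0.4, beta1=0.9,
                          sigma=0.7)
    csv = tmp_path / "d.csv"
    pd.DataFrame({"y": y.astype(int), "x": x, "g": gid}).to_csv(csv, index=False)
    rscript = textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m1 <- glmer(y ~ x + (1|g), data=d, family=binomial, nAGQ=1)
        cat(fixef(m1), sqrt(unlist(VarCorr(m1))), logLik(m1), sep="\\n")
    """)
    out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    b0_r, b1_r, sig_r, ll_r = map(float, out.stdout.split())
    fit = gea.fit_binomial_glmm(y, x, gid)
    assert fit.loglik == pytest.approx(ll_r, abs=2e-3)
    assert fit.beta0 == pytest.approx(b0_r, abs=5e-3)
    assert fit.beta1 == pytest.approx(b1_r, abs=5e-3)
    assert fit.sigma_u == pytest.approx(sig_r, abs=5e-3)


def test_table_identities_from_published_aic_pairs():
    """chi2(1) p-values recomputed from printed (AIC_null, AIC_full) pairs of
    known significant associations, using stat = dAIC + 2 for one added fixed
    parameter."""
    rows = [(453.4, 390.3, 7.24e-16, 0.025),   # altitude association
            (469.9, 412.3, 1.16e-14, 0.005),   # negative openness
            (491.4, 470.7, 1.85e-06, 0.10)]    # wind exposure
    for aic_null, aic_full, printed, rel in rows:
        stat = aic_null - aic_full + 2
        p = stats.chi2.sf(stat, 1)
        assert p == pytest.approx(printed, rel=rel)


# ---------------------------------------------------------------------------
# Scan-level behavior on a tiny landscape

@pytest.fixture(scope="module")
def tiny_scan_inputs():
    rng = np.random.default_rng(8)
    n = 80
    dem = Grid(rng.uniform(0, 1, (16, 16)) + 100.0, 0.0, 16.0, 1.0)
    pyr = build_pyramid(dem, ResolutionLadder(1.0, factors=(1, 2)))
    samples = pd.DataFrame({
        "id": [f"i{k}" for k in range(n)],
        "x": rng.uniform(0.5, 15.5, n),
        "y": rng.uniform(0.5, 15.5, n),
        "alt": rng.normal(2000, 10, n),
        "plot_id": [f"P{k % 10}" for k in range(n)],
    })
    env = pd.concat([
        pd.DataFrame({"id": samples["id"], "var": "V1", "res": r,
                      "value": rng.normal(size=n)})
        for r in (1.0, 2.0)
    ], ignore_index=True)
    gm = pd.DataFrame((rng.uniform(size=(n, 4)) < 0.5).astype(float),
                      index=samples["id"], columns=["La", "Lb", "Lc", "Ld"])
    return gm, env, samples, pyr


def test_scan_record_count_combinatorics(tiny_scan_inputs):
    gm, env, samples, pyr = tiny_scan_inputs
    res = gea.scan(gm, env, samples, pyr,
                   cfg=gea.ScanConfig(position_vars=("Alt", "X", "Y")))
    # 4 loci x (1 raster var x 2 res + 3 plot-level vars)
    assert len(res) == 4 * (2 + 3)
    assert res.attrs["n_tests"] == len(res)
    assert res.attrs["bonferroni_threshold"] == pytest.approx(0.05 / len(res))
    ok = res.dropna(subset=["p"])
    np.testing.assert_allclose(ok["lrt_stat"],
                               ok["aic_null"] - ok["aic_full"] + 2, atol=1e-6)


def test_membership_covariate_and_frequencies_by_population(tiny_scan_inputs):
    gm, env, samples, pyr = tiny_scan_inputs
    rng = np.random.default_rng(1)
    membership = rng.uniform(size=len(samples))
    res = gea.scan(gm, env, samples, pyr, membership=membership,
                   cfg=gea.ScanConfig(position_vars=("membership",)))
    assert set(res["variable"]) == {"V1", "membership"}
    assert res["freq_A"].notna().all()  # frequencies attached per population


def test_resolution_profile_shape_and_flatness(tiny_scan_inputs):
    gm, env, samples, pyr = tiny_scan_inputs
    env_const = env.copy()
    v = env_const[env_const["res"] == 1.0]["value"].to_numpy()
    env_const.loc[env_const["res"] == 2.0, "value"] = v  # same values at both res
    res = gea.scan(gm, env_const, samples, pyr,
                   cfg=gea.ScanConfig(include_position=False))
    prof = gea.resolution_profile(res, "La", "V1")
    assert len(prof) == 2
    assert prof["neglog10_p"].iloc[0] == pytest.approx(prof["neglog10_p"].iloc[1],
                                                       abs=0.05)
    with pytest.raises(ValueError, match="two or more"):
        gea.resolution_profile(res[res["resolution"] == 1.0], "La", "V1")


def test_evidence_grows_monotonically_with_effect_size(tiny_scan_inputs):
    _, env, samples, pyr = tiny_scan_inputs
    rng = np.random.default_rng(12)
    v = env[env["res"] == 1.0].set_index("id")["value"].loc[samples["id"]].to_numpy()
    x = (v - v.mean()) / v.std()
    med_neglogp = []
    for beta1 in (0.0, 0.5, 1.0, 2.0):
        ps = []
        for rep in range(6):
            p = 1 / (1 + np.exp(-beta1 * x))
            y = (rng.uniform(size=len(x)) < p).astype(float)
            if y.min() == y.max():
                continue
            gm1 = pd.DataFrame({"L": y}, index=samples["id"])
            res = gea.scan(gm1, env, samples, pyr,
                           cfg=gea.ScanConfig(include_position=False,
                                              resolutions=(1.0,)))
            ps.append(res["p"].iloc[0])
        med_neglogp.append(np.median(-np.log10(ps)))
    assert med_neglogp == sorted(med_neglogp)
    assert med_neglogp[-1] > med_neglogp[0] + 2
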