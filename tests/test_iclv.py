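"""Factor analysis and the joint choice + latent-variable likelihood."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from mctpref._draws import halton_normal
from mctpref.encoding import UtilitySpec, encode
from mctpref.estimation import mnl_loglik
from mctpref.iclv import ICLVModel, LatentSpec, MeasurementSpec, _iclv_loglik, factor_loadings
from mctpref.simulate import Measurement, TrueParameters, generate_respondents, simulate_choices


# ---------------------------------------------------------------------------
# factor analysis
# ---------------------------------------------------------------------------


def test_perfectly_correlated_pair_loads_fully():
    rng = np.random.default_rng(0)
    x = (rng.random(500) < 0.4).astype(float)
    res = factor_loadings(pd.DataFrame({"a": x, "b": x}))
    assert res.loadings["a"] == pytest.approx(res.loadings["b"], abs=1e-8)
    assert res.loadings["a"] == pytest.approx(1.0, abs=1e-3)
    assert res.variance_share == pytest.approx(1.0, abs=1e-3)


def test_independent_indicators_show_no_common_factor():
    """On independent data the first factor carries loadings at the sampling
    noise scale sqrt(p/sqrt(n)) and explains almost none of the variance."""
    rng = np.random.default_rng(1)
    df = pd.DataFrame(rng.random((10_000, 4)) < 0.5, dtype=float)
    res = factor_loadings(df)
    assert np.all(np.abs(res.loadings.to_numpy()) < 0.15)
    assert res.variance_share < 0.02


def test_one_factor_data_reproduces_observed_correlations():
    """On data generated from the one-factor fixture, the rank-1 loading
    product reconstructs the observed indicator correlations within 0.05."""
    truth = TrueParameters.fixture()
    resp = generate_respondents(0, 10_000, truth=truth, seed=2)
    cols = ["screened", "had_cancer", "tested", "symptom_count"]
    res = factor_loadings(resp[cols])
    corr = np.corrcoef(resp[cols].to_numpy(), rowvar=False)
    implied = np.outer(res.loadings, res.loadings)
    off = ~np.eye(len(cols), dtype=bool)
    assert np.max(np.abs(implied[off] - corr[off])) < 0.05
    assert res.variance_share > 0.1  # logit links attenuate binary correlations


def test_constant_indicator_rejected():
    df = pd.DataFrame({"a": np.ones(100), "b": np.random.default_rng(3).random(100)})
    with pytest.raises(ValueError, match="a"):
        factor_loadings(df)


# ---------------------------------------------------------------------------
# joint likelihood
# ---------------------------------------------------------------------------


def _public_model(small_design, n=80, seed=50, tau_terms=("early_yes",), truth=None):
    truth = truth or TrueParameters.iclv_fixture()
    resp = generate_respondents(0, n, truth=truth, seed=seed)
    ds = simulate_choices(small_design, resp, truth, seed=seed + 1)
    model = ICLVModel(ds, UtilitySpec.public_split(ds.schema), tau_terms=tau_terms)
    return truth, resp, ds, model


def _closed_form_measurement_ll(model, parts_alpha, kappa, weights=True):
    """Independent Bernoulli / ordered-logit measurement log likelihood at
    zero loadings, computed directly from the formulas."""
    total = 0.0
    for batch in model.bundle.batches:
        for i in range(batch.yb.shape[0]):
            w = batch.w[i]
            contrib = 0.0
            for j, k in enumerate(("screened", "had_cancer", "tested")):
                y = batch.yb[i, j]
                if not np.isfinite(y):
                    continue
                p = expit(parts_alpha[k])
                contrib += y * math.log(p) + (1 - y) * math.log(1 - p)
            y = batch.ys[i]
            if np.isfinite(y):
                kext = np.concatenate([[-np.inf], kappa, [np.inf]])
                hi = expit(kext[int(y) + 1])
                lo = expit(kext[int(y)])
                contrib += math.log(hi - lo)
            total += w * contrib
    return total


def test_iclv_separates_exactly_at_zero_couplings(small_design):
    """With every tau and every loading zero the joint likelihood equals the
    choice log likelihood plus the closed-form measurement log likelihood."""
    truth, _, ds, model = _public_model(small_design)
    lay = model.layout
    rng = np.random.default_rng(4)
    x = np.zeros(lay.n_params)
    x[: lay.K] = rng.normal(0, 0.3, lay.K)
    x[lay.K + lay.M : lay.K + lay.M + lay.P] = 0.1
    i = lay.K + lay.M + lay.P + len(lay.tau_terms)
    x[i : i + len(lay.covs)] = rng.normal(0, 0.3, len(lay.covs))  # gamma free
    i += len(lay.covs)
    alphas = {}
    for k in lay.binary:
        alphas[k] = rng.normal(0, 0.5)
        x[i] = alphas[k]
        x[i + 1] = 0.0  # loading zero
        i += 2
    x[i] = -2.0
    x[i + 1 : i + 16] = math.log(0.4)
    x[i + 16] = 0.0  # symptom loading zero
    draws = halton_normal(model.bundle.n_respondents, 25, 1, seed=5)
    joint = _iclv_loglik(x, model.bundle, lay, draws, want_grad=False)
    choice = mnl_loglik(
        np.concatenate([x[: lay.K], x[lay.K + lay.M : lay.K + lay.M + lay.P]]), model.bundle
    )
    kappa = lay.kappa({"kappa1": x[i], "dln": x[i + 1 : i + 16]})
    meas = _closed_form_measurement_ll(model, alphas, kappa)
    assert joint == pytest.approx(choice + meas, abs=1e-8)


def test_single_indicator_probability_matches_quadrature(small_design):
    """One respondent, one binary indicator: the simulated logit-normal
    Bernoulli mixture matches 50-node Gauss-Hermite quadrature to 1e-3."""
    truth, resp, ds, _ = _public_model(small_design, n=1, seed=60)
    df = ds.df.copy()
    model = ICLVModel(
        df,
        UtilitySpec.public_split(ds.schema),
        measurement=MeasurementSpec(binary=("screened",), include_symptoms=False),
    )
    lay = model.layout
    alpha, zeta = 0.4, 1.1
    x = np.zeros(lay.n_params)
    x[lay.names.index("meas_screened_const")] = alpha
    x[lay.names.index("meas_screened_loading")] = zeta
    draws = halton_normal(1, 10_000, 1, seed=6)
    ll = _iclv_loglik(x, model.bundle, lay, draws, want_grad=False)
    # choice part is uniform (all utility parameters zero)
    n_tasks = model.bundle.n_obs
    ll_meas = ll - n_tasks * math.log(0.5) * model.bundle.batches[0].w[0]
    y = model.bundle.batches[0].yb[0, 0]
    nodes, weights = np.polynomial.hermite.hermgauss(50)
    p1 = float(np.sum(weights / np.sqrt(np.pi) * expit(alpha + zeta * np.sqrt(2) * nodes)))
    expected = p1 if y == 1 else 1 - p1
    assert math.exp(ll_meas) == pytest.approx(expected, abs=1e-3)


def test_location_shift_invariance(small_design):
    """Adding a constant to the structural index while subtracting zeta_k x
    constant from each measurement intercept and tau_j x constant from each
    shifted utility coefficient leaves the likelihood unchanged."""
    truth, resp, ds, _ = _public_model(small_design, n=40, seed=70)
    df = ds.df.copy()
    df["suburban"] = 1  # constant covariate plays the intercept role
    model = ICLVModel(df, UtilitySpec.public_split(ds.schema), tau_terms=("early_yes",))
    lay = model.layout
    rng = np.random.default_rng(7)
    x = rng.normal(0, 0.2, lay.n_params)
    # keep cut points increasing
    i_dln = lay.names.index("meas_symptoms_dln2")
    x[i_dln : i_dln + 15] = math.log(0.4)
    draws = halton_normal(model.bundle.n_respondents, 30, 1, seed=8)
    base = _iclv_loglik(x, model.bundle, lay, draws, want_grad=False)

    a = 0.6
    shifted = x.copy()
    shifted[lay.names.index("lv_on_suburban")] += a
    tau = x[lay.names.index("lv_x_early_yes")]
    shifted[lay.names.index("early_yes")] -= tau * a
    for k in lay.binary:
        zeta = x[lay.names.index(f"meas_{k}_loading")]
        shifted[lay.names.index(f"meas_{k}_const")] -= zeta * a
    shifted[lay.names.index("meas_symptoms_cut1")] += x[lay.names.index("meas_symptoms_loading")] * a
    moved = _iclv_loglik(shifted, model.bundle, lay, draws, want_grad=False)
    assert moved == pytest.approx(base, abs=1e-8)


def test_iclv_gradient_matches_central_differences(small_design):
    truth, _, ds, model = _public_model(small_design, n=50, seed=80,
                                        tau_terms=("ppv_60", "early_yes"))
    lay = model.layout
    rng = np.random.default_rng(9)
    x = rng.normal(0, 0.25, lay.n_params)
    draws = halton_normal(model.bundle.n_respondents, 12, 1, seed=10)
    ll, g = _iclv_loglik(x, model.bundle, lay, draws)
    idx = rng.choice(lay.n_params, size=15, replace=False)
    for j in idx:
        h = 1e-5
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        fd = (
            _iclv_loglik(xp, model.bundle, lay, draws, want_grad=False)
            - _iclv_loglik(xm, model.bundle, lay, draws, want_grad=False)
        ) / (2 * h)
        assert g[j] == pytest.approx(fd, rel=2e-6, abs=1e-8), lay.names[j]


def test_sign_normalisation_flips_whole_latent_block(small_design):
    truth, _, ds, model = _public_model(small_design, n=30, seed=90)
    lay = model.layout
    x = np.random.default_rng(11).normal(0, 0.2, lay.n_params)
    j = lay.names.index("meas_screened_loading")
    x[j] = -0.5
    flipped = model._normalise_sign(x)
    assert flipped[j] == 0.5
    for i, name in enumerate(lay.names):
        if name.startswith(("lv_on_", "lv_x_")) or name.endswith("_loading"):
            assert flipped[i] == -x[i]
        else:
            assert flipped[i] == x[i]


def test_iclv_fit_recovers_latent_effects_small(small_design):
    """Reduced-scale end-to-end sanity: a strong positive latent effect on
    early-stage detection is recovered with the right sign and magnitude."""
    base = TrueParameters.iclv_fixture()
    truth = TrueParameters(
        beta=base.beta, delta=base.delta, sigma={}, lambda_public=1.0,
        lambda_npv_arm=base.lambda_npv_arm, covariate_interactions={},
        tau={"early_yes": base.tau["early_yes"]}, gamma=base.gamma,
    )
    resp = generate_respondents(0, 350, truth=truth, seed=12)
    ds = simulate_choices(small_design, resp, truth, seed=13)
    model = ICLVModel(ds, UtilitySpec.public_split(ds.schema), tau_terms=("early_yes",))
    res = model.fit(n_draws=100, seed=14, maxiter=400)
    assert res.converged
    tau = res.params["lv_x_early_yes"]
    assert tau > 0
    assert abs(tau - truth.tau["early_yes"]) < 4 * res.bse["lv_x_early_yes"]
    post = res.latent_scores()
    lv_truth = resp.set_index("respondent_id")["latent_score"]
    assert np.corrcoef(post, lv_truth.loc[post.index])[0, 1] > 0.5
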