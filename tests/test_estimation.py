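"""Encoding, likelihoods (against oracles), estimation and refinement."""

import math

import numpy as np
import pandas as pd
import pytest

from mctpref._draws import halton_normal
from mctpref.encoding import EncodingError, Interaction, UtilitySpec, encode
from mctpref.estimation import (
    MixedLogit,
    estimate,
    mixed_panel_loglik,
    mnl_loglik,
    null_loglik,
    refine_interactions,
    _panel_loglik,
)
from mctpref.schema import Attribute, AttributeSchema, Profile
from mctpref.simulate import TrueParameters, generate_respondents, simulate_choices


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------


def test_main_effect_columns_count_13(canonical_schema):
    spec = UtilitySpec(canonical_schema)
    assert len(spec.main_columns()) == 13  # 3+3+1+1+1+3+1


def test_all_reference_profile_encodes_to_zero_row(canonical_schema):
    spec = UtilitySpec(canonical_schema)
    row = spec.encode_profile(
        Profile({"ppv": 80, "npv": 99.9, "waiting": "1 week", "cancers": 1,
                 "site": "no", "form": "blood", "early": "no"})
    )
    expected = np.zeros(13)
    expected[spec.main_columns().index("cancers_per10")] = 0.1
    np.testing.assert_allclose(row, expected)


def test_cancers_divisor_ten(canonical_schema):
    spec = UtilitySpec(canonical_schema)
    row = spec.encode_profile(
        Profile({"ppv": 20, "npv": 96.0, "waiting": "1 week", "cancers": 25,
                 "site": "no", "form": "blood", "early": "no"})
    )
    assert row[spec.main_columns().index("cancers_per10")] == pytest.approx(2.5)


def test_unknown_level_raises_encoding_error(canonical_schema, small_design):
    truth = TrueParameters.recovery_fixture()
    resp = generate_respondents(4, 0, truth=truth, seed=0)
    ds = simulate_choices(small_design, resp, truth, seed=0)
    df = ds.df.copy()
    df.loc[df.index[0], "form"] = "saliva"
    with pytest.raises(EncodingError, match="form"):
        encode(df, UtilitySpec(canonical_schema))


# ---------------------------------------------------------------------------
# likelihood oracles
# ---------------------------------------------------------------------------


def _toy_dataset(canonical_schema):
    """3 respondents x 2 tasks, enumerable by hand."""
    profiles = canonical_schema.enumerate_profiles()
    rows = []
    rng = np.random.default_rng(7)
    for rid in range(1, 4):
        for tid in range(1, 3):
            a, b = rng.choice(2048, size=2, replace=False)
            chosen = int(rng.integers(2))
            for alt, pidx in enumerate((a, b)):
                rec = {"respondent_id": rid, "group": "gp", "arm": "full", "block": 1,
                       "task_id": tid, "alternative": alt + 1, "chosen": int(alt == chosen)}
                rec.update(profiles[pidx].assignment)
                rows.append(rec)
    return pd.DataFrame(rows)


def test_mnl_loglik_matches_hand_enumerated_softmax(canonical_schema):
    df = _toy_dataset(canonical_schema)
    spec = UtilitySpec.single_group(canonical_schema)
    bundle = encode(df, spec)
    rng = np.random.default_rng(3)
    beta = rng.normal(0, 0.5, size=13)
    # independent oracle: exhaustive sum of log softmax over raw rows
    cols = spec.main_columns()
    expected = 0.0
    for (_, _), grp in df.groupby(["respondent_id", "task_id"]):
        vs = []
        for _, row in grp.sort_values("alternative").iterrows():
            x = spec.encode_profile(Profile({a.name: row[a.name] for a in canonical_schema}))
            vs.append(float(np.dot(x, beta)))
        chosen = int(grp.sort_values("alternative")["chosen"].to_numpy().argmax())
        denom = math.log(math.exp(vs[0]) + math.exp(vs[1]))
        expected += vs[chosen] - denom
    assert mnl_loglik(beta, bundle) == pytest.approx(expected, rel=1e-10)


def test_uniform_mnl_loglik_is_minus_n_log2(small_pooled_data):
    _, _, ds = small_pooled_data
    spec = UtilitySpec.single_group(ds.schema)
    bundle = encode(ds, spec)
    n_tasks = sum(b.D.shape[0] * b.D.shape[1] for b in bundle.batches)
    assert mnl_loglik(np.zeros(13), bundle) == pytest.approx(-n_tasks * math.log(2))
    assert null_loglik(bundle) == pytest.approx(-n_tasks * math.log(2))


def test_loglik_linear_in_weights(small_pooled_data):
    _, _, ds = small_pooled_data
    spec = UtilitySpec.pooled_default(ds.schema)
    bundle = encode(ds, spec)
    x = np.random.default_rng(0).normal(0, 0.2, size=len(bundle.columns) + 2)
    ll1 = mnl_loglik(x, bundle)
    for b in bundle.batches:
        b.w = b.w * 2
    ll2 = mnl_loglik(x, bundle)
    assert ll2 == pytest.approx(2 * ll1, rel=1e-12)
    for b in bundle.batches:
        b.w = b.w / 2


def test_weighted_loglik_equals_unweighted_for_equal_groups(small_design):
    truth = TrueParameters.recovery_fixture()
    resp = generate_respondents(40, 40, truth=truth, seed=30)
    ds = simulate_choices(small_design, resp, truth, seed=31)
    balanced = UtilitySpec.pooled_default(ds.schema)
    unweighted = UtilitySpec.pooled_default(ds.schema)
    unweighted.weight_rule = "none"
    x = np.random.default_rng(1).normal(0, 0.2, size=len(balanced.all_columns()) + 2)
    assert mnl_loglik(x, encode(ds, balanced)) == pytest.approx(
        mnl_loglik(x, encode(ds, unweighted)), rel=1e-12
    )


@pytest.mark.parametrize("mixed", [False, True])
def test_analytic_gradient_matches_central_differences(small_pooled_data, mixed):
    _, _, ds = small_pooled_data
    spec = UtilitySpec.pooled_default(ds.schema, random_terms=("ppv_60", "early_yes") if mixed else ())
    bundle = encode(ds, spec)
    n_par = len(bundle.columns) + (2 if mixed else 0) + 2
    draws = halton_normal(bundle.n_respondents, 10, 2, seed=5) if mixed else None
    rng = np.random.default_rng(4)
    x = rng.normal(0, 0.3, size=n_par)
    ll, g = _panel_loglik(x, bundle, draws)
    for j in range(n_par):
        h = 1e-5
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        fd = (
            _panel_loglik(xp, bundle, draws, want_grad=False)
            - _panel_loglik(xm, bundle, draws, want_grad=False)
        ) / (2 * h)
        assert g[j] == pytest.approx(fd, rel=1e-6, abs=1e-8)


def test_mixed_loglik_reduces_to_mnl_at_zero_spread(small_pooled_data):
    _, _, ds = small_pooled_data
    spec = UtilitySpec.pooled_default(ds.schema, random_terms=("ppv_60",))
    bundle = encode(ds, spec)
    rng = np.random.default_rng(5)
    theta = rng.normal(0, 0.3, size=len(bundle.columns))
    s = rng.normal(0, 0.1, size=2)
    draws = halton_normal(bundle.n_respondents, 50, 1, seed=6)
    mixed = mixed_panel_loglik(np.concatenate([theta, [0.0], s]), bundle, draws)
    plain = mnl_loglik(np.concatenate([theta, s]), encode(ds, UtilitySpec.pooled_default(ds.schema)))
    assert mixed == pytest.approx(plain, rel=1e-12)


def test_mixed_loglik_invariant_to_draw_permutation(small_pooled_data):
    _, _, ds = small_pooled_data
    spec = UtilitySpec.pooled_default(ds.schema, random_terms=("ppv_60",))
    bundle = encode(ds, spec)
    x = np.random.default_rng(6).normal(0, 0.3, size=len(bundle.columns) + 3)
    draws = halton_normal(bundle.n_respondents, 40, 1, seed=7)
    ll1 = mixed_panel_loglik(x, bundle, draws)
    perm = np.random.default_rng(8).permutation(40)
    ll2 = mixed_panel_loglik(x, bundle, draws[:, perm, :])
    assert ll2 == pytest.approx(ll1, rel=1e-12)


def test_simulated_mixing_probability_matches_gauss_hermite():
    """One random coefficient, one task: the simulated choice probability at
    10k Halton draws matches 50-node Gauss-Hermite quadrature of the
    logit-normal integral to 1e-3."""
    schema = AttributeSchema([Attribute("x", coding="continuous", levels=(0.0, 1.0))])
    df = pd.DataFrame(
        [
            {"respondent_id": 1, "group": "gp", "arm": "full", "block": 1, "task_id": 1,
             "alternative": 1, "chosen": 1, "x": 1.0},
            {"respondent_id": 1, "group": "gp", "arm": "full", "block": 1, "task_id": 1,
             "alternative": 2, "chosen": 0, "x": 0.0},
        ]
    )
    spec = UtilitySpec.single_group(schema)
    spec.random_terms = ("x_per1",)
    bundle = encode(df, spec)
    b, s = 0.7, 1.3
    draws = halton_normal(1, 10_000, 1, seed=9)
    ll = mixed_panel_loglik(np.array([b, s]), bundle, draws)
    nodes, weights = np.polynomial.hermite.hermgauss(50)
    p_quad = float(
        np.sum(weights / np.sqrt(np.pi) / (1 + np.exp(-(b + s * np.sqrt(2) * nodes))))
    )
    assert math.exp(ll) == pytest.approx(p_quad, abs=1e-3)


def test_closed_form_mle_on_balanced_binary_design():
    """Single dummy regressor whose task difference is always +1: the MLE is
    the log odds of choosing the richer alternative, ln(n+/n-)."""
    schema = AttributeSchema([Attribute("flag", levels=("no", "yes"), reference_level="no")])
    rows = []
    n_plus, n_minus = 30, 10
    for i in range(n_plus + n_minus):
        chosen_first = i < n_plus
        rows += [
            {"respondent_id": i, "group": "gp", "arm": "full", "block": 1, "task_id": 1,
             "alternative": 1, "chosen": int(chosen_first), "flag": "yes"},
            {"respondent_id": i, "group": "gp", "arm": "full", "block": 1, "task_id": 1,
             "alternative": 2, "chosen": int(not chosen_first), "flag": "no"},
        ]
    spec = UtilitySpec.single_group(schema)
    res = estimate(pd.DataFrame(rows), spec)
    assert res.params["flag_yes"] == pytest.approx(math.log(n_plus / n_minus), abs=1e-5)
    assert res.llf >= res.ll_zero


# ---------------------------------------------------------------------------
# estimation behaviour
# ---------------------------------------------------------------------------


def test_mnl_recovery_without_mixing(small_design):
    """Pooled MNL on sigma-free data recovers coefficients and the arm scale
    within 3 reported standard errors (the GP-vs-public scale requires the
    shared mixing spread and is excluded here by fixing no interactions)."""
    truth = TrueParameters.recovery_fixture()
    truth = TrueParameters(
        beta=truth.beta, delta={k: 0.0 for k in truth.beta}, sigma={},
        lambda_public=0.5, lambda_npv_arm=1.3,
        covariate_interactions={}, tau={}, gamma={},
    )
    resp = generate_respondents(400, 1600, truth=truth, seed=33)
    ds = simulate_choices(small_design, resp, truth, seed=34)
    spec = UtilitySpec.pooled_default(ds.schema, sample_interactions=())
    res = MixedLogit(ds, spec).fit(seed=35)
    for name, value in truth.beta.items():
        assert abs(res.params[name] - value) <= 3 * res.bse[name], name
    assert abs(res.params["ln_scale_public"] - math.log(0.5)) <= 3 * res.bse["ln_scale_public"]
    assert abs(res.params["ln_scale_npv_arm"] - math.log(1.3)) <= 3 * res.bse["ln_scale_npv_arm"]


def test_pooled_interaction_model_matches_separate_group_fits(small_design):
    """With a shared design, the pooled fit with sample-dummy interactions is
    a reparameterisation of per-group fits: GP coefficients agree, and the
    public coefficients agree after undoing the estimated public scale."""
    truth = TrueParameters.recovery_fixture()
    truth = TrueParameters(
        beta=truth.beta, delta=truth.delta, sigma={}, lambda_public=1.0,
        lambda_npv_arm=1.0, covariate_interactions={}, tau={}, gamma={},
    )
    resp = generate_respondents(600, 0, truth=truth, seed=36)
    pub = generate_respondents(0, 600, truth=truth, seed=37)
    pub["arm"] = "full"  # same full design for both groups
    pub["respondent_id"] += 10_000
    ds = simulate_choices(small_design, pd.concat([resp, pub], ignore_index=True), truth, seed=38)
    pooled_spec = UtilitySpec.pooled_default(ds.schema)
    # equal layouts and full sample interactions: the relative scale is not
    # separately identified, so both cells share the normalised scale
    pooled_spec.scale_cells = {("gp", "full"): (), ("public", "full"): ()}
    pooled = MixedLogit(ds, pooled_spec).fit(seed=39)

    gp_only = MixedLogit(ds.df[ds.df.group == "gp"], UtilitySpec.single_group(ds.schema)).fit(seed=40)
    pub_only = MixedLogit(ds.df[ds.df.group == "public"], UtilitySpec.single_group(ds.schema)).fit(seed=41)
    for col in pooled_spec.main_columns():
        se = math.hypot(pooled.bse[col], gp_only.bse[col])
        assert abs(pooled.params[col] - gp_only.params[col]) <= 3 * se, col
        joint = pooled.params[col] + pooled.params[f"pub_x_{col}"]
        se_pub = math.hypot(pooled.bse[f"pub_x_{col}"], pub_only.bse[col])
        assert abs(joint - pub_only.params[col]) <= 3 * se_pub, col


def test_refinement_with_zero_threshold_keeps_full_model(small_pooled_data):
    _, _, ds = small_pooled_data
    spec = UtilitySpec.pooled_default(ds.schema, sample_interactions=("early_yes", "site_yes"))
    res = refine_interactions(ds, spec, alpha_t=0.0)
    assert res.removal_trail == []
    assert {"pub_x_early_yes", "pub_x_site_yes"} <= set(res.params.index)


def test_refinement_drops_null_interaction_keeps_strong_one(small_design):
    """A planted strong covariate interaction survives refinement; a null one
    is removed."""
    truth = TrueParameters(
        beta=TrueParameters().public_beta(), delta={}, sigma={}, lambda_public=1.0,
        lambda_npv_arm=1.0,
        covariate_interactions={"female": {"site_yes": 1.2}}, tau={}, gamma={},
    )
    resp = generate_respondents(0, 500, truth=truth, seed=44)
    ds = simulate_choices(small_design, resp, truth, seed=45)
    spec = UtilitySpec.public_split(ds.schema)
    spec.interactions = (
        Interaction("female", "site_yes"),
        Interaction("age65", "early_yes"),  # true coefficient zero
    )
    res = refine_interactions(ds, spec, alpha_t=1.96, seed=46)
    assert "female_x_site_yes" in res.params.index
    assert abs(res.tvalues["female_x_site_yes"]) > 1.96


def test_summary_renders(small_pooled_data):
    _, _, ds = small_pooled_data
    spec = UtilitySpec.pooled_default(ds.schema, sample_interactions=("early_yes", "site_yes"))
    res = estimate(ds, spec, seed=1)
    text = res.summary()
    assert "log-likelihood" in text and "ln_scale_public" in text
    assert res.llf >= res.ll_zero
    eig = np.linalg.eigvalsh(res.cov.to_numpy())
    assert eig.min() > -1e-6 * max(eig.max(), 1.0)


def test_result_json_round_trip(small_pooled_data, tmp_path):
    _, _, ds = small_pooled_data
    res = estimate(ds, UtilitySpec.pooled_default(ds.schema), seed=1)
    res.to_json(tmp_path / "res.json")
    from mctpref.estimation import EstimationResult

    loaded = EstimationResult.from_json(tmp_path / "res.json")
    pd.testing.assert_series_equal(loaded.params, res.params)
    assert loaded.llf == res.llf
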