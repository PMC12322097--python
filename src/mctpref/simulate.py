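"""Synthetic respondents and stated choices from known parameters.

The generator inverts the estimator's data-generating assumptions: each
respondent n draws a coefficient vector

    beta_n = beta_group + covariate shifts + tau * (LV_n - E[LV]) + sigma o xi_n,

computes scaled utilities V = lambda_cell * x'beta_n for the two alternatives
of each of their 12 tasks, adds independent standard Gumbel noise and chooses
the maximum.  The latent cancer knowledge/experience score LV_n = gamma'z_n +
eta_n (eta standard normal) also generates the binary screening/cancer-history
indicators (logit link) and a 0-16 symptom-recognition count (ordered logit).

Heterogeneity terms are centred — covariate shifts enter as
delta*(z - prevalence) and latent shifts as tau*(LV - E[LV]) — so the base
coefficients remain population-average effects regardless of how much
heterogeneity is switched on.

The default fixture coefficients are log odds-ratios transcribed from
published sample-level estimates for GP and public preferences over
multi-cancer tests; they make synthetic runs qualitatively faithful but are
illustrative, not a reconstruction of any study's raw data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import BINARY_INDICATORS, COVARIATES, SYMPTOM_MAX, UtilitySpec
from .schema import AttributeSchema

DEFAULT_PREVALENCES = {
    "age65": 0.25,
    "female": 0.51,
    "ethnic_minority": 0.20,
    "degree": 0.43,
    "rural": 0.23,
    "suburban": 0.46,
}

_GP_BETA = {
    "ppv_20": -4.6818,  # linear in PPV%: slope 0.078030 per point
    "ppv_40": -3.1212,
    "ppv_60": -1.5606,  # ln 0.21
    "npv_96.0": -2.5282,  # implies a GP NPV 99.9->96 trade of 32.4 PPV points
    "npv_99.0": -1.2000,
    "npv_99.5": -0.5798,  # ln 0.56
    "waiting_1-2_weeks": -0.05,
    "cancers_per10": 0.4511,  # ln 1.57
    "site_yes": 0.8372,  # ln 2.31
    "form_faecal": -0.1625,  # ln 0.85
    "form_urine": 0.02,
    "form_breath": -0.02,
    "early_yes": 0.1906,  # ln 1.21
}

_PUBLIC_BETA = {
    "ppv_20": -1.9046,  # linear in PPV%: slope 0.031744 per point
    "ppv_40": -1.2697,
    "ppv_60": -0.6349,  # ln 0.53
    "npv_96.0": -0.4463,  # ln 0.64
    "npv_99.0": -0.08,
    "npv_99.5": -0.02,
    "waiting_1-2_weeks": -0.02,
    "cancers_per10": 0.3075,  # ln 1.36
    "site_yes": 0.2624,  # ln 1.30
    "form_faecal": -0.1625,  # ln 0.85
    "form_urine": 0.01,
    "form_breath": -0.01,
    "early_yes": 0.9594,  # ln 2.61
}

_RANDOM_TERMS = ("ppv_20", "ppv_40", "ppv_60", "npv_96.0", "npv_99.0", "npv_99.5")


@dataclass
class Measurement:
    """Measurement model of one latent trait: binary indicators with logit
    links (intercept alpha, loading zeta) and an ordered-logit symptom count
    with strictly increasing cut points."""

    alpha: dict = field(
        default_factory=lambda: {"screened": -0.6, "had_cancer": -2.3, "tested": -0.7}
    )
    zeta: dict = field(
        default_factory=lambda: {"screened": 0.8, "had_cancer": 0.6, "tested": 0.7}
    )
    symptom_cutpoints: tuple = field(
        default_factory=lambda: tuple(0.45 * (c - 8.5) for c in range(1, SYMPTOM_MAX + 1))
    )
    symptom_zeta: float = 1.0


@dataclass
class TrueParameters:
    """Everything the generating process (and the estimators) parameterise.

    beta: GP (reference-sample) utility coefficients per encoded column.
    delta: additive public-sample shifts (public coefficient = beta + delta).
    sigma: nonnegative spreads of respondent-level normal random coefficients.
    lambda_public / lambda_npv_arm: positive scale multipliers (GP full
        design is the reference cell; the public NPV arm carries the product).
    covariate_interactions: covariate -> {column: shift} (centred at the
        covariate prevalence).
    gamma: structural coefficients of the latent trait on covariates;
        the structural disturbance is standard normal (variance fixed at 1).
    tau: latent-trait x attribute utility shifts (centred at E[LV]).
    measurement: indicator intercepts/loadings and symptom cut points.
    """

    beta: dict = field(default_factory=lambda: dict(_GP_BETA))
    delta: dict = field(
        default_factory=lambda: {k: _PUBLIC_BETA[k] - _GP_BETA[k] for k in _GP_BETA}
    )
    sigma: dict = field(default_factory=lambda: {k: 0.5 for k in _RANDOM_TERMS})
    lambda_public: float = 0.9
    lambda_npv_arm: float = 1.2
    covariate_interactions: dict = field(
        default_factory=lambda: {
            "age65": {"ppv_60": 0.3812},
            "ethnic_minority": {"ppv_60": -0.3124, "cancers_per10": -0.1766},
            "rural": {"form_faecal": -0.1320},
        }
    )
    gamma: dict = field(
        default_factory=lambda: {
            "age65": 0.4,
            "female": 0.3,
            "ethnic_minority": -0.4,
            "degree": 0.3,
            "rural": 0.0,
            "suburban": 0.0,
        }
    )
    tau: dict = field(
        default_factory=lambda: {"ppv_60": -1.1490, "site_yes": 0.3341, "early_yes": 0.7514}
    )
    measurement: Measurement = field(default_factory=Measurement)
    covariate_prevalences: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))

    def __post_init__(self) -> None:
        if self.lambda_public <= 0 or self.lambda_npv_arm <= 0:
            raise ValueError("scale multipliers must be positive")
        if any(s < 0 for s in self.sigma.values()):
            raise ValueError("sigma spreads must be nonnegative")

    # -- derived ------------------------------------------------------------
    def public_beta(self) -> dict:
        return {k: self.beta[k] + self.delta.get(k, 0.0) for k in self.beta}

    def mean_latent(self) -> float:
        return sum(self.gamma.get(c, 0.0) * self.covariate_prevalences.get(c, 0.0) for c in COVARIATES)

    def scale(self, group: str, arm: str) -> float:
        if group == "gp":
            return 1.0
        return self.lambda_public * (self.lambda_npv_arm if arm == "npv" else 1.0)

    # -- variants used by recovery experiments ------------------------------
    @classmethod
    def fixture(cls) -> "TrueParameters":
        return cls()

    @classmethod
    def recovery_fixture(cls) -> "TrueParameters":
        """Heterogeneity the pooled mixed-logit does not model switched off."""
        return cls(covariate_interactions={}, tau={}, gamma={k: 0.0 for k in COVARIATES})

    @classmethod
    def iclv_fixture(cls) -> "TrueParameters":
        """Public-only truth: public coefficients as the base, overall scale
        normalised to 1 (a single-sample fit cannot separate it from beta),
        fixed coefficients, latent effects on."""
        base = cls()
        return cls(
            beta=base.public_beta(),
            delta={k: 0.0 for k in base.beta},
            sigma={},
            lambda_public=1.0,
            lambda_npv_arm=base.lambda_npv_arm,
            covariate_interactions={},
        )

    # -- IO -----------------------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "beta": self.beta,
            "delta": self.delta,
            "sigma": self.sigma,
            "lambda_public": self.lambda_public,
            "lambda_npv_arm": self.lambda_npv_arm,
            "covariate_interactions": self.covariate_interactions,
            "gamma": self.gamma,
            "tau": self.tau,
            "measurement": {
                "alpha": self.measurement.alpha,
                "zeta": self.measurement.zeta,
                "symptom_cutpoints": list(self.measurement.symptom_cutpoints),
                "symptom_zeta": self.measurement.symptom_zeta,
            },
            "covariate_prevalences": self.covariate_prevalences,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TrueParameters":
        with open(path) as fh:
            payload = json.load(fh)
        meas = payload.pop("measurement")
        return cls(
            measurement=Measurement(
                alpha=meas["alpha"],
                zeta=meas["zeta"],
                symptom_cutpoints=tuple(meas["symptom_cutpoints"]),
                symptom_zeta=meas["symptom_zeta"],
            ),
            **payload,
        )


@dataclass
class ChoiceDataset:
    """Long-format panel of binary stated choices with group/arm metadata."""

    df: pd.DataFrame
    schema: AttributeSchema

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, schema: AttributeSchema) -> "ChoiceDataset":
        return cls(pd.read_csv(path), schema)


# ---------------------------------------------------------------------------
# respondents
# ---------------------------------------------------------------------------


def generate_respondents(
    n_gp: int,
    n_public: int,
    truth: TrueParameters | None = None,
    covariate_prevalences: dict | None = None,
    seed: int = 0,
    n_blocks: int = 2,
) -> pd.DataFrame:
    """Draw respondent covariates, arms, blocks, latent scores and indicators.

    GPs are always on the full design; public respondents are randomised
    50/50 to the PPV or NPV arm and 50/50 to one of two task blocks.
    Group-balancing weights w = 0.5 * N_total / N_group are attached.
    """
    if n_gp < 0 or n_public < 0:
        raise ValueError("respondent counts must be nonnegative")
    truth = truth or TrueParameters.fixture()
    prev = covariate_prevalences or truth.covariate_prevalences
    if any(not (0.0 <= p <= 1.0) for p in prev.values()):
        raise ValueError("prevalences must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    n = n_gp + n_public

    rows = pd.DataFrame({"respondent_id": np.arange(1, n + 1)})
    rows["group"] = ["gp"] * n_gp + ["public"] * n_public
    arm = np.where(rng.random(n) < 0.5, "ppv", "npv").astype(object)
    arm[:n_gp] = "full"
    rows["arm"] = arm
    rows["block"] = rng.integers(1, n_blocks + 1, size=n)

    for cov in COVARIATES:
        p = prev.get(cov, 0.0)
        rows[cov] = (rng.random(n) < p).astype(int)
    # rural/suburban/urban are exclusive; re-draw jointly
    p_r, p_s = prev.get("rural", 0.0), prev.get("suburban", 0.0)
    u = rng.random(n)
    rows["rural"] = (u < p_r).astype(int)
    rows["suburban"] = ((u >= p_r) & (u < p_r + p_s)).astype(int)

    z = rows[list(COVARIATES)].to_numpy(dtype=float)
    gam = np.array([truth.gamma.get(c, 0.0) for c in COVARIATES])
    eta = rng.standard_normal(n)
    latent = z @ gam + eta
    rows["latent_score"] = latent

    meas = truth.measurement
    for ind in BINARY_INDICATORS:
        p = 1.0 / (1.0 + np.exp(-(meas.alpha[ind] + meas.zeta[ind] * latent)))
        rows[ind] = (rng.random(n) < p).astype(int)
    # ordered logit count: P(Y <= c) = logistic(kappa_{c+1} - zeta*LV)
    kappa = np.asarray(meas.symptom_cutpoints)
    if not np.all(np.diff(kappa) > 0):
        raise ValueError("symptom cut points must be strictly increasing")
    cdf = 1.0 / (1.0 + np.exp(-(kappa[None, :] - meas.symptom_zeta * latent[:, None])))
    u = rng.random(n)[:, None]
    rows["symptom_count"] = (u > cdf).sum(axis=1)

    if n_gp and n_public:
        w_gp, w_pub = 0.5 * n / n_gp, 0.5 * n / n_public
    else:
        w_gp = w_pub = 1.0
    rows["weight"] = np.where(rows["group"] == "gp", w_gp, w_pub)
    return rows


# ---------------------------------------------------------------------------
# choices
# ---------------------------------------------------------------------------


def simulate_choices(design, respondents: pd.DataFrame, truth: TrueParameters, seed: int = 0):
    """Simulate every respondent's stated choices on their arm view/block.

    Returns a :class:`ChoiceDataset` in long format: two rows per task, the
    chosen alternative flagged, hidden split-arm attributes left missing.
    """
    schema = design.schema
    spec = UtilitySpec(schema)
    columns = spec.main_columns()
    ss = np.random.SeedSequence(seed).spawn(2)
    rng_coef = np.random.default_rng(ss[0])
    rng_noise = np.random.default_rng(ss[1])

    beta_gp = np.array([truth.beta.get(c, 0.0) for c in columns])
    delta = np.array([truth.delta.get(c, 0.0) for c in columns])
    sigma = np.array([truth.sigma.get(c, 0.0) for c in columns])
    tau = np.array([truth.tau.get(c, 0.0) for c in columns])
    mean_lv = truth.mean_latent()
    prev = truth.covariate_prevalences

    # pre-encode each arm view once
    views: dict[str, dict] = {}
    for arm in ("full", "ppv", "npv"):
        view = design.arm_view(arm)
        frames = {}
        for block in range(1, design.n_blocks + 1):
            tasks = view.tasks_in_block(block)
            if not tasks:
                continue
            X = np.array(
                [spec.encode_profile(p) for t in tasks for p in t.profiles]
            )
            frames[block] = (tasks, X)
        views[arm] = frames

    records = []
    for row in respondents.itertuples(index=False):
        if row.arm not in views or row.block not in views[row.arm]:
            raise ValueError(f"respondent {row.respondent_id}: arm/block missing from design")
        tasks, X = views[row.arm][row.block]
        beta_n = beta_gp.copy()
        if row.group == "public":
            beta_n = beta_n + delta
            for cov, shifts in truth.covariate_interactions.items():
                zc = getattr(row, cov) - prev.get(cov, 0.0)
                for col, val in shifts.items():
                    beta_n[columns.index(col)] += val * zc
            beta_n = beta_n + tau * (row.latent_score - mean_lv)
        beta_n = beta_n + sigma * rng_coef.standard_normal(len(columns))
        lam = truth.scale(row.group, row.arm)
        V = lam * (X @ beta_n)
        eps = rng_noise.gumbel(size=V.shape)
        U = (V + eps).reshape(-1, 2)
        chosen_alt = np.argmax(U, axis=1)
        for ti, task in enumerate(tasks):
            for alt, profile in enumerate(task.profiles):
                rec = {
                    "respondent_id": row.respondent_id,
                    "group": row.group,
                    "arm": row.arm,
                    "block": row.block,
                    "task_id": task.task_id,
                    "alternative": alt + 1,
                    "chosen": int(alt == chosen_alt[ti]),
                }
                for a in schema:
                    rec[a.name] = profile.assignment.get(a.name, np.nan)
                for cov in COVARIATES:
                    rec[cov] = getattr(row, cov)
                for ind in BINARY_INDICATORS:
                    rec[ind] = getattr(row, ind, np.nan)
                rec["symptom_count"] = getattr(row, "symptom_count", np.nan)
                rec["weight"] = row.weight
                rec["latent_score"] = row.latent_score
                records.append(rec)
    df = pd.DataFrame.from_records(records)
    return ChoiceDataset(df, design.schema)


def simulate_study(
    n_gp: int = 251,
    n_public: int = 1005,
    design=None,
    truth: TrueParameters | None = None,
    seed: int = 0,
):
    """Convenience wrapper: respondents + choices at study-scale defaults
    (251 GPs on the full design, 1005 public split across PPV/NPV arms)."""
    truth = truth or TrueParameters.fixture()
    if design is None:
        raise ValueError("a design is required; see mctpref.design.generate_design")
    ss = np.random.SeedSequence(seed).spawn(2)
    respondents = generate_respondents(n_gp, n_public, truth=truth, seed=ss[0].generate_state(1)[0] % (2**31))
    dataset = simulate_choices(design, respondents, truth, seed=ss[1].generate_state(1)[0] % (2**31))
    return respondents, dataset
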