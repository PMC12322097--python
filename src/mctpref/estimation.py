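"""Multinomial and mixed (random-coefficient) logit by simulated maximum
likelihood, statsmodels-style.

The model.  Respondent n faces T binary tasks; alternative j of task t gives
scaled utility

    U = lambda_n * x'beta_n + epsilon,   epsilon iid standard Gumbel,

with lambda_n the product of that respondent's scale-cell parameters
(reference cell fixed at 1; scales estimated on the log scale) and

    beta_n = beta + sigma o xi_n,   xi_n ~ N(0, I)  (panel: one draw per
    respondent, common across their tasks; only ``random_terms`` mix).

The panel simulated log likelihood is

    LL = sum_n w_n ln[ (1/R) sum_r prod_t P_nt(beta + sigma o xi_nr) ],

maximised by quasi-Newton ascent with the analytic gradient; with all sigma
fixed at zero it reduces exactly to the multinomial logit.  Weights
w_n = 0.5 N_total / N_group make unequal samples contribute equally
(WESML), so the reported covariance is the respondent-clustered sandwich.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from ._draws import halton_normal
from .encoding import DesignMatrixBundle, UtilitySpec, encode


class EstimationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# likelihood engine
# ---------------------------------------------------------------------------


def _split_params(params: np.ndarray, bundle: DesignMatrixBundle, with_sigma: bool):
    K = len(bundle.columns)
    M = len(bundle.random_idx) if with_sigma else 0
    P = len(bundle.scale_names)
    if len(params) != K + M + P:
        raise EstimationError(f"expected {K + M + P} parameters, got {len(params)}")
    theta = np.asarray(params[:K], dtype=float)
    sigma = np.asarray(params[K : K + M], dtype=float)
    s = np.asarray(params[K + M :], dtype=float)
    return theta, sigma, s


def _panel_loglik(
    params: np.ndarray,
    bundle: DesignMatrixBundle,
    draws: np.ndarray | None,
    want_grad: bool = True,
    per_respondent: bool = False,
    chunk: int = 64,
):
    """Simulated panel log likelihood, analytic gradient, per-respondent scores.

    ``draws``: (n_resp_total, R, K_rand) standard normals in bundle
    respondent order, or None for the plain MNL.
    """
    with_sigma = draws is not None and draws.shape[2] > 0
    theta, sigma, s = _split_params(params, bundle, with_sigma)
    K = len(bundle.columns)
    M = len(sigma)
    P = len(bundle.scale_names)
    rand = np.asarray(bundle.random_idx, dtype=int)

    ll = 0.0
    grads = []
    total_grad = np.zeros(K + M + P)
    offset = 0
    R = 1 if draws is None else draws.shape[1]

    for batch in bundle.batches:
        D, c, S, w = batch.D, batch.c, batch.S, batch.w
        n, T, _ = D.shape
        lam = np.exp(S @ s) if P else np.ones(n)
        dv_fix = np.einsum("ntk,k->nt", D, theta)
        xi = None if draws is None else draws[offset : offset + n]
        offset += n

        S_n = np.zeros(n)
        Gb = np.zeros((n, K))
        Gs = np.zeros((n, M))
        Gl = np.zeros((n, P))
        Drand = D[:, :, rand] if M else None

        for r0 in range(0, R, chunk):
            r1 = min(r0 + chunk, R)
            if with_sigma:
                xi_c = sigma * xi[:, r0:r1, :]  # (n, Rc, M)
                dvr = dv_fix[:, :, None] + Drand @ xi_c.transpose(0, 2, 1)
            else:
                dvr = dv_fix[:, :, None]
            a = c[:, :, None] * lam[:, None, None] * dvr
            lnP = -np.logaddexp(0.0, -a).sum(axis=1)  # (n, Rc)
            Pnr = np.exp(lnP)
            S_n += Pnr.sum(axis=1)
            if want_grad:
                # ew_ntr = P_nr * d lnP_nt / d(lam * dv): draw-weighted scores
                ew = (c[:, :, None] * expit(-a)) * Pnr[:, None, :]
                Gb += lam[:, None] * np.einsum("nt,ntk->nk", ew.sum(axis=2), D)
                if M:
                    C = ew @ xi[:, r0:r1, :]  # (n, T, M)
                    Gs += lam[:, None] * np.einsum("ntm,ntm->nm", C, Drand)
                if P:
                    h = np.einsum("ntr,ntr->n", ew, dvr)  # d lnP / d ln(lam)
                    Gl += (lam * h)[:, None] * S

        ll += float(w @ (np.log(S_n) - np.log(R)))
        if want_grad:
            score = np.concatenate([Gb, Gs, Gl], axis=1) / S_n[:, None]
            total_grad += (w[:, None] * score).sum(axis=0)
            if per_respondent:
                grads.append(w[:, None] * score)

    if not np.isfinite(ll):
        raise EstimationError("log likelihood is not finite")
    if per_respondent:
        return ll, total_grad, np.vstack(grads)
    if want_grad:
        return ll, total_grad
    return ll


def mnl_loglik(params, bundle: DesignMatrixBundle, grad: bool = False):
    """Multinomial-logit log likelihood (no mixing).  ``params`` stacks the
    utility columns then the log-scale parameters."""
    out = _panel_loglik(np.asarray(params, float), bundle, None, want_grad=grad)
    return out if grad else out


def mixed_panel_loglik(params, bundle: DesignMatrixBundle, draws: np.ndarray, grad: bool = False):
    """Panel mixed-logit simulated log likelihood.  ``params`` stacks utility
    columns, random-coefficient spreads, then log-scale parameters; ``draws``
    is (n_respondents, R, K_random).  Reduces exactly to :func:`mnl_loglik`
    when every spread is zero."""
    if draws.ndim != 3:
        raise EstimationError("draws must be (n_respondents, R, K_random)")
    if draws.shape[1] < 1:
        raise EstimationError("need at least one draw")
    out = _panel_loglik(np.asarray(params, float), bundle, draws, want_grad=grad)
    return out if grad else out


def null_loglik(bundle: DesignMatrixBundle) -> float:
    """Weighted log likelihood of uniform choice (all parameters zero)."""
    return float(
        sum(-(b.w * b.D.shape[1]).sum() * np.log(2.0) for b in bundle.batches)
    )


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------


@dataclass
class EstimationResult:
    """Point estimates, clustered sandwich covariance and diagnostics."""

    params: pd.Series
    cov: pd.DataFrame
    llf: float
    ll_zero: float
    n_respondents: int
    n_obs: int
    n_draws: int
    draw_type: str
    converged: bool
    grad_norm: float
    seed: int
    spec: UtilitySpec = None
    model: "MixedLogit" = None
    removal_trail: list = field(default_factory=list)

    def __post_init__(self) -> None:
        c = self.cov.to_numpy()
        if not np.allclose(c, c.T, atol=1e-8):
            raise EstimationError("covariance must be symmetric")

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Mixed multinomial logit (simulated maximum likelihood)",
            f"respondents: {self.n_respondents}   choice tasks: {self.n_obs}   "
            f"draws: {self.n_draws} ({self.draw_type})",
            f"log-likelihood: {self.llf:.3f}   LL(0): {self.ll_zero:.3f}   "
            f"converged: {self.converged} (|grad| {self.grad_norm:.2e})",
            "-" * 78,
            f"{'parameter':<26}{'estimate':>10}{'std err':>10}{'t':>8}{'[0.025':>11}{'0.975]':>11}",
            "-" * 78,
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<26}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{self.tvalues[name]:>8.2f}{ci.loc[name, 'lower']:>11.4f}{ci.loc[name, 'upper']:>11.4f}"
            )
        lines.append("-" * 78)
        return "\n".join(lines)

    # -- post-estimation conveniences (see mctpref.postestimation) ----------
    def odds_ratios(self, n_draws: int = 10_000, seed: int = 0, parameters=None):
        from .postestimation import odds_ratios

        return odds_ratios(self, n_draws=n_draws, seed=seed, parameters=parameters)

    def ppv_slope(self, group: str = "gp"):
        from .postestimation import ppv_slope

        return ppv_slope(self, group=group)

    def mrs_npv_ppv(self, npv_from: float, npv_to: float, group: str = "gp"):
        from .postestimation import mrs_npv_ppv

        return mrs_npv_ppv(self, npv_from, npv_to, group=group)

    def group_coefficient(self, column: str, group: str = "gp") -> float:
        """beta (GP) or beta + sample-interaction shift (public)."""
        value = float(self.params.get(column, 0.0))
        if group == "public":
            value += float(self.params.get(f"pub_x_{column}", 0.0))
        return value

    def group_scale(self, group: str) -> float:
        if group == "public" and "ln_scale_public" in self.params.index:
            return float(np.exp(self.params["ln_scale_public"]))
        return 1.0

    # -- IO -----------------------------------------------------------------
    def to_json(self, path) -> None:
        import json

        payload = {
            "params": self.params.to_dict(),
            "cov": self.cov.to_numpy().tolist(),
            "names": list(self.params.index),
            "llf": self.llf,
            "ll_zero": self.ll_zero,
            "n_respondents": self.n_respondents,
            "n_obs": self.n_obs,
            "n_draws": self.n_draws,
            "draw_type": self.draw_type,
            "converged": self.converged,
            "grad_norm": self.grad_norm,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "EstimationResult":
        import json

        with open(path) as fh:
            payload = json.load(fh)
        names = payload.pop("names")
        params = pd.Series(payload.pop("params")).reindex(names)
        cov = pd.DataFrame(np.array(payload.pop("cov")), index=names, columns=names)
        return cls(params=params, cov=cov, **payload)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class MixedLogit:
    """Mixed multinomial logit model bound to a choice dataset.

    Parameters
    ----------
    dataset : ChoiceDataset or DataFrame
        Long-format stated choices (two rows per task).
    spec : UtilitySpec
        Encoding, mixing, interaction, scale and weighting structure.
    """

    def __init__(self, dataset, spec: UtilitySpec):
        self.spec = spec
        self.bundle = encode(dataset, spec)

    @classmethod
    def from_dataframe(cls, df, spec: UtilitySpec) -> "MixedLogit":
        return cls(df, spec)

    @property
    def param_names(self) -> list[str]:
        return (
            list(self.bundle.columns)
            + [f"sd_{t}" for t in self.spec.random_terms]
            + list(self.bundle.scale_names)
        )

    def _draws(self, n_draws: int, seed: int) -> np.ndarray | None:
        M = len(self.bundle.random_idx)
        if M == 0:
            return None
        return halton_normal(self.bundle.n_respondents, n_draws, M, seed=seed)

    def loglik(self, params, n_draws: int = 500, seed: int = 0) -> float:
        draws = self._draws(n_draws, seed)
        return _panel_loglik(np.asarray(params, float), self.bundle, draws, want_grad=False)

    def fit(
        self,
        n_draws: int = 500,
        seed: int = 0,
        start: np.ndarray | None = None,
        maxiter: int = 1000,
        gtol: float = 1e-5,
        cov_type: str = "sandwich",
        sigma_start: float = 0.1,
    ) -> EstimationResult:
        """Maximise the simulated likelihood; quasi-Newton (L-BFGS) ascent
        from a zero start (a fast MNL stage seeds the mixed stage)."""
        bundle = self.bundle
        K, M, P = len(bundle.columns), len(bundle.random_idx), len(bundle.scale_names)
        names = self.param_names

        # stage 1: MNL on (theta, s)
        x0 = np.zeros(K + P)
        if start is not None and M == 0:
            x0 = np.asarray(start, float)
        res1 = optimize.minimize(
            lambda x: tuple(-v for v in _panel_loglik(x, bundle, None)),
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
        )
        if M == 0:
            xhat, opt = res1.x, res1
            draws = None
        else:
            draws = self._draws(n_draws, seed)
            xs = np.concatenate([res1.x[:K], np.full(M, sigma_start), res1.x[K:]])
            if start is not None:
                xs = np.asarray(start, float)
            opt = optimize.minimize(
                lambda x: tuple(-v for v in _panel_loglik(x, bundle, draws)),
                xs,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
            )
            xhat = opt.x

        ll, grad, scores = _panel_loglik(xhat, bundle, draws, per_respondent=True)
        cov = self._covariance(xhat, draws, scores, cov_type)
        return EstimationResult(
            params=pd.Series(xhat, index=names),
            cov=pd.DataFrame(cov, index=names, columns=names),
            llf=float(ll),
            ll_zero=null_loglik(bundle),
            n_respondents=bundle.n_respondents,
            n_obs=bundle.n_obs,
            n_draws=1 if draws is None else n_draws,
            draw_type="halton" if draws is not None else "none",
            converged=bool(opt.success) or float(np.max(np.abs(grad))) < 1e-3,
            grad_norm=float(np.max(np.abs(grad))),
            seed=seed,
            spec=self.spec,
            model=self,
        )

    def _covariance(self, xhat, draws, scores, cov_type: str, step: float = 1e-5) -> np.ndarray:
        """Respondent-clustered sandwich A^-1 B A^-1 with A from central
        finite differences of the analytic gradient."""
        Kp = len(xhat)
        B = scores.T @ scores
        H = np.zeros((Kp, Kp))
        for j in range(Kp):
            h = step * max(1.0, abs(xhat[j]))
            xp, xm = xhat.copy(), xhat.copy()
            xp[j] += h
            xm[j] -= h
            _, gp = _panel_loglik(xp, self.bundle, draws)
            _, gm = _panel_loglik(xm, self.bundle, draws)
            H[:, j] = (gp - gm) / (2 * h)
        H = 0.5 * (H + H.T)
        A = -H
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            Ainv = np.linalg.pinv(A)
        if cov_type == "hessian":
            return 0.5 * (Ainv + Ainv.T)
        V = Ainv @ B @ Ainv
        return 0.5 * (V + V.T)


def estimate(dataset, spec: UtilitySpec, **fit_kwargs) -> EstimationResult:
    """One-shot convenience: build :class:`MixedLogit` and fit."""
    return MixedLogit(dataset, spec).fit(**fit_kwargs)


# ---------------------------------------------------------------------------
# interaction refinement
# ---------------------------------------------------------------------------


def refine_interactions(
    dataset,
    spec: UtilitySpec,
    alpha_t: float = 1.96,
    **fit_kwargs,
) -> EstimationResult:
    """Fit the full model, then iteratively drop the single least significant
    interaction with |t| below ``alpha_t`` and refit until every remaining
    interaction passes.  Main effects are never removed.  The removal order
    is recorded on the result's ``removal_trail``."""
    current = spec
    trail: list[tuple[str, float]] = []
    while True:
        result = estimate(dataset, current, **fit_kwargs)
        inter_cols = [ia.column for ia in current.interactions if ia.modifier != "latent"]
        if not inter_cols:
            break
        tvals = result.tvalues[inter_cols].abs()
        worst = tvals.idxmin()
        if tvals[worst] >= alpha_t:
            break
        trail.append((worst, float(tvals[worst])))
        keep = tuple(
            ia for ia in current.interactions if ia.modifier == "latent" or ia.column != worst
        )
        current = replace(current, interactions=keep)
    result.removal_trail = trail
    return result
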