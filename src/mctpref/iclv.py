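"""Integrated Choice and Latent Variable (hybrid choice) model.

A single latent trait — cancer knowledge and experience — ties three
equation blocks together, estimated jointly by simulated maximum likelihood:

structural      LV_n = gamma' z_n + eta_n,          eta ~ N(0, 1)
measurement     binary indicators: logit(p_k) = alpha_k + zeta_k LV_n
                symptom count (0-16): ordered logit with 16 increasing cut
                points and loading zeta_sym
choice          utilities as in the mixed logit, with the latent trait
                shifting selected attribute coefficients: beta_j + tau_j LV_n

The structural disturbance variance is fixed at 1 and one loading (the
screening indicator's) is constrained positive by a post-convergence sign
reflection — the likelihood is invariant to flipping (gamma, zeta, tau)
jointly.  The simulated likelihood integrates the latent disturbance (and
any random coefficients) with scrambled Halton draws, the latent dimension
occupying the last draw column:

    LL = sum_n w_n ln[ (1/R) sum_r  prod_t P_nt(beta + tau LV_nr)
                                  * prod_k m_k(I_nk | LV_nr) ],

which separates exactly into mixed-logit + closed-form measurement terms
when every tau and zeta is zero.

The module also houses the one-factor principal-axis factor analysis used to
motivate collapsing the knowledge/experience indicators into one trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

from ._draws import halton_normal
from .encoding import BINARY_INDICATORS, COVARIATES, SYMPTOM_MAX, UtilitySpec, encode
from .estimation import EstimationError, EstimationResult, null_loglik, _panel_loglik


# ---------------------------------------------------------------------------
# exploratory factor analysis
# ---------------------------------------------------------------------------


@dataclass
class FactorResult:
    loadings: pd.Series
    eigenvalues: np.ndarray
    variance_share: float


def factor_loadings(indicators: pd.DataFrame, max_iter: int = 1, tol: float = 1e-6) -> FactorResult:
    """One-factor principal-factor solution on the indicator correlation
    matrix: a single eigen-decomposition of the reduced correlation matrix
    with squared-multiple-correlation communalities (set ``max_iter > 1`` to
    iterate the communalities, principal-axis style; on data with no common
    factor the iteration is known to inflate a single spurious communality,
    which is why the classical single pass is the default).

    Returns first-factor loadings, the eigenvalues of the reduced matrix,
    and the first factor's share of total indicator variance.
    """
    X = indicators.astype(float)
    if X.shape[1] < 2 or X.shape[0] < 10:
        raise ValueError("need at least 2 indicator columns and 10 rows")
    stds = X.std(ddof=1)
    if (stds == 0).any():
        bad = stds.index[stds == 0][0]
        raise ValueError(f"degenerate indicator {bad!r}: constant column")
    R = np.corrcoef(X.to_numpy(), rowvar=False)
    p = R.shape[0]
    # squared multiple correlations as starting communalities
    try:
        h2 = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        h2 = np.full(p, 1.0 - 1e-6)
    h2 = np.clip(h2, 1e-6, 1.0 - 1e-6)
    for _ in range(max_iter):
        Rh = R.copy()
        np.fill_diagonal(Rh, h2)
        vals, vecs = np.linalg.eigh(Rh)
        lam1, v1 = vals[-1], vecs[:, -1]
        load = v1 * np.sqrt(max(lam1, 0.0))
        new_h2 = np.clip(load**2, 1e-8, 1.0 - 1e-6)
        if np.max(np.abs(new_h2 - h2)) < tol:
            h2 = new_h2
            break
        h2 = new_h2
    Rh = R.copy()
    np.fill_diagonal(Rh, h2)
    vals, vecs = np.linalg.eigh(Rh)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    load = vecs[:, order[0]] * np.sqrt(max(vals[0], 0.0))
    if load.sum() < 0:  # orient the factor positively
        load = -load
    share = float(max(vals[0], 0.0) / p)
    return FactorResult(
        loadings=pd.Series(load, index=list(indicators.columns)),
        eigenvalues=vals,
        variance_share=share,
    )


# ---------------------------------------------------------------------------
# specification blocks
# ---------------------------------------------------------------------------


@dataclass
class LatentSpec:
    """Structural equation: latent trait on respondent covariates, standard
    normal disturbance (variance fixed at 1 for identification)."""

    covariates: tuple = COVARIATES


@dataclass
class MeasurementSpec:
    """Which indicators measure the trait and through which links (logit for
    binaries; ordered logit for the symptom count).  ``positive_loading``
    names the indicator whose loading anchors the trait's sign."""

    binary: tuple = BINARY_INDICATORS
    include_symptoms: bool = True
    positive_loading: str = "screened"


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


class _ICLVParams:
    """Index bookkeeping for the stacked ICLV parameter vector:
    [theta | sigma | ln-scale | tau | gamma | (alpha_k, zeta_k)_k |
     kappa_1, ln-increments_2..16, zeta_sym]."""

    def __init__(self, bundle, tau_terms, latent: LatentSpec, meas: MeasurementSpec):
        self.K = len(bundle.columns)
        self.M = len(bundle.random_idx)
        self.P = len(bundle.scale_names)
        self.tau_terms = list(tau_terms)
        self.tau_idx = [bundle.columns.index(t) for t in self.tau_terms]
        self.covs = list(latent.covariates)
        self.binary = list(meas.binary)
        self.symptoms = meas.include_symptoms
        self.names = (
            list(bundle.columns)
            + [f"sd_{bundle.columns[i]}" for i in bundle.random_idx]
            + list(bundle.scale_names)
            + [f"lv_x_{t}" for t in self.tau_terms]
            + [f"lv_on_{c}" for c in self.covs]
        )
        for k in self.binary:
            self.names += [f"meas_{k}_const", f"meas_{k}_loading"]
        if self.symptoms:
            self.names += ["meas_symptoms_cut1"]
            self.names += [f"meas_symptoms_dln{c}" for c in range(2, SYMPTOM_MAX + 1)]
            self.names += ["meas_symptoms_loading"]
        self.n_params = len(self.names)

    def split(self, x):
        i = 0
        out = {}
        for key, size in [
            ("theta", self.K),
            ("sigma", self.M),
            ("s", self.P),
            ("tau", len(self.tau_terms)),
            ("gamma", len(self.covs)),
        ]:
            out[key] = x[i : i + size]
            i += size
        out["alpha"] = {}
        out["zeta"] = {}
        for k in self.binary:
            out["alpha"][k] = x[i]
            out["zeta"][k] = x[i + 1]
            i += 2
        if self.symptoms:
            out["kappa1"] = x[i]
            out["dln"] = x[i + 1 : i + SYMPTOM_MAX]
            out["zsym"] = x[i + SYMPTOM_MAX]
            i += SYMPTOM_MAX + 1
        return out

    def kappa(self, parts) -> np.ndarray:
        return parts["kappa1"] + np.concatenate([[0.0], np.cumsum(np.exp(parts["dln"]))])


def _iclv_loglik(
    x: np.ndarray,
    bundle,
    layout: _ICLVParams,
    draws: np.ndarray,
    want_grad: bool = True,
    per_respondent: bool = False,
    latent_posterior: bool = False,
    chunk: int = 64,
):
    """Joint simulated log likelihood of choices and indicators.

    ``draws`` is (n_resp, R, M+1): random-coefficient dimensions first, the
    latent disturbance last.
    """
    parts = layout.split(np.asarray(x, dtype=float))
    theta, sigma, s = parts["theta"], parts["sigma"], parts["s"]
    tau, gamma = parts["tau"], parts["gamma"]
    K, M, P = layout.K, layout.M, layout.P
    rand = np.asarray(bundle.random_idx, dtype=int)
    tau_vec = np.zeros(K)
    tau_vec[layout.tau_idx] = tau
    cov_sel = [COVARIATES.index(c) for c in layout.covs]
    R = draws.shape[1]

    if layout.symptoms:
        kap = layout.kappa(parts)
        kap_ext = np.concatenate([[-np.inf], kap, [np.inf]])

    ll = 0.0
    total_grad = np.zeros(layout.n_params)
    resp_scores = []
    post_num = []
    post_den = []
    offset = 0

    for batch in bundle.batches:
        D, c, S, w = batch.D, batch.c, batch.S, batch.w
        n, T, _ = D.shape
        lam = np.exp(S @ s) if P else np.ones(n)
        z = batch.z[:, cov_sel]
        dv_fix = np.einsum("ntk,k->nt", D, theta)
        Dtau = np.einsum("ntk,k->nt", D, tau_vec)
        Drand = D[:, :, rand] if M else None
        xi = draws[offset : offset + n]
        offset += n
        lv_mean = z @ gamma  # (n,)

        yb = {k: batch.yb[:, i] for i, k in enumerate(BINARY_INDICATORS) if k in layout.binary}
        ys = batch.ys
        if layout.symptoms:
            have_ys = np.isfinite(ys)
            ysi = np.where(have_ys, ys, 0).astype(int)
            k_hi = kap_ext[ysi + 1]
            k_lo = kap_ext[ysi]

        S_n = np.zeros(n)
        G = {
            "theta": np.zeros((n, K)),
            "sigma": np.zeros((n, M)),
            "s": np.zeros((n, P)),
            "tau": np.zeros((n, len(tau))),
            "gamma_lv": np.zeros(n),  # d lnL / d LV-location, expanded by z later
            "alpha": {k: np.zeros(n) for k in yb},
            "zeta": {k: np.zeros(n) for k in yb},
        }
        if layout.symptoms:
            G["kap_hi"] = np.zeros(n)
            G["kap_lo"] = np.zeros(n)
            G["zsym"] = np.zeros(n)
        pnum = np.zeros(n)

        for r0 in range(0, R, chunk):
            r1 = min(r0 + chunk, R)
            eta = xi[:, r0:r1, M]
            LV = lv_mean[:, None] + eta  # (n, Rc)
            dvr = dv_fix[:, :, None] + Dtau[:, :, None] * LV[:, None, :]
            if M:
                xi_c = sigma * xi[:, r0:r1, :M]
                dvr = dvr + Drand @ xi_c.transpose(0, 2, 1)
            a = c[:, :, None] * lam[:, None, None] * dvr
            lnJ = -np.logaddexp(0.0, -a).sum(axis=1)  # choice part (n, Rc)

            pk = {}
            for k, y in yb.items():
                miss = ~np.isfinite(y)
                yk = np.where(miss, 0.0, y)[:, None]
                p = expit(parts["alpha"][k] + parts["zeta"][k] * LV)
                lnm = yk * np.log(p) + (1 - yk) * np.log1p(-p)
                lnJ += np.where(miss[:, None], 0.0, lnm)
                pk[k] = (p, yk, miss)
            if layout.symptoms:
                b_hi = k_hi[:, None] - parts["zsym"] * LV
                b_lo = k_lo[:, None] - parts["zsym"] * LV
                F_hi, F_lo = expit(b_hi), expit(b_lo)
                # complementary form avoids cancellation when both CDFs -> 1
                upper = b_lo > 0
                Pord = np.where(upper, expit(-b_lo) - expit(-b_hi), F_hi - F_lo)
                Pord = np.clip(Pord, 1e-300, None)
                lnJ += np.where(have_ys[:, None], np.log(Pord), 0.0)

            J = np.exp(lnJ)
            S_n += J.sum(axis=1)
            if latent_posterior:
                pnum += (J * LV).sum(axis=1)
            if not want_grad:
                continue

            ew = (c[:, :, None] * expit(-a)) * J[:, None, :]
            ewt = ew.sum(axis=2)  # (n, T)
            G["theta"] += lam[:, None] * np.einsum("nt,ntk->nk", ewt, D)
            if M:
                C = ew @ xi[:, r0:r1, :M]
                G["sigma"] += lam[:, None] * np.einsum("ntm,ntm->nm", C, Drand)
            if P:
                h = np.einsum("ntr,ntr->n", ew, dvr)
                G["s"] += (lam * h)[:, None] * S
            # tau: scores against D columns weighted by LV per draw
            W = (ew * LV[:, None, :]).sum(axis=2)  # (n, T)
            G["tau"] += lam[:, None] * np.einsum("nt,ntj->nj", W, D[:, :, layout.tau_idx])
            # latent-location channel (choice): lam * sum_t e * Dtau
            dLV = lam * np.einsum("nt,nt->n", ewt, Dtau)
            for k, (p, yk, miss) in pk.items():
                u = np.where(miss[:, None], 0.0, yk - p)  # (n, Rc)
                G["alpha"][k] += (J * u).sum(axis=1)
                G["zeta"][k] += (J * u * LV).sum(axis=1)
                dLV = dLV + parts["zeta"][k] * (J * u).sum(axis=1)
            if layout.symptoms:
                f_hi = F_hi * (1 - F_hi)
                f_lo = F_lo * (1 - F_lo)
                wgt = np.where(have_ys[:, None], J / Pord, 0.0)
                a_hi = (wgt * f_hi).sum(axis=1)
                a_lo = (wgt * f_lo).sum(axis=1)
                G["kap_hi"] += a_hi
                G["kap_lo"] += a_lo
                G["zsym"] += -(wgt * (f_hi - f_lo) * LV).sum(axis=1)
                dLV = dLV - parts["zsym"] * ((wgt * (f_hi - f_lo)).sum(axis=1))
            G["gamma_lv"] += dLV

        ll += float(w @ (np.log(S_n) - np.log(R)))
        if latent_posterior:
            post_num.append(pnum)
            post_den.append(S_n)
        if want_grad:
            cols = [G["theta"], G["sigma"], G["s"], G["tau"], G["gamma_lv"][:, None] * z]
            for k in yb:
                cols += [G["alpha"][k][:, None], G["zeta"][k][:, None]]
            if layout.symptoms:
                gk1 = (G["kap_hi"] - G["kap_lo"])[:, None]
                # chain rule through kappa_c = kappa_1 + cumsum(exp(dln))
                incr = np.exp(parts["dln"])  # (15,)
                js = np.arange(2, SYMPTOM_MAX + 1)
                hi_mask = (ysi[:, None] + 1) >= js
                lo_mask = ysi[:, None] >= js
                gd = incr * (G["kap_hi"][:, None] * hi_mask - G["kap_lo"][:, None] * lo_mask)
                cols += [gk1, gd, G["zsym"][:, None]]
            score = np.concatenate(cols, axis=1) / S_n[:, None]
            total_grad += (w[:, None] * score).sum(axis=0)
            if per_respondent:
                resp_scores.append(w[:, None] * score)

    if not np.isfinite(ll):
        raise EstimationError("ICLV log likelihood is not finite")
    out = [ll]
    if want_grad:
        out.append(total_grad)
    if per_respondent:
        out.append(np.vstack(resp_scores))
    if latent_posterior:
        out.append(np.concatenate(post_num) / np.concatenate(post_den))
    return out[0] if len(out) == 1 else tuple(out)


def iclv_loglik(params, bundle, layout_or_model, draws, grad: bool = False):
    """Functional access to the joint ICLV simulated log likelihood."""
    layout = getattr(layout_or_model, "layout", layout_or_model)
    return _iclv_loglik(np.asarray(params, float), bundle, layout, draws, want_grad=grad)


# ---------------------------------------------------------------------------
# results + model
# ---------------------------------------------------------------------------


@dataclass
class ICLVResults(EstimationResult):
    """Estimation result carrying the latent blocks; adds posterior latent
    scores computed by draw reweighting."""

    def latent_scores(self) -> pd.Series:
        model = self.model
        *_, post = _iclv_loglik(
            self.params.to_numpy(),
            model.bundle,
            model.layout,
            model._fitted_draws,
            want_grad=False,
            latent_posterior=True,
        )
        rids = np.concatenate([b.resp for b in model.bundle.batches])
        return pd.Series(post, index=rids, name="latent_score")

    def summary(self) -> str:  # noqa: D102 - same table, different headline
        text = super().summary()
        return text.replace(
            "Mixed multinomial logit (simulated maximum likelihood)",
            "Integrated choice and latent variable model (simulated maximum likelihood)",
        )


class ICLVModel:
    """Joint choice + latent-variable model bound to a choice dataset.

    ``tau_terms`` (or ``Interaction("latent", col)`` entries on the utility
    spec) select which attribute coefficients shift with the latent trait.
    """

    def __init__(
        self,
        dataset,
        spec: UtilitySpec,
        tau_terms: tuple = (),
        latent: LatentSpec | None = None,
        measurement: MeasurementSpec | None = None,
    ):
        self.spec = spec
        self.bundle = encode(dataset, spec)
        from_spec = tuple(ia.target for ia in spec.interactions if ia.modifier == "latent")
        self.tau_terms = tuple(tau_terms) or from_spec
        self.latent = latent or LatentSpec()
        self.measurement = measurement or MeasurementSpec()
        self.layout = _ICLVParams(self.bundle, self.tau_terms, self.latent, self.measurement)
        self._fitted_draws = None
        n_missing = sum(int((~np.isfinite(b.yb)).any(axis=1).sum()) for b in self.bundle.batches)
        if n_missing:
            warnings.warn(
                f"{n_missing} respondents have missing indicators; they are "
                "excluded from the affected measurement terms"
            )

    @property
    def param_names(self) -> list[str]:
        return list(self.layout.names)

    def _draws(self, n_draws: int, seed: int) -> np.ndarray:
        return halton_normal(
            self.bundle.n_respondents, n_draws, len(self.bundle.random_idx) + 1, seed=seed
        )

    def _start(self) -> np.ndarray:
        lay = self.layout
        x0 = np.zeros(lay.n_params)
        # choice-only MNL warm start for the utility block
        res = optimize.minimize(
            lambda v: tuple(-t for t in _panel_loglik(v, self.bundle, None)),
            np.zeros(lay.K + lay.P),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500, "gtol": 1e-5},
        )
        x0[: lay.K] = res.x[: lay.K]
        x0[lay.K + lay.M : lay.K + lay.M + lay.P] = res.x[lay.K :]
        i = lay.K + lay.M + lay.P + len(lay.tau_terms) + len(lay.covs)
        yb = np.vstack([b.yb for b in self.bundle.batches])
        for j, k in enumerate(lay.binary):
            col = yb[:, BINARY_INDICATORS.index(k)]
            p = np.nanmean(col) if np.isfinite(col).any() else 0.5
            x0[i + 2 * j] = logit(np.clip(p, 0.01, 0.99))
            x0[i + 2 * j + 1] = 0.1
        i += 2 * len(lay.binary)
        if lay.symptoms:
            ys = np.concatenate([b.ys for b in self.bundle.batches])
            ys = ys[np.isfinite(ys)]
            cum = np.array([(ys <= c).mean() for c in range(SYMPTOM_MAX)])
            cum = np.clip(cum, 0.005, 0.995)
            kap = np.maximum.accumulate(logit(cum))
            kap += np.arange(SYMPTOM_MAX) * 1e-3  # strictly increasing
            x0[i] = kap[0]
            x0[i + 1 : i + SYMPTOM_MAX] = np.log(np.maximum(np.diff(kap), 1e-3))
            x0[i + SYMPTOM_MAX] = 0.1
        return x0

    def loglik(self, params, n_draws: int = 500, seed: int = 0) -> float:
        return _iclv_loglik(
            np.asarray(params, float), self.bundle, self.layout, self._draws(n_draws, seed),
            want_grad=False,
        )

    def fit(
        self,
        n_draws: int = 500,
        seed: int = 0,
        start: np.ndarray | None = None,
        maxiter: int = 1000,
        gtol: float = 1e-5,
        cov_type: str = "sandwich",
        sigma_start: float = 0.1,
    ) -> ICLVResults:
        lay = self.layout
        draws = self._draws(n_draws, seed)
        x0 = self._start() if start is None else np.asarray(start, float)
        if start is None and lay.M:
            x0[lay.K : lay.K + lay.M] = sigma_start

        opt = optimize.minimize(
            lambda v: tuple(-t for t in _iclv_loglik(v, self.bundle, lay, draws)),
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
        )
        xhat = self._normalise_sign(opt.x)
        ll, grad, scores = _iclv_loglik(xhat, self.bundle, lay, draws, per_respondent=True)
        cov = self._covariance(xhat, draws, scores, cov_type)
        self._fitted_draws = draws
        return ICLVResults(
            params=pd.Series(xhat, index=lay.names),
            cov=pd.DataFrame(cov, index=lay.names, columns=lay.names),
            llf=float(ll),
            ll_zero=null_loglik(self.bundle),
            n_respondents=self.bundle.n_respondents,
            n_obs=self.bundle.n_obs,
            n_draws=n_draws,
            draw_type="halton",
            converged=bool(opt.success) or float(np.max(np.abs(grad))) < 1e-3,
            grad_norm=float(np.max(np.abs(grad))),
            seed=seed,
            spec=self.spec,
            model=self,
        )

    def _normalise_sign(self, x: np.ndarray) -> np.ndarray:
        """Reflect the latent trait so the anchoring loading is positive."""
        lay = self.layout
        anchor = self.measurement.positive_loading
        if anchor not in lay.binary:
            return x
        j = lay.names.index(f"meas_{anchor}_loading")
        if x[j] >= 0:
            return x
        out = x.copy()
        for flip in self._sign_flip_indices():
            out[flip] = -out[flip]
        return out

    def _sign_flip_indices(self) -> list[int]:
        lay = self.layout
        idx = []
        for i, name in enumerate(lay.names):
            if (
                name.startswith("lv_x_")
                or name.startswith("lv_on_")
                or name.endswith("_loading")
            ):
                idx.append(i)
        return idx

    def _covariance(self, xhat, draws, scores, cov_type: str, step: float = 1e-5) -> np.ndarray:
        Kp = len(xhat)
        B = scores.T @ scores
        H = np.zeros((Kp, Kp))
        for j in range(Kp):
            h = step * max(1.0, abs(xhat[j]))
            xp, xm = xhat.copy(), xhat.copy()
            xp[j] += h
            xm[j] -= h
            _, gp = _iclv_loglik(xp, self.bundle, self.layout, draws)
            _, gm = _iclv_loglik(xm, self.bundle, self.layout, draws)
            H[:, j] = (gp - gm) / (2 * h)
        H = 0.5 * (H + H.T)
        try:
            Ainv = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            Ainv = np.linalg.pinv(-H)
        if cov_type == "hessian":
            return 0.5 * (Ainv + Ainv.T)
        V = Ainv @ B @ Ainv
        return 0.5 * (V + V.T)


def estimate_iclv(
    dataset,
    spec: UtilitySpec,
    tau_terms: tuple = (),
    latent: LatentSpec | None = None,
    measurement: MeasurementSpec | None = None,
    **fit_kwargs,
) -> ICLVResults:
    """One-shot convenience: build :class:`ICLVModel` and fit."""
    return ICLVModel(dataset, spec, tau_terms, latent, measurement).fit(**fit_kwargs)
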