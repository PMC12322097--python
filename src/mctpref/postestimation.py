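"""Post-estimation transforms: odds ratios, the linearised PPV slope, and
NPV-for-PPV marginal rates of substitution.

Odds ratios exponentiate utility coefficients; their 95% intervals are
Krinsky-Robb — percentiles of the transformed parameter over multivariate
normal draws from the estimator's asymptotic distribution.

The PPV attribute is dummy-coded at 20/40/60/80%, so a per-percentage-point
utility slope is defined as the least-squares line through the points
(20, b20), (40, b40), (60, b60), (80, 0); the slope is a fixed linear
contrast c'theta, hence its variance c'Sigma c is exact.  The marginal rate
of substitution between two NPV levels is then

    MRS = -(b_npv_to - b_npv_from) / slope     [PPV percentage points],

the PPV gain needed to compensate for the NPV drop at equal utility, with a
delta-method confidence interval from the analytic gradient of the ratio.
MRS is invariant to rescaling all utility parameters by a common constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .encoding import level_token


class PostEstimationError(ValueError):
    pass


def _mvn_draws(result, n_draws: int, seed: int) -> pd.DataFrame:
    """Multivariate-normal parameter draws at (estimates, covariance); a
    non-PSD covariance is repaired by clipping negative eigenvalues."""
    mean = result.params.to_numpy()
    cov = result.cov.to_numpy()
    vals, vecs = np.linalg.eigh(0.5 * (cov + cov.T))
    if vals.min() < -1e-10 * max(vals.max(), 1.0):
        warnings.warn("covariance not positive semi-definite; clipping eigenvalues")
    vals = np.clip(vals, 0.0, None)
    root = vecs * np.sqrt(vals)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, len(mean)))
    return pd.DataFrame(mean + z @ root.T, columns=result.params.index)


@dataclass
class OddsRatioTable:
    table: pd.DataFrame  # parameter, or, lower, upper
    method: str
    n_draws: int
    seed: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def plot_forest(self, ax=None):
        """Horizontal forest plot of odds ratios with their intervals."""
        import matplotlib.pyplot as plt

        tab = self.table.iloc[::-1]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.35 * len(tab) + 1))
        y = np.arange(len(tab))
        ax.errorbar(
            tab["or"], y,
            xerr=[tab["or"] - tab["lower"], tab["upper"] - tab["or"]],
            fmt="o", color="tab:blue", ecolor="gray", capsize=2,
        )
        ax.axvline(1.0, color="k", lw=0.8, ls="--")
        ax.set_yticks(y)
        ax.set_yticklabels(tab["parameter"])
        ax.set_xlabel("odds ratio (95% Krinsky-Robb interval)")
        return ax


def odds_ratios(result, n_draws: int = 10_000, seed: int = 0, parameters=None) -> OddsRatioTable:
    """exp(estimate) with 95% Krinsky-Robb intervals per utility parameter."""
    names = list(parameters) if parameters is not None else [
        n for n in result.params.index if not n.startswith(("sd_", "ln_scale", "meas_", "lv_on_"))
    ]
    draws = _mvn_draws(result, n_draws, seed)
    rows = []
    for name in names:
        sample = np.exp(draws[name].to_numpy())
        rows.append(
            {
                "parameter": name,
                "or": float(np.exp(result.params[name])),
                "lower": float(np.percentile(sample, 2.5)),
                "upper": float(np.percentile(sample, 97.5)),
            }
        )
    return OddsRatioTable(pd.DataFrame(rows), method="krinsky-robb", n_draws=n_draws, seed=seed)


# ---------------------------------------------------------------------------
# PPV slope and MRS
# ---------------------------------------------------------------------------


def _ppv_contrast(result, group: str) -> tuple[np.ndarray, list[str]]:
    """Contrast vector c over the full parameter vector such that
    slope = c'theta: least squares of the PPV dummy coefficients (plus the
    implicit zero at the reference level) on the PPV percentage."""
    schema = result.spec.schema if result.spec is not None else None
    if schema is not None and "ppv" in schema:
        attr = schema["ppv"]
        levels = [float(v) for v in attr.levels]
        ref = float(attr.reference_level)
        names = [f"ppv_{level_token(v)}" for v in attr.nonreference_levels()]
        xs = [float(v) for v in attr.nonreference_levels()]
    else:
        names = ["ppv_20", "ppv_40", "ppv_60"]
        xs = [20.0, 40.0, 60.0]
        levels = xs + [80.0]
        ref = 80.0
    missing = [n for n in names if n not in result.params.index]
    if missing:
        raise PostEstimationError(f"result lacks PPV level coefficients: {missing}")
    xbar = float(np.mean(levels))
    sxx = float(sum((v - xbar) ** 2 for v in levels))
    c = pd.Series(0.0, index=result.params.index)
    for name, x in zip(names, xs):
        c[name] += (x - xbar) / sxx
        if group == "public" and f"pub_x_{name}" in c.index:
            c[f"pub_x_{name}"] += (x - xbar) / sxx
    # the reference point (ref, 0) contributes nothing to c
    return c.to_numpy(), names


@dataclass
class PPVSlope:
    slope: float  # utility per PPV percentage point
    variance: float
    contrast: np.ndarray
    group: str

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))

    @property
    def tvalue(self) -> float:
        return self.slope / self.se


def ppv_slope(result, group: str = "gp") -> PPVSlope:
    """Per-percentage-point PPV utility slope with exact linear-contrast
    variance c'Sigma c."""
    c, _ = _ppv_contrast(result, group)
    slope = float(c @ result.params.to_numpy())
    var = float(c @ result.cov.to_numpy() @ c)
    return PPVSlope(slope=slope, variance=var, contrast=c, group=group)


@dataclass
class MRSResult:
    npv_from: float
    npv_to: float
    estimate: float  # PPV percentage points
    lower: float
    upper: float
    gradient: np.ndarray
    group: str
    stable: bool

    def __repr__(self) -> str:
        flag = "" if self.stable else "  [unstable slope]"
        return (
            f"MRS(NPV {self.npv_from}% -> {self.npv_to}%, {self.group}): "
            f"{self.estimate:.1f} PPV points (95% CI {self.lower:.1f}-{self.upper:.1f}){flag}"
        )


def _npv_coef_vector(result, level: float, group: str) -> pd.Series:
    """Selector row for the NPV coefficient at ``level`` (0 at the reference)."""
    sel = pd.Series(0.0, index=result.params.index)
    schema = result.spec.schema if result.spec is not None else None
    ref = float(schema["npv"].reference_level) if schema is not None and "npv" in schema else 99.9
    if float(level) == ref:
        return sel
    name = f"npv_{level_token(level)}"
    if name not in sel.index:
        # tolerate e.g. 96 vs 96.0 formatting
        alt = f"npv_{level_token(float(level))}"
        if alt in sel.index:
            name = alt
        else:
            raise PostEstimationError(f"no NPV coefficient {name!r} in result")
    sel[name] = 1.0
    if group == "public" and f"pub_x_{name}" in sel.index:
        sel[f"pub_x_{name}"] = 1.0
    return sel


def mrs_npv_ppv(result, npv_from: float, npv_to: float, group: str = "gp") -> MRSResult:
    """PPV gain (percentage points) compensating an NPV drop from
    ``npv_from``% to ``npv_to``%, with a delta-method 95% interval."""
    c, _ = _ppv_contrast(result, group)
    theta = result.params.to_numpy()
    Sigma = result.cov.to_numpy()
    slope = float(c @ theta)
    sel = (_npv_coef_vector(result, npv_to, group) - _npv_coef_vector(result, npv_from, group)).to_numpy()
    dbeta = float(sel @ theta)
    stable = True
    if abs(slope) * np.sqrt(max(c @ Sigma @ c, 0.0)) > 0 and abs(slope) < np.sqrt(c @ Sigma @ c):
        stable = False
        warnings.warn("PPV slope not significantly different from zero (|t| < 1); MRS unstable")
    mrs = -dbeta / slope
    # gradient of g(theta) = -(sel'theta)/(c'theta)
    grad = (-sel + (dbeta / slope) * c) / slope
    var = float(grad @ Sigma @ grad)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    return MRSResult(
        npv_from=float(npv_from),
        npv_to=float(npv_to),
        estimate=float(mrs),
        lower=float(mrs - half),
        upper=float(mrs + half),
        gradient=grad,
        group=group,
        stable=stable,
    )


def mrs_table(result, npv_levels=None, group: str = "gp") -> pd.DataFrame:
    """All pairwise NPV drops from the reference, one row each."""
    schema = result.spec.schema
    attr = schema["npv"]
    ref = float(attr.reference_level)
    levels = npv_levels or [float(v) for v in attr.levels if float(v) != ref]
    rows = []
    for to in sorted(levels, reverse=True):
        res = mrs_npv_ppv(result, ref, to, group=group)
        rows.append(
            {
                "group": group,
                "npv_from": ref,
                "npv_to": to,
                "ppv_gain": res.estimate,
                "lower": res.lower,
                "upper": res.upper,
                "stable": res.stable,
            }
        )
    return pd.DataFrame(rows)
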