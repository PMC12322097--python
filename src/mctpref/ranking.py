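"""Preference simulation: rank every profile in the design space against a
benchmark test and compare clinical comparators.

Predicted utilities use the estimated coefficient means for a stakeholder
group (GP base coefficients; public = base + sample-interaction shifts) with
the group's scale applied.  Off-grid numeric levels (a benchmark PPV of 76%,
say) are evaluated by piecewise-linear interpolation between the adjacent
level coefficients; values outside the level range are clamped to the
nearest level with a warning.  The probability that profile a is chosen over
profile b is the binary logit exp(V_a) / (exp(V_a) + exp(V_b)); "preferred
in X% of cases" is the share of enumerated profiles whose probability
against the benchmark falls below one half (ties counted in the benchmark's
disfavour and logged).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .encoding import UtilitySpec
from .schema import AttributeSchema, Profile

logger = logging.getLogger(__name__)


@dataclass
class BenchmarkProfile:
    """A (possibly off-grid) test profile with provenance notes."""

    name: str
    profile: Profile
    notes: str = ""

    @classmethod
    def from_dict(cls, name: str, payload: dict) -> "BenchmarkProfile":
        notes = payload.pop("notes", "")
        return cls(name=name, profile=Profile(dict(payload), off_grid=True), notes=notes)


def load_benchmarks(path=None) -> dict[str, BenchmarkProfile]:
    """Benchmark and clinical-comparator profiles from YAML (packaged
    defaults: a SYMPLIFY-like multi-cancer test plus FIT, PSA and CA125 with
    illustrative accuracy values)."""
    if path is None:
        text = resources.files("mctpref.data").joinpath("benchmarks.yaml").read_text()
        payload = yaml.safe_load(text)
    else:
        with open(path) as fh:
            payload = yaml.safe_load(fh)
    return {name: BenchmarkProfile.from_dict(name, dict(spec)) for name, spec in payload.items()}


def _clamped(profile: Profile, schema: AttributeSchema, policy: str = "clamp") -> Profile:
    """Report numeric values outside the level range; clamp or raise."""
    assignment = dict(profile.assignment)
    for attr in schema:
        if attr.name not in assignment or not attr.is_numeric:
            continue
        value = assignment[attr.name]
        if not isinstance(value, (int, float)):
            continue
        lo, hi = min(attr.levels), max(attr.levels)
        if value < lo or value > hi:
            if policy == "error":
                raise ValueError(f"{attr.name}={value} outside level range [{lo}, {hi}]")
            clamped = min(max(value, lo), hi)
            warnings.warn(f"{attr.name}={value} clamped to {clamped} (level range [{lo}, {hi}])")
            assignment[attr.name] = clamped
    return Profile(assignment, off_grid=True)


def profile_utility(
    profile: Profile,
    result,
    group: str = "gp",
    out_of_range: str = "clamp",
) -> float:
    """Deterministic scaled utility of one profile at the coefficient means.

    The GP cell's scale is the normalised reference (1); public utilities use
    the estimated GP-vs-public scale.
    """
    spec: UtilitySpec = result.spec
    schema = spec.schema
    prof = _clamped(profile, schema, policy=out_of_range)
    row = spec.encode_profile(prof, interpolate=True)
    coef = np.array([result.group_coefficient(c, group) for c in spec.main_columns()])
    return float(result.group_scale(group) * (row @ coef))


def pairwise_preference(a: Profile, b: Profile, result, group: str = "gp") -> float:
    """P(choose a over b) = exp(V_a) / (exp(V_a) + exp(V_b))."""
    va = profile_utility(a, result, group)
    vb = profile_utility(b, result, group)
    return float(1.0 / (1.0 + np.exp(-(va - vb))))


@dataclass
class RankingResult:
    table: pd.DataFrame  # attributes, utility, probability vs benchmark, rank
    benchmark: BenchmarkProfile
    benchmark_utility: float
    fraction_benchmark_preferred: float
    group: str

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def rank_against_benchmark(
    schema: AttributeSchema,
    benchmark: BenchmarkProfile | Profile,
    result,
    group: str = "gp",
) -> RankingResult:
    """Enumerate all profiles, compute each profile's probability of being
    chosen over the benchmark, sort descending, and report the fraction of
    profiles over which the benchmark is preferred (probability > 0.5 for
    the benchmark; ties counted against the benchmark)."""
    bench = benchmark if isinstance(benchmark, BenchmarkProfile) else BenchmarkProfile("benchmark", benchmark)
    vb = profile_utility(bench.profile, result, group)
    spec: UtilitySpec = result.spec
    coef = np.array([result.group_coefficient(c, group) for c in spec.main_columns()])
    lam = result.group_scale(group)
    profiles = schema.enumerate_profiles()
    rows = np.array([spec.encode_profile(p) for p in profiles])
    utils = lam * (rows @ coef)
    probs = 1.0 / (1.0 + np.exp(-(utils - vb)))
    table = pd.DataFrame([p.assignment for p in profiles])
    table["utility"] = utils
    table["p_over_benchmark"] = probs
    table = table.sort_values("p_over_benchmark", ascending=False, kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    ties = int((probs == 0.5).sum())
    if ties:
        logger.info("%d profiles tie with the benchmark; counted as not preferred by it", ties)
    fraction = float((probs < 0.5).mean())
    return RankingResult(
        table=table,
        benchmark=bench,
        benchmark_utility=vb,
        fraction_benchmark_preferred=fraction,
        group=group,
    )


def compare_clinical_tests(
    comparators: dict[str, BenchmarkProfile] | list[BenchmarkProfile],
    benchmark: BenchmarkProfile,
    result,
    groups=("gp", "public"),
) -> pd.DataFrame:
    """Probability of choosing each clinical comparator over the benchmark,
    one row per comparator per group."""
    if isinstance(comparators, dict):
        comparators = list(comparators.values())
    rows = []
    for group in groups:
        for comp in comparators:
            p = pairwise_preference(comp.profile, benchmark.profile, result, group)
            rows.append(
                {
                    "group": group,
                    "comparator": comp.name,
                    "benchmark": benchmark.name,
                    "p_comparator_over_benchmark": p,
                }
            )
    return pd.DataFrame(rows)


def plot_ranking(ranking: RankingResult, n_show: int = 40, ax=None, seed: int = 0):
    """Horizontal-bar view of a random subset of profiles' probabilities of
    being chosen over the benchmark."""
    import matplotlib.pyplot as plt

    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(ranking.table), size=min(n_show, len(ranking.table)), replace=False))
    sub = ranking.table.iloc[idx].sort_values("p_over_benchmark")
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.22 * len(sub) + 1))
    colors = ["tab:purple" if p > 0.5 else "tab:blue" for p in sub["p_over_benchmark"]]
    ax.barh(np.arange(len(sub)), sub["p_over_benchmark"], color=colors)
    ax.axvline(0.5, color="k", lw=0.8, ls="--")
    ax.set_xlabel(f"P(choose profile over {ranking.benchmark.name})")
    ax.set_yticks([])
    ax.set_xlim(0, 1)
    return ax
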