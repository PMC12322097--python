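"""Blocked Bayesian D-efficient designs for binary choice tasks.

The design criterion is the Bayesian D-error: the mean over prior parameter
draws of det(I(beta))^(-1/K), where I is the multinomial-logit information
matrix of the (dummy-coded) design, normalised per task, and K the number of
utility parameters.  For the split public design the criterion is the
arm-weighted average of per-arm D-errors, each arm evaluated with its own
utility function (the hidden attribute's columns dropped) — one design, two
utility functions, averaged.

The search is balanced-start coordinate exchange: start from a design in
which every level of every attribute appears the same number of times across
alternative slots, then repeatedly propose pairwise level swaps between two
slots (which preserve exact level balance) and accept a swap when it lowers
the Bayesian D-error without creating a duplicate or an a-priori dominated
task pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .encoding import UtilitySpec
from .schema import ARMS, AttributeSchema, Profile


class DesignError(ValueError):
    pass


class InfeasibleDesignError(DesignError):
    """Level balance impossible for the requested number of tasks."""


@dataclass
class ChoiceTask:
    task_id: int
    profiles: tuple[Profile, Profile]
    block_id: int = 1

    def __post_init__(self) -> None:
        if len(self.profiles) != 2:
            raise DesignError("a choice task holds exactly two profiles")
        if self.profiles[0] == self.profiles[1]:
            raise DesignError(f"task {self.task_id}: identical alternatives")


@dataclass
class PriorSpec:
    """Normal prior over the encoded utility parameters (full-design columns)."""

    mean: np.ndarray
    cov: np.ndarray

    def draws(self, n: int, seed: int) -> np.ndarray:
        """Quasi-random multivariate-normal draws (Sobol'-based)."""
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        eng = qmc.MultivariateNormalQMC(mean=mean, cov=cov, seed=seed)
        m = 1 << (int(n) - 1).bit_length()  # power of two keeps Sobol' balanced
        return eng.random(m)[:n]


def pilot_priors(schema: AttributeSchema | None = None, path=None) -> PriorSpec:
    """Packaged pilot-style priors matched to the canonical schema's columns."""
    import yaml
    from importlib import resources

    if path is None:
        text = resources.files("mctpref.data").joinpath("priors_pilot.yaml").read_text()
        payload = yaml.safe_load(text)
    else:
        with open(path) as fh:
            payload = yaml.safe_load(fh)
    schema = schema or AttributeSchema.canonical_mct()
    cols = UtilitySpec(schema).main_columns()
    mean = np.array([float(payload["mean"].get(c, 0.0)) for c in cols])
    var = payload.get("variance", 0.05)
    cov = np.asarray(var, dtype=float)
    cov = np.diag(np.full(len(cols), float(cov))) if cov.ndim == 0 else cov
    return PriorSpec(mean=mean, cov=cov)


@dataclass
class ExperimentalDesign:
    schema: AttributeSchema
    tasks: list[ChoiceTask]
    n_blocks: int = 1
    prior_spec: PriorSpec | None = None
    d_error: float | None = None
    seed: int | None = None
    arm: str = "full"

    def __post_init__(self) -> None:
        per_block = {}
        for t in self.tasks:
            per_block[t.block_id] = per_block.get(t.block_id, 0) + 1
        if per_block and len(set(per_block.values())) > 1:
            raise DesignError("blocks must contain equally many tasks")

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)

    def tasks_in_block(self, block_id: int) -> list[ChoiceTask]:
        return [t for t in self.tasks if t.block_id == block_id]

    def arm_view(self, arm: str) -> "ExperimentalDesign":
        return split_arm_view(self, arm)

    # -- IO -----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.tasks:
            for alt, p in enumerate(t.profiles, start=1):
                row = {"task_id": t.task_id, "block": t.block_id, "alternative": alt}
                row.update(p.assignment)
                rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path, sidecar: bool = True) -> None:
        self.to_frame().to_csv(path, index=False)
        if sidecar:
            meta = {"d_error": self.d_error, "seed": self.seed, "n_blocks": self.n_blocks, "arm": self.arm}
            if self.prior_spec is not None:
                meta["prior_mean"] = np.asarray(self.prior_spec.mean).tolist()
                meta["prior_cov"] = np.asarray(self.prior_spec.cov).tolist()
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=1)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, schema: AttributeSchema, **kw) -> "ExperimentalDesign":
        tasks = []
        names = [a.name for a in schema if a.name in df.columns]
        for tid, grp in df.groupby("task_id", sort=True):
            grp = grp.sort_values("alternative")
            profiles = tuple(
                Profile({n: r[n] for n in names}) for _, r in grp.iterrows()
            )
            tasks.append(ChoiceTask(int(tid), profiles, int(grp["block"].iloc[0])))
        n_blocks = int(df["block"].nunique())
        return cls(schema=schema, tasks=tasks, n_blocks=n_blocks, **kw)


def split_arm_view(design: ExperimentalDesign, arm: str) -> ExperimentalDesign:
    """Design as seen by one arm: ``full`` is the identity; ``ppv`` removes
    the NPV attribute from every profile, ``npv`` removes PPV.  Task ids and
    blocks are preserved."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    if arm == "full":
        return design
    view = design.schema.visible(arm)
    keep = set(view.names)
    tasks = [
        ChoiceTask(
            t.task_id,
            tuple(Profile({k: v for k, v in p.assignment.items() if k in keep}) for p in t.profiles),
            t.block_id,
        )
        for t in design.tasks
    ]
    return replace(design, schema=view, tasks=tasks, arm=arm)


# ---------------------------------------------------------------------------
# internal slot representation
# ---------------------------------------------------------------------------


class _SlotDesign:
    """Level-index arrays per attribute over 2*n_tasks alternative slots.

    Slot 2t is alternative 1 of task t, slot 2t+1 alternative 2.  Encoding
    tables map level indices to dummy/continuous columns per arm view so the
    information matrix can be rebuilt cheaply after each candidate swap.
    """

    def __init__(self, schema: AttributeSchema, n_tasks: int):
        self.schema = schema
        self.n_tasks = n_tasks
        self.n_slots = 2 * n_tasks
        self.levels = {a.name: np.zeros(self.n_slots, dtype=int) for a in schema}
        spec = UtilitySpec(schema)
        self.full_columns = spec.main_columns()
        # per-attribute encoding tables on the full column set
        self.tables = {}
        pos = 0
        for a in schema:
            if a.is_continuous:
                div = spec.divisors.get(a.name, 1.0)
                tbl = np.array([[float(v) / div] for v in a.levels])
                width = 1
            else:
                nonref = a.nonreference_levels()
                tbl = np.zeros((len(a.levels), len(nonref)))
                for i, lv in enumerate(a.levels):
                    if lv != a.reference_level:
                        tbl[i, nonref.index(lv)] = 1.0
                width = len(nonref)
            self.tables[a.name] = (tbl, pos, width)
            pos += width
        self.K_full = pos

    def encode(self, arm: str = "full") -> np.ndarray:
        """(n_slots, K_arm) encoded matrix for one arm view."""
        view = self.schema.visible(arm)
        cols = []
        for a in view:
            tbl, _, _ = self.tables[a.name]
            cols.append(tbl[self.levels[a.name]])
        return np.hstack(cols)

    def arm_param_idx(self, arm: str) -> np.ndarray:
        view = self.schema.visible(arm)
        idx = []
        for a in view:
            _, pos, width = self.tables[a.name]
            idx.extend(range(pos, pos + width))
        return np.array(idx, dtype=int)

    def task_profiles(self, t: int) -> tuple[dict, dict]:
        out = []
        for slot in (2 * t, 2 * t + 1):
            out.append({a.name: a.levels[self.levels[a.name][slot]] for a in self.schema})
        return tuple(out)

    def task_valid(self, t: int) -> bool:
        """Neither duplicate alternatives nor an a-priori dominated pair."""
        i, j = 2 * t, 2 * t + 1
        if all(self.levels[a.name][i] == self.levels[a.name][j] for a in self.schema):
            return False
        # dominance on monotone attributes: reject if one alternative is weakly
        # better everywhere and strictly better somewhere
        ge = le = True
        strict = False
        for a in self.schema:
            ra = a.preference_rank(a.levels[self.levels[a.name][i]])
            rb = a.preference_rank(a.levels[self.levels[a.name][j]])
            if ra is None:
                continue
            if ra > rb:
                le = False
                strict = True
            elif ra < rb:
                ge = False
                strict = True
        return not (strict and (ge or le))

    def all_valid(self) -> bool:
        return all(self.task_valid(t) for t in range(self.n_tasks))

    def to_design(self, n_blocks: int, rng: np.random.Generator, **kw) -> ExperimentalDesign:
        order = rng.permutation(self.n_tasks)
        per_block = self.n_tasks // n_blocks
        tasks = []
        for rank, t in enumerate(order):
            block = rank // per_block + 1
            p1, p2 = self.task_profiles(t)
            tasks.append(ChoiceTask(int(t) + 1, (Profile(p1), Profile(p2)), int(block)))
        tasks.sort(key=lambda task: task.task_id)
        return ExperimentalDesign(schema=self.schema, tasks=tasks, n_blocks=n_blocks, **kw)


def _info_d_errors(diffs: np.ndarray, betas: np.ndarray) -> np.ndarray:
    """Per-draw D-errors for a binary design given by task difference rows.

    diffs: (T, K); betas: (R, K).  Information per task t is
    p_t(1-p_t) d_t d_t'; the matrix is averaged over tasks (so duplicating
    every task leaves the criterion unchanged).
    """
    T, K = diffs.shape
    v = betas @ diffs.T  # (R, T)
    p = 1.0 / (1.0 + np.exp(-v))
    w = p * (1.0 - p) / T
    info = np.einsum("rt,ti,tj->rij", w, diffs, diffs)
    sign, logdet = np.linalg.slogdet(info)
    out = np.full(betas.shape[0], np.inf)
    ok = sign > 0
    out[ok] = np.exp(-logdet[ok] / K)
    return out


def _slot_d_error(slots: _SlotDesign, prior_draws: np.ndarray, arm_weights: dict) -> float:
    total = 0.0
    for arm, wt in arm_weights.items():
        X = slots.encode(arm)
        diffs = X[0::2] - X[1::2]
        betas = prior_draws[:, slots.arm_param_idx(arm)]
        total += wt * float(np.mean(_info_d_errors(diffs, betas)))
    return total


def default_arm_weights(schema: AttributeSchema) -> dict:
    """Split schemas average the two public arm criteria 50/50 (matching the
    50/50 randomisation); otherwise the full design is the criterion."""
    if schema.has_split_attributes():
        return {"ppv": 0.5, "npv": 0.5}
    return {"full": 1.0}


def bayesian_d_error(
    design: ExperimentalDesign,
    prior_draws: np.ndarray,
    arm_weights: dict | None = None,
) -> float:
    """Mean over prior draws of det(I)^(-1/K); +inf (flagged, not raised)
    when the information matrix is singular for every draw."""
    slots = _SlotDesign(design.schema, design.n_tasks)
    for t, task in enumerate(design.tasks):
        for k, p in enumerate(task.profiles):
            for a in design.schema:
                slots.levels[a.name][2 * t + k] = a.level_rank(p.assignment[a.name])
    weights = arm_weights or default_arm_weights(design.schema)
    return _slot_d_error(slots, np.atleast_2d(prior_draws), weights)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _balanced_start(schema: AttributeSchema, n_tasks: int, rng: np.random.Generator) -> _SlotDesign:
    slots = _SlotDesign(schema, n_tasks)
    n_slots = slots.n_slots
    for a in schema:
        L = len(a.levels)
        if n_slots % L:
            raise InfeasibleDesignError(
                f"attribute {a.name!r}: {n_slots} alternative slots not divisible by {L} levels"
            )
        vec = np.repeat(np.arange(L), n_slots // L)
        rng.shuffle(vec)
        slots.levels[a.name] = vec
    # repair duplicate/dominated tasks by balance-preserving random swaps
    for _ in range(200 * n_tasks):
        bad = [t for t in range(n_tasks) if not slots.task_valid(t)]
        if not bad:
            break
        t = int(rng.choice(bad))
        a = schema.attributes[int(rng.integers(len(schema)))]
        i = 2 * t + int(rng.integers(2))
        j = int(rng.integers(n_slots))
        slots.levels[a.name][i], slots.levels[a.name][j] = (
            slots.levels[a.name][j],
            slots.levels[a.name][i],
        )
    if not slots.all_valid():
        raise DesignError("could not construct a valid balanced starting design")
    return slots


def generate_design(
    schema: AttributeSchema,
    priors: PriorSpec,
    n_tasks: int = 24,
    n_blocks: int = 2,
    seed: int = 0,
    n_sweeps: int = 200,
    n_prior_draws: int = 100,
    arm_weights: dict | None = None,
) -> ExperimentalDesign:
    """Level-balanced Bayesian D-efficient design by coordinate exchange.

    Deterministic given (schema, priors, seed).  The returned design's
    D-error is never larger than that of the balanced random start.
    """
    if n_tasks % n_blocks:
        raise DesignError(f"{n_tasks} tasks not divisible into {n_blocks} blocks")
    rng = np.random.default_rng(seed)
    weights = arm_weights or default_arm_weights(schema)
    draws = priors.draws(n_prior_draws, seed=seed)
    if draws.shape[1] != _SlotDesign(schema, n_tasks).K_full:
        raise DesignError(
            f"prior draws have {draws.shape[1]} columns; design needs "
            f"{_SlotDesign(schema, n_tasks).K_full}"
        )

    slots = _balanced_start(schema, n_tasks, rng)
    current = _slot_d_error(slots, draws, weights)
    n_slots = slots.n_slots

    for _ in range(n_sweeps):
        improved = False
        for a in schema:
            lv = slots.levels[a.name]
            for _ in range(n_slots):
                i, j = rng.integers(n_slots, size=2)
                if lv[i] == lv[j]:
                    continue
                lv[i], lv[j] = lv[j], lv[i]
                ti, tj = i // 2, j // 2
                if slots.task_valid(ti) and slots.task_valid(tj):
                    cand = _slot_d_error(slots, draws, weights)
                    if cand < current:
                        current = cand
                        improved = True
                        continue
                lv[i], lv[j] = lv[j], lv[i]  # revert
        if not improved:
            break

    return slots.to_design(
        n_blocks, rng, prior_spec=priors, d_error=float(current), seed=seed
    )


def random_balanced_design(
    schema: AttributeSchema,
    n_tasks: int = 24,
    n_blocks: int = 2,
    seed: int = 0,
) -> ExperimentalDesign:
    """A valid level-balanced design with no efficiency search: the
    distribution the coordinate-exchange optimiser starts from, useful as a
    Monte-Carlo reference for the achieved D-error."""
    if n_tasks % n_blocks:
        raise DesignError(f"{n_tasks} tasks not divisible into {n_blocks} blocks")
    rng = np.random.default_rng(seed)
    slots = _balanced_start(schema, n_tasks, rng)
    return slots.to_design(n_blocks, rng, seed=seed)


def level_balance_table(design: ExperimentalDesign, arm: str = "full") -> pd.DataFrame:
    """Level counts across alternative slots per visible attribute."""
    view = split_arm_view(design, arm)
    rows = []
    for a in view.schema:
        counts = {lv: 0 for lv in a.levels}
        for t in view.tasks:
            for p in t.profiles:
                counts[p.assignment[a.name]] += 1
        for lv, n in counts.items():
            rows.append({"attribute": a.name, "level": lv, "count": n})
    return pd.DataFrame(rows)
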