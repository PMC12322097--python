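"""Utility specification and design-matrix construction.

Categorical attributes are dummy-coded against their reference level
(PPV 80%, NPV 99.9%, 1 week, blood, site=no, early=no); the number of
cancers enters as a continuous term per 10 cancers.  A profile at every
reference level therefore has a zero utility row, and the canonical
seven-attribute system yields 13 main-effect columns.

Interaction terms multiply a respondent-level modifier (the GP/public
"sample" dummy or a binary covariate) into an attribute column.  Scale
differences between data sources are handled by per-respondent scale cells:
each (group, arm) cell maps to a product of positive scale parameters with
the reference cell fixed at 1.

The split public design is encoded without imputation: an attribute a
respondent never saw contributes structurally-zero columns to both
alternatives of each of their tasks, which is algebraically identical to the
arm-specific utility function with those columns dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
import pandas as pd

from .schema import AttributeSchema, Profile

#: covariates collected for every respondent (urban is the omitted category)
COVARIATES = ("age65", "female", "ethnic_minority", "degree", "rural", "suburban")

#: cancer knowledge/experience indicators (binary; symptom_count is 0-16)
BINARY_INDICATORS = ("screened", "had_cancer", "tested")
SYMPTOM_MAX = 16

DEFAULT_DIVISORS = {"cancers": 10.0}


class EncodingError(ValueError):
    """Raised when data cannot be mapped onto the utility specification."""


def level_token(value) -> str:
    return str(value).replace(" ", "_")


@dataclass(frozen=True)
class Interaction:
    """A respondent-modifier x attribute-column interaction term.

    ``modifier`` is ``"sample"`` (1 for public respondents), a covariate name,
    or ``"latent"`` (handled inside the ICLV likelihood, never materialised
    as a data column).
    """

    modifier: str
    target: str

    @property
    def column(self) -> str:
        prefix = "pub" if self.modifier == "sample" else self.modifier
        return f"{prefix}_x_{self.target}"


@dataclass
class UtilitySpec:
    """What enters the utility function and how.

    Parameters
    ----------
    schema : AttributeSchema
        Attribute system the data were generated from.
    divisors : dict
        Continuous-attribute divisors (default: cancers per 10).
    random_terms : tuple of str
        Main-effect columns given normally distributed respondent-specific
        coefficients (panel mixing: one draw per respondent).
    interactions : tuple of Interaction
        Additional modifier x attribute columns.
    scale_cells : dict
        Maps (group, arm) -> tuple of scale-parameter names whose product
        multiplies that cell's utilities; the empty tuple is the reference
        cell fixed at 1.  Exactly one normalisation is required.
    weight_rule : {"group_balance", "none"}
        ``group_balance`` gives each group weight 0.5 * N_total / N_group so
        unequal samples contribute equally to the pooled likelihood.
    """

    schema: AttributeSchema
    divisors: dict = field(default_factory=lambda: dict(DEFAULT_DIVISORS))
    random_terms: tuple = ()
    interactions: tuple = ()
    scale_cells: dict = field(default_factory=dict)
    weight_rule: str = "group_balance"

    # -- column bookkeeping -------------------------------------------------
    def main_columns(self) -> list[str]:
        cols: list[str] = []
        for attr in self.schema:
            if attr.is_continuous:
                div = self.divisors.get(attr.name, 1.0)
                cols.append(f"{attr.name}_per{div:g}")
            else:
                cols.extend(f"{attr.name}_{level_token(lv)}" for lv in attr.nonreference_levels())
        return cols

    def interaction_columns(self) -> list[str]:
        return [ia.column for ia in self.interactions if ia.modifier != "latent"]

    def all_columns(self) -> list[str]:
        return self.main_columns() + self.interaction_columns()

    def scale_params(self) -> list[str]:
        seen: list[str] = []
        for names in self.scale_cells.values():
            for name in names:
                if name not in seen:
                    seen.append(name)
        return seen

    def random_indices(self) -> list[int]:
        cols = self.all_columns()
        missing = [t for t in self.random_terms if t not in cols]
        if missing:
            raise EncodingError(f"random terms not in specification: {missing}")
        return [cols.index(t) for t in self.random_terms]

    def validate(self) -> None:
        for ia in self.interactions:
            if ia.target not in self.main_columns():
                raise EncodingError(f"interaction target {ia.target!r} is not a main column")
        if self.scale_cells and not any(len(v) == 0 for v in self.scale_cells.values()):
            raise EncodingError("one scale cell must be the reference (empty product)")

    # -- constructors -------------------------------------------------------
    @classmethod
    def pooled_default(
        cls,
        schema: AttributeSchema,
        random_terms: tuple = (),
        sample_interactions: str | tuple = "all",
    ) -> "UtilitySpec":
        """Pooled GP + public specification: sample-dummy interactions on
        every attribute column and the two-scale-parameter structure
        (GP full design normalised to 1; the public PPV arm carries the
        GP-vs-public scale; the NPV arm additionally carries the arm scale)."""
        spec = cls(schema=schema, random_terms=tuple(random_terms))
        targets = spec.main_columns() if sample_interactions == "all" else list(sample_interactions)
        spec.interactions = tuple(Interaction("sample", t) for t in targets)
        spec.scale_cells = {
            ("gp", "full"): (),
            ("public", "ppv"): ("ln_scale_public",),
            ("public", "npv"): ("ln_scale_public", "ln_scale_npv_arm"),
        }
        return spec

    @classmethod
    def single_group(cls, schema: AttributeSchema, random_terms: tuple = ()) -> "UtilitySpec":
        """One sample, one scale (no interactions); e.g. a GP-only fit."""
        return cls(schema=schema, random_terms=tuple(random_terms), weight_rule="none")

    @classmethod
    def public_split(cls, schema: AttributeSchema, random_terms: tuple = ()) -> "UtilitySpec":
        """Public-only specification: PPV arm is the reference scale cell and
        the NPV arm carries the arm scale parameter."""
        spec = cls(schema=schema, random_terms=tuple(random_terms))
        spec.scale_cells = {
            ("public", "ppv"): (),
            ("public", "npv"): ("ln_scale_npv_arm",),
        }
        return spec

    # -- profile encoding ---------------------------------------------------
    def encode_profile(self, profile: Profile, interpolate: bool = None) -> np.ndarray:
        """Main-effect row for one profile.

        Off-grid numeric values on dummy-coded attributes are evaluated by
        piecewise-linear interpolation between the adjacent level columns
        (the reference level contributing an implicit zero column).
        """
        if interpolate is None:
            interpolate = profile.off_grid
        cols = self.main_columns()
        row = np.zeros(len(cols))
        pos = 0
        for attr in self.schema:
            if attr.name not in profile.assignment:
                # hidden split-arm attribute: structural zeros
                pos += 1 if attr.is_continuous else len(attr.nonreference_levels())
                continue
            value = profile.assignment[attr.name]
            if attr.is_continuous:
                row[pos] = float(value) / self.divisors.get(attr.name, 1.0)
                pos += 1
                continue
            nonref = attr.nonreference_levels()
            if value in attr.levels:
                if value != attr.reference_level:
                    row[pos + nonref.index(value)] = 1.0
            elif interpolate and attr.is_numeric:
                lv = np.array(sorted(float(v) for v in attr.levels))
                x = float(value)
                x = min(max(x, lv[0]), lv[-1])  # clamp to the level range
                j = int(np.searchsorted(lv, x, side="right")) - 1
                j = min(j, len(lv) - 2)
                lo, hi = lv[j], lv[j + 1]
                w_hi = (x - lo) / (hi - lo)
                for level, weight in ((lo, 1.0 - w_hi), (hi, w_hi)):
                    for orig in attr.levels:
                        if float(orig) == level and orig != attr.reference_level:
                            row[pos + nonref.index(orig)] = weight
            else:
                raise EncodingError(f"{attr.name}={value!r} is not a schema level (set off_grid to interpolate)")
            pos += len(nonref)
        return row


# ---------------------------------------------------------------------------
# dataset -> arrays
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrixBundle:
    """Binary-task, within-task differenced arrays grouped for batching.

    Each batch collects respondents with the same number of tasks:
    ``D`` (n, T, K) holds alternative-1 minus alternative-2 encoded rows,
    ``c`` (n, T) is +1 when alternative 1 was chosen else -1, ``S`` (n, P)
    maps respondents onto log-scale parameters, ``w`` (n,) are likelihood
    weights, ``z`` (n, n_cov) respondent covariates, ``yb`` (n, 3) binary
    indicators and ``ys`` (n,) the symptom count (NaN where missing).
    """

    columns: list[str]
    scale_names: list[str]
    random_idx: list[int]
    batches: list[SimpleNamespace]
    spec: UtilitySpec

    @property
    def n_respondents(self) -> int:
        return sum(b.D.shape[0] for b in self.batches)

    @property
    def n_obs(self) -> int:
        return sum(b.D.shape[0] * b.D.shape[1] for b in self.batches)


def _attribute_matrix(df: pd.DataFrame, spec: UtilitySpec) -> np.ndarray:
    """Main-effect encoding of the long-format rows (absent attributes -> 0)."""
    cols = []
    for attr in spec.schema:
        if attr.name not in df.columns:
            raise EncodingError(f"dataset lacks attribute column {attr.name!r}")
        values = df[attr.name]
        if attr.is_continuous:
            div = spec.divisors.get(attr.name, 1.0)
            cols.append((values.astype(float) / div).fillna(0.0).to_numpy())
        else:
            present = values.notna()
            known = values.isin(attr.levels) | ~present
            if not known.all():
                bad = df.index[~known][0]
                raise EncodingError(
                    f"row {bad}: {attr.name}={values.loc[bad]!r} is not a schema level"
                )
            for lv in attr.nonreference_levels():
                cols.append((values == lv).to_numpy().astype(float))
    return np.column_stack(cols)


def compute_weights(groups: pd.Series) -> pd.Series:
    """Group-balancing weights w = 0.5 * N_total / N_group per respondent."""
    counts = groups.value_counts()
    if len(counts) == 1:
        return pd.Series(1.0, index=groups.index)
    total = len(groups)
    return groups.map(lambda g: 0.5 * total / counts[g])


def encode(dataset, spec: UtilitySpec) -> DesignMatrixBundle:
    """Build the differenced design-matrix bundle from a long-format dataset.

    ``dataset`` is a :class:`~mctpref.simulate.ChoiceDataset` or a DataFrame
    with columns respondent_id, group, arm, task_id, alternative, chosen,
    one column per attribute, and (optionally) covariates and indicators.
    """
    df = dataset.df if hasattr(dataset, "df") else dataset
    spec.validate()
    df = df.sort_values(["respondent_id", "task_id", "alternative"], kind="stable")
    df = df.reset_index(drop=True)

    X = _attribute_matrix(df, spec)

    # interactions: modifier value per row x target main column
    main_cols = spec.main_columns()
    extra = []
    for ia in spec.interactions:
        if ia.modifier == "latent":
            continue
        if ia.modifier == "sample":
            mod = (df["group"] == "public").to_numpy().astype(float)
        elif ia.modifier in df.columns:
            mod = df[ia.modifier].to_numpy().astype(float)
        else:
            raise EncodingError(f"interaction modifier {ia.modifier!r} not in dataset")
        extra.append(mod * X[:, main_cols.index(ia.target)])
    if extra:
        X = np.column_stack([X] + extra)

    columns = spec.all_columns()
    scale_names = spec.scale_params()

    # per-respondent metadata
    rmeta = df.groupby("respondent_id", sort=True).first()
    if spec.weight_rule == "group_balance" and "group" in rmeta:
        weights = compute_weights(rmeta["group"])
    elif "weight" in rmeta and spec.weight_rule == "dataset":
        weights = rmeta["weight"].astype(float)
    else:
        weights = pd.Series(1.0, index=rmeta.index)

    smat = pd.DataFrame(0.0, index=rmeta.index, columns=scale_names)
    if spec.scale_cells:
        for rid, row in rmeta.iterrows():
            cell = (row.get("group", "gp"), row.get("arm", "full"))
            if cell not in spec.scale_cells:
                raise EncodingError(f"respondent {rid}: no scale cell for {cell}")
            for pname in spec.scale_cells[cell]:
                smat.loc[rid, pname] = 1.0

    # difference alternative rows within task; batch by tasks-per-respondent
    n_alt = df.groupby(["respondent_id", "task_id"]).size()
    if not (n_alt == 2).all():
        raise EncodingError("every task must have exactly two alternatives")
    first = df.groupby(["respondent_id", "task_id"], sort=True)
    idx1 = first.head(1).index.to_numpy()
    idx2 = first.tail(1).index.to_numpy()
    Drows = X[idx1] - X[idx2]
    ch1 = df.loc[idx1, "chosen"].to_numpy().astype(int)
    ch2 = df.loc[idx2, "chosen"].to_numpy().astype(int)
    if not ((ch1 + ch2) == 1).all():
        raise EncodingError("exactly one alternative must be chosen per task")
    csign = np.where(ch1 == 1, 1.0, -1.0)
    task_resp = df.loc[idx1, "respondent_id"].to_numpy()

    counts = pd.Series(task_resp).value_counts()
    batches = []
    for T in sorted(counts.unique()):
        rids = sorted(counts.index[counts == T])
        mask = np.isin(task_resp, rids)
        order = np.argsort(task_resp[mask], kind="stable")
        D = Drows[mask][order].reshape(len(rids), T, X.shape[1])
        c = csign[mask][order].reshape(len(rids), T)
        sub = rmeta.loc[rids]
        z = np.column_stack(
            [sub[c_].to_numpy(dtype=float) if c_ in sub else np.zeros(len(rids)) for c_ in COVARIATES]
        )
        yb = np.column_stack(
            [
                sub[c_].to_numpy(dtype=float) if c_ in sub else np.full(len(rids), np.nan)
                for c_ in BINARY_INDICATORS
            ]
        )
        ys = (
            sub["symptom_count"].to_numpy(dtype=float)
            if "symptom_count" in sub
            else np.full(len(rids), np.nan)
        )
        batches.append(
            SimpleNamespace(
                D=D,
                c=c,
                S=smat.loc[rids].to_numpy(dtype=float),
                w=weights.loc[rids].to_numpy(dtype=float),
                resp=np.asarray(rids),
                z=z,
                yb=yb,
                ys=ys,
            )
        )

    return DesignMatrixBundle(
        columns=columns,
        scale_names=scale_names,
        random_idx=spec.random_indices(),
        batches=batches,
        spec=spec,
    )
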