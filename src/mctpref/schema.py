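"""Attribute/level descriptive system for choice experiments on multi-cancer tests.

A hypothetical test ("MCT") is described by a small set of attributes, each
taking one of a few levels: positive predictive value (PPV, %), negative
predictive value (NPV, %), waiting time for results, number of cancer sites
covered, whether the test identifies the cancer site, the sample form
(blood/faecal/urine/breath) and whether early-stage disease is detected.
The canonical seven-attribute system has level counts (4, 4, 2, 4, 2, 4, 2),
whose Cartesian product spans 2048 distinct test profiles.

In the split public design the PPV attribute is shown only to the PPV arm and
the NPV attribute only to the NPV arm; clinicians see the full system.  The
``arm_visibility`` field on :class:`Attribute` carries that rule.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Iterator

import yaml

ARMS = ("full", "ppv", "npv")
ARM_VISIBILITIES = ("all", "ppv_arm", "npv_arm")
MONOTONE = ("increasing", "decreasing", "none")


class SchemaError(ValueError):
    """Raised when an attribute system is internally inconsistent."""


@dataclass(frozen=True)
class Attribute:
    """One characteristic of a hypothetical test.

    Parameters
    ----------
    name : str
        Identifier used in data files and coefficient names.
    coding : {"categorical", "continuous"}
        Dummy-vs-reference coding or a single numeric column.
    levels : tuple
        Ordered experimental levels (numeric where meaningful).
    reference_level :
        Omitted category for dummy coding (categorical only).
    arm_visibility : {"all", "ppv_arm", "npv_arm"}
        Which public design arm displays the attribute.
    monotone : {"increasing", "decreasing", "none"}
        A-priori preference direction over the level ordering, used for
        dominance screening during design generation.
    wording : dict, optional
        Audience-specific display labels (metadata only).
    """

    name: str
    coding: str = "categorical"
    levels: tuple = ()
    reference_level: Any = None
    arm_visibility: str = "all"
    monotone: str = "none"
    wording: dict | None = None

    def __post_init__(self) -> None:
        if self.coding not in ("categorical", "continuous"):
            raise SchemaError(f"{self.name}: unknown coding {self.coding!r}")
        if self.arm_visibility not in ARM_VISIBILITIES:
            raise SchemaError(f"{self.name}: unknown arm_visibility {self.arm_visibility!r}")
        if self.monotone not in MONOTONE:
            raise SchemaError(f"{self.name}: unknown monotone tag {self.monotone!r}")
        if len(self.levels) < 2:
            raise SchemaError(f"{self.name}: needs at least 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise SchemaError(f"{self.name}: levels must be unique")
        if self.coding == "continuous":
            if not all(isinstance(v, (int, float)) for v in self.levels):
                raise SchemaError(f"{self.name}: continuous attribute needs numeric levels")
        elif self.reference_level is not None and self.reference_level not in self.levels:
            raise SchemaError(f"{self.name}: reference level {self.reference_level!r} not a level")
        object.__setattr__(self, "levels", tuple(self.levels))

    @property
    def is_continuous(self) -> bool:
        return self.coding == "continuous"

    @property
    def is_numeric(self) -> bool:
        return all(isinstance(v, (int, float)) for v in self.levels)

    def nonreference_levels(self) -> list:
        return [v for v in self.levels if v != self.reference_level]

    def level_rank(self, value: Any) -> int:
        return self.levels.index(value)

    def preference_rank(self, value: Any) -> float | None:
        """Position of ``value`` on the a-priori better/worse axis, or None."""
        if self.monotone == "none":
            return None
        rank = self.level_rank(value)
        return rank if self.monotone == "increasing" else -rank


@dataclass
class Profile:
    """A single hypothetical test: a full attribute -> level assignment.

    ``off_grid`` permits numeric values strictly between categorical numeric
    levels; such profiles are prediction-only (benchmark tests like the
    SYMPLIFY MCT with PPV 76% / NPV 98%) and are evaluated by interpolation.
    """

    assignment: dict[str, Any]
    off_grid: bool = False

    def __getitem__(self, name: str) -> Any:
        return self.assignment[name]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Profile) and self.assignment == other.assignment


@dataclass
class AttributeSchema:
    """Ordered collection of :class:`Attribute` with unique names."""

    attributes: list[Attribute] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise SchemaError("attribute names must be unique")
        for vis in ("ppv_arm", "npv_arm"):
            if sum(a.arm_visibility == vis for a in self.attributes) > 1:
                raise SchemaError(f"at most one attribute may have arm_visibility={vis}")

    # -- container protocol -------------------------------------------------
    def __iter__(self) -> Iterator[Attribute]:
        return iter(self.attributes)

    def __len__(self) -> int:
        return len(self.attributes)

    def __getitem__(self, name: str) -> Attribute:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(a.name == name for a in self.attributes)

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.attributes]

    # -- arm views ----------------------------------------------------------
    def visible(self, arm: str) -> "AttributeSchema":
        """Sub-schema shown to one design arm (full/ppv/npv)."""
        if arm not in ARMS:
            raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
        if arm == "full":
            return self
        hidden = "npv_arm" if arm == "ppv" else "ppv_arm"
        return AttributeSchema([a for a in self.attributes if a.arm_visibility != hidden])

    def has_split_attributes(self) -> bool:
        return any(a.arm_visibility != "all" for a in self.attributes)

    # -- enumeration --------------------------------------------------------
    def n_profiles(self) -> int:
        n = 1
        for a in self.attributes:
            n *= len(a.levels)
        return n

    def enumerate_profiles(self) -> list[Profile]:
        """Full Cartesian product of levels, in deterministic lexicographic
        order of the schema's attribute and level ordering."""
        if not self.attributes:
            raise SchemaError("cannot enumerate an empty schema")
        combos = itertools.product(*(a.levels for a in self.attributes))
        return [Profile(dict(zip(self.names, combo))) for combo in combos]

    def validate_profile(self, profile: Profile) -> None:
        for a in self.attributes:
            if a.name not in profile.assignment:
                raise SchemaError(f"profile missing attribute {a.name!r}")
            value = profile.assignment[a.name]
            if a.is_continuous or profile.off_grid:
                continue
            if value not in a.levels:
                raise SchemaError(f"{a.name}={value!r} is not a schema level")

    # -- IO -----------------------------------------------------------------
    @classmethod
    def from_dict(cls, payload: dict) -> "AttributeSchema":
        attrs = []
        for spec in payload["attributes"]:
            spec = dict(spec)
            spec["levels"] = tuple(spec["levels"])
            attrs.append(Attribute(**spec))
        return cls(attrs)

    @classmethod
    def from_yaml(cls, path) -> "AttributeSchema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def canonical_mct(cls) -> "AttributeSchema":
        """The packaged seven-attribute multi-cancer-test system (2048 profiles)."""
        text = resources.files("mctpref.data").joinpath("schema_mct.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))


def enumerate_profiles(schema: AttributeSchema) -> list[Profile]:
    """Functional alias for :meth:`AttributeSchema.enumerate_profiles`."""
    return schema.enumerate_profiles()
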