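"""The matrisome domain rule set: category definitions and validation.

A rule set is an ordered list of categories.  Each category carries a set of
inclusion accessions (signature domains), a set of exclusion accessions
(negative screen), a division (core / associated / adhesome / other), and
signal-peptide / membrane requirements.  Category order is precedence order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["CategoryRule", "DomainRuleSet", "load_rules", "default_rules"]

DIVISIONS = ("core", "associated", "adhesome", "other")
MEMBRANE_STATES = ("required", "forbidden", "any")


@dataclass(frozen=True)
class CategoryRule:
    name: str
    division: str
    inclusion: frozenset[str]
    exclusion: frozenset[str]
    requires_signal: bool = False
    membrane: str = "any"  # tri-state: required | forbidden | any

    def __post_init__(self) -> None:
        if self.division not in DIVISIONS:
            raise ValueError(f"{self.name}: unknown division {self.division!r}")
        if self.membrane not in MEMBRANE_STATES:
            raise ValueError(f"{self.name}: membrane must be one of {MEMBRANE_STATES}")
        if self.inclusion & self.exclusion:
            raise ValueError(
                f"{self.name}: inclusion and exclusion sets overlap: "
                f"{sorted(self.inclusion & self.exclusion)}"
            )
        if not self.inclusion:
            raise ValueError(f"{self.name}: empty inclusion set")


@dataclass(frozen=True)
class DomainRuleSet:
    """Ordered category rules plus the bona fide ECM signature list."""

    categories: tuple[CategoryRule, ...]
    bona_fide: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError("rule set must define at least one category")
        names = [c.name for c in self.categories]
        if len(set(names)) != len(names):
            raise ValueError("category names must be unique")

    @property
    def positive_screen(self) -> frozenset[str]:
        """Union of all inclusion domains — the candidate screen set."""
        acc: set[str] = set()
        for cat in self.categories:
            acc |= cat.inclusion
        return frozenset(acc)

    def category(self, name: str) -> CategoryRule:
        for cat in self.categories:
            if cat.name == name:
                return cat
        raise KeyError(name)

    @property
    def division_of(self) -> dict[str, str]:
        return {c.name: c.division for c in self.categories}


def load_rules(path: str | Path) -> DomainRuleSet:
    """Load a rule set from a YAML config file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _from_dict(doc)


def _from_dict(doc: dict) -> DomainRuleSet:
    cats = []
    for entry in doc.get("categories", []):
        cats.append(CategoryRule(
            name=entry["name"],
            division=entry["division"],
            inclusion=frozenset(entry.get("inclusion", [])),
            exclusion=frozenset(entry.get("exclusion", [])),
            requires_signal=bool(entry.get("requires_signal", False)),
            membrane=entry.get("membrane", "any"),
        ))
    return DomainRuleSet(
        categories=tuple(cats),
        bona_fide=frozenset(doc.get("bona_fide", [])),
    )


def default_rules() -> DomainRuleSet:
    """The shipped default rule set (see data/default_rules.yaml)."""
    text = resources.files("matrisopy.data").joinpath("default_rules.yaml").read_text()
    return _from_dict(yaml.safe_load(text))
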