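"""Variable catalog: resource-class x ownership covariates and risk tiers.

Each covariate of the selection models is the area (ha) of one land-class
variable inside a resource unit. A variable is a crossing of a foraging
resource class (agriculture, water, marsh, supplemental feeding refuge,
flooded agriculture) with an ownership stratum, each ownership carrying a
presumed hunting-risk tier. Michigan DNR property is an ownership-only
variable: cells inside it are coded MICH-DNR regardless of land class.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

RESOURCE_CLASSES = (
    "agriculture",
    "water",
    "marsh",
    "supplemental feeding refuge",
    "flooded agriculture",
    "other",
)

OWNERSHIPS = ("public", "private", "Walpole", "CWS", "MICH-DNR", "Michigan")

#: tie-break when ownership polygons overlap: most legally constrained first
OWNERSHIP_PRIORITY = ("CWS", "Walpole", "MICH-DNR", "Michigan", "private", "public")

RISK_TIERS = ("high", "intermediate", "none")

#: ownership -> presumed hunting risk. Public land has the fewest hunting
#: restrictions; the federal (CWS) refuge prohibits hunting entirely; the
#: remaining ownerships regulate frequency/locations and sit in between.
OWNERSHIP_RISK = {
    "public": "high",
    "private": "intermediate",
    "Walpole": "intermediate",
    "MICH-DNR": "intermediate",
    "Michigan": "intermediate",
    "CWS": "none",
}

OTHER_CODE = 0
NODATA_CODE = -1


@dataclass(frozen=True)
class Variable:
    code: int
    abbreviation: str
    resource_class: str | None  # None => ownership-only variable
    ownership: str
    risk_tier: str

    def __post_init__(self) -> None:
        if self.resource_class is not None and self.resource_class not in RESOURCE_CLASSES:
            raise ValueError(f"unknown resource class {self.resource_class!r}")
        if self.ownership not in OWNERSHIPS:
            raise ValueError(f"unknown ownership {self.ownership!r}")
        if self.risk_tier not in RISK_TIERS:
            raise ValueError(f"unknown risk tier {self.risk_tier!r}")


@dataclass
class VariableCatalog:
    """Registry of covariate codes used in the crossed landscape raster."""

    variables: list[Variable] = field(default_factory=list)

    def __post_init__(self) -> None:
        abbrs = [v.abbreviation for v in self.variables]
        if len(set(abbrs)) != len(abbrs):
            raise ValueError("variable abbreviations must be unique")
        codes = [v.code for v in self.variables]
        if len(set(codes)) != len(codes):
            raise ValueError("variable codes must be unique")
        if OTHER_CODE in codes or NODATA_CODE in codes:
            raise ValueError("codes 0 and -1 are reserved for OTHER and NODATA")

    def __len__(self) -> int:
        return len(self.variables)

    def __iter__(self):
        return iter(self.variables)

    @property
    def abbreviations(self) -> list[str]:
        return [v.abbreviation for v in self.variables]

    @property
    def codes(self) -> list[int]:
        return [v.code for v in self.variables]

    def by_abbreviation(self, abbr: str) -> Variable:
        for v in self.variables:
            if v.abbreviation == abbr:
                return v
        raise KeyError(abbr)

    def by_code(self, code: int) -> Variable:
        for v in self.variables:
            if v.code == code:
                return v
        raise KeyError(code)

    def crossing_code(self, resource_class: str, ownership: str) -> int:
        """Code for a (resource class, ownership) crossing.

        Ownership-only variables (MICH-DNR) swallow every resource class in
        their stratum. Crossings with no registered variable map to OTHER.
        """
        for v in self.variables:
            if v.resource_class is None and v.ownership == ownership:
                return v.code
        for v in self.variables:
            if v.resource_class == resource_class and v.ownership == ownership:
                return v.code
        return OTHER_CODE

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["code", "abbreviation", "resource_class", "ownership", "risk_tier"])
            for v in self.variables:
                w.writerow([v.code, v.abbreviation, v.resource_class or "", v.ownership, v.risk_tier])

    @classmethod
    def from_csv(cls, path: str | Path) -> "VariableCatalog":
        variables = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                variables.append(
                    Variable(
                        code=int(row["code"]),
                        abbreviation=row["abbreviation"],
                        resource_class=row["resource_class"] or None,
                        ownership=row["ownership"],
                        risk_tier=row["risk_tier"],
                    )
                )
        return cls(variables)


def default_catalog() -> VariableCatalog:
    """The 14 default variables of the autumn-winter selection analysis."""
    spec = [
        ("MICH-DNR", None, "MICH-DNR"),
        ("PUB-WATER", "water", "public"),
        ("PRI-WATER", "water", "private"),
        ("WAL-WATER", "water", "Walpole"),
        ("MICH-WATER", "water", "Michigan"),
        ("PUB-MARSH", "marsh", "public"),
        ("PRI-MARSH", "marsh", "private"),
        ("WAL-MARSH", "marsh", "Walpole"),
        ("CWS-MARSH", "marsh", "CWS"),
        ("CWS-WATER", "water", "CWS"),
        ("PRI-FLAG", "flooded agriculture", "private"),
        ("PRI-SUPP", "supplemental feeding refuge", "private"),
        ("PRI-AGRI", "agriculture", "private"),
        ("WAL-AGRI", "agriculture", "Walpole"),
    ]
    variables = []
    for i, (abbr, rclass, own) in enumerate(spec, start=1):
        risk = "intermediate" if rclass == "supplemental feeding refuge" else OWNERSHIP_RISK[own]
        variables.append(Variable(i, abbr, rclass, own, risk))
    return VariableCatalog(variables)
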