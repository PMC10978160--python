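"""Drug master data and hazard-group assignment.

Antineoplastic drugs (ADs) are assessed not drug-by-drug but in eight
hazard groups that share a contamination-relevant property of the
marketed product: powdered form, liquid form, corrosivity, availability
in a single strength, instability (immediate-use only), absence of an
external holder casing (plastic shrink film or break-proof container),
high average therapeutic concentration, and poor solubility.  One
product may fall into several groups; group membership is what the risk
matrices downstream are indexed by.

The packaged catalog (``data/drugs.csv``) transcribes the product
characteristics used in a four-hospital Italian FMECA study of manual
vs automated AD compounding; a few products absent from the published
characteristics table carry standard formulary strengths instead.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

from .errors import ParseError, SchemaError

__all__ = [
    "ADGroup",
    "Form",
    "StabilityClass",
    "DrugRecord",
    "assign_groups",
    "load_drug_catalog",
    "default_catalog",
    "group_members",
]


class Form(enum.Enum):
    """Marketed pharmaceutical form of the product."""

    POWDER = "powder"
    LIQUID = "liquid"


class StabilityClass(enum.Enum):
    """Post-reconstitution/dilution shelf-life class.

    ``IMMEDIATE_USE`` means the preparation must be used at once; it is
    the only class that feeds the *unstable* hazard group.  ``LIMITED``
    is a bounded shelf life under 24 h, ``EXTENDED`` 24 h or more.
    """

    IMMEDIATE_USE = "immediate_use"
    LIMITED = "limited"
    EXTENDED = "extended"
    UNKNOWN = "unknown"


class ADGroup(enum.Enum):
    """The eight antineoplastic-drug hazard groups, in table order."""

    POWDER = "powder"
    LIQUID = "liquid"
    CORROSIVE = "corrosive"
    ONE_CONCENTRATION = "one_concentration"
    UNSTABLE = "unstable"
    NO_HOLDER_CASING = "no_holder_casing"
    HIGH_AVG_CONCENTRATION = "high_avg_concentration"
    POORLY_SOLUBLE = "poorly_soluble"


@dataclass(frozen=True)
class DrugRecord:
    """One marketed antineoplastic product and its hazard-relevant attributes.

    Parameters
    ----------
    drug_id
        Short code used throughout monitoring data (e.g. ``"CP"``).
    forms
        Marketed forms; non-empty subset of {powder, liquid}.
    liquid_concentrations, reconstituted_concentrations
        mg/mL values of the solution as sold / after reconstitution.
    marketed_strengths_mg
        Distinct vial strengths (mg) on the market; a product marketed
        in exactly one strength belongs to the one-concentration group.
    has_holder_casing
        Whether the vial ships inside an external plastic shrink film or
        break-proof container (reduces outer-surface contamination).
    """

    drug_id: str
    name: str
    forms: frozenset[Form]
    liquid_concentrations: tuple[float, ...] = ()
    reconstituted_concentrations: tuple[float, ...] = ()
    marketed_strengths_mg: tuple[float, ...] = ()
    corrosive: bool = False
    stability_class: StabilityClass = StabilityClass.UNKNOWN
    poorly_soluble: bool = False
    packaging_materials: tuple[str, ...] = ()
    has_holder_casing: bool = True
    high_avg_therapeutic_concentration: bool = False
    recommended_dosage: str = ""

    def __post_init__(self) -> None:
        if not self.forms:
            raise ParseError(f"drug {self.drug_id!r}: forms must be non-empty")
        for label, values in (
            ("liquid_concentrations", self.liquid_concentrations),
            ("reconstituted_concentrations", self.reconstituted_concentrations),
            ("marketed_strengths_mg", self.marketed_strengths_mg),
        ):
            for v in values:
                if not v > 0:
                    raise ParseError(
                        f"drug {self.drug_id!r}: {label} value {v!r} must be > 0"
                    )
        if (
            Form.POWDER in self.forms
            and not self.reconstituted_concentrations
            and self.stability_class is not StabilityClass.UNKNOWN
        ):
            raise ParseError(
                f"drug {self.drug_id!r}: powdered form requires reconstituted "
                "concentrations (or stability flagged unknown)"
            )


def _distinct_marketed_concentrations(drug: DrugRecord) -> int:
    """Count the distinct marketed presentations of a product.

    Vial strengths are the discriminator when known; otherwise fall back
    to distinct concentration values across liquid and reconstituted
    lists.
    """
    if drug.marketed_strengths_mg:
        return len(set(drug.marketed_strengths_mg))
    return len(set(drug.liquid_concentrations) | set(drug.reconstituted_concentrations))


def assign_groups(drug: DrugRecord) -> frozenset[ADGroup]:
    """Return every hazard group whose predicate ``drug`` satisfies.

    Total and deterministic: a valid record always maps to a (possibly
    empty) set, and a product may belong to several groups.
    """
    groups: set[ADGroup] = set()
    if Form.POWDER in drug.forms:
        groups.add(ADGroup.POWDER)
    if Form.LIQUID in drug.forms:
        groups.add(ADGroup.LIQUID)
    if drug.corrosive:
        groups.add(ADGroup.CORROSIVE)
    if _distinct_marketed_concentrations(drug) == 1:
        groups.add(ADGroup.ONE_CONCENTRATION)
    if drug.stability_class is StabilityClass.IMMEDIATE_USE:
        groups.add(ADGroup.UNSTABLE)
    if not drug.has_holder_casing:
        groups.add(ADGroup.NO_HOLDER_CASING)
    if drug.high_avg_therapeutic_concentration:
        groups.add(ADGroup.HIGH_AVG_CONCENTRATION)
    if drug.poorly_soluble:
        groups.add(ADGroup.POORLY_SOLUBLE)
    return frozenset(groups)


def group_members(catalog: Iterable[DrugRecord], group: ADGroup) -> frozenset[str]:
    """Drug ids in ``catalog`` belonging to ``group``."""
    return frozenset(d.drug_id for d in catalog if group in assign_groups(d))


_REQUIRED_COLUMNS = (
    "drug_id",
    "name",
    "forms",
    "liquid_conc_mg_ml",
    "reconst_conc_mg_ml",
    "corrosive",
    "stability",
    "poorly_soluble",
    "packaging",
    "has_holder_casing",
    "high_avg_conc",
)

_BOOL_TOKENS = {"true": True, "1": True, "yes": True, "x": True,
                "false": False, "0": False, "no": False, "": False}


def _parse_bool(cell: str, row_id: str, column: str) -> bool:
    try:
        return _BOOL_TOKENS[cell.strip().lower()]
    except KeyError:
        raise ParseError(f"row {row_id!r}, column {column!r}: not a boolean: {cell!r}")


def _parse_floats(cell: str, row_id: str, column: str) -> tuple[float, ...]:
    values = []
    for token in cell.split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            value = float(token)
        except ValueError:
            raise ParseError(
                f"row {row_id!r}, column {column!r}: not numeric: {token!r}"
            )
        if not value > 0:
            raise ParseError(
                f"row {row_id!r}, column {column!r}: value must be > 0, got {token!r}"
            )
        values.append(value)
    return tuple(values)


def load_drug_catalog(path: Union[str, Path]) -> list[DrugRecord]:
    """Load a drug catalog CSV into a list of :class:`DrugRecord`.

    Schema (header row required): ``drug_id,name,forms,liquid_conc_mg_ml,
    reconst_conc_mg_ml,strengths_mg,corrosive,stability,poorly_soluble,
    packaging,has_holder_casing,high_avg_conc[,recommended_dosage]``.
    Multi-valued cells are ``;``-separated.  An unknown stability token
    is a parse error, but the literal token ``unknown`` is accepted.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        missing = [c for c in _REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s): {missing}")
        records: list[DrugRecord] = []
        for row in reader:
            row_id = row.get("drug_id", "").strip() or f"line {reader.line_num}"
            try:
                forms = frozenset(
                    Form(tok.strip()) for tok in row["forms"].split(";") if tok.strip()
                )
            except ValueError:
                raise ParseError(f"row {row_id!r}: unknown form in {row['forms']!r}")
            try:
                stability = StabilityClass(row["stability"].strip() or "unknown")
            except ValueError:
                raise ParseError(
                    f"row {row_id!r}: unknown stability class {row['stability']!r}"
                )
            records.append(
                DrugRecord(
                    drug_id=row_id,
                    name=row["name"].strip(),
                    forms=forms,
                    liquid_concentrations=_parse_floats(
                        row["liquid_conc_mg_ml"], row_id, "liquid_conc_mg_ml"
                    ),
                    reconstituted_concentrations=_parse_floats(
                        row["reconst_conc_mg_ml"], row_id, "reconst_conc_mg_ml"
                    ),
                    marketed_strengths_mg=_parse_floats(
                        row.get("strengths_mg", ""), row_id, "strengths_mg"
                    ),
                    corrosive=_parse_bool(row["corrosive"], row_id, "corrosive"),
                    stability_class=stability,
                    poorly_soluble=_parse_bool(
                        row["poorly_soluble"], row_id, "poorly_soluble"
                    ),
                    packaging_materials=tuple(
                        tok.strip() for tok in row["packaging"].split(";") if tok.strip()
                    ),
                    has_holder_casing=_parse_bool(
                        row["has_holder_casing"], row_id, "has_holder_casing"
                    ),
                    high_avg_therapeutic_concentration=_parse_bool(
                        row["high_avg_conc"], row_id, "high_avg_conc"
                    ),
                    recommended_dosage=(row.get("recommended_dosage") or "").strip(),
                )
            )
    return records


def default_catalog() -> list[DrugRecord]:
    """The packaged 29-product catalog."""
    with resources.as_file(
        resources.files("adrisk").joinpath("data/drugs.csv")
    ) as path:
        return load_drug_catalog(path)
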