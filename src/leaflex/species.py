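"""Lipid species shorthand model and the shared membrane-composition data model.

Species are identified at sum-composition level using the shotgun-lipidomics
shorthand ``"CLASS C:D"`` — headgroup class, total acyl carbons, total double
bonds (e.g. ``"PC 34:1"``, ``"SM 42:2"``). Chain-resolved names such as
``"PE(20:0/20:0)"`` are accepted and collapsed to totals. Cholesterol is a
special species with no acyl-chain descriptor.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Dict, Mapping

__all__ = [
    "HeadgroupClass",
    "LipidSpecies",
    "LeafletComposition",
    "SpeciesParseError",
    "parse_species_name",
    "class_of",
    "CHOLESTEROL",
]


class SpeciesParseError(ValueError):
    """Raised when a lipid species name cannot be parsed."""


class HeadgroupClass(str, enum.Enum):
    """Phospholipid headgroup classes (plus cholesterol and a catch-all)."""

    SM = "SM"
    PC = "PC"
    PE = "PE"
    PS = "PS"
    PI = "PI"
    LPC = "LPC"
    LPE = "LPE"
    CHOL = "CHOL"
    OTHER = "OTHER"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Classes that count as phospholipids (denominator of mol% computations).
PHOSPHOLIPID_CLASSES = frozenset(
    c for c in HeadgroupClass if c not in (HeadgroupClass.CHOL,)
)

_CHOL_RE = re.compile(r"chol(esterol)?", re.IGNORECASE)
_SHORTHAND_RE = re.compile(r"([A-Za-z]+)\s*(\d+)\s*:\s*(\d+)")
_CHAIN_RE = re.compile(r"[OdtP]?-?(\d+)\s*:\s*(\d+)(?:;\w+)?")


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid identity at sum-composition level.

    ``class_label`` retains the original class token for species that parse to
    :attr:`HeadgroupClass.OTHER` in permissive mode (e.g. ``"CER"``); for known
    classes it equals the enum value.
    """

    headgroup_class: HeadgroupClass
    carbons: int
    double_bonds: int
    class_label: str = ""

    def __post_init__(self) -> None:
        if not self.class_label:
            object.__setattr__(self, "class_label", self.headgroup_class.value)
        if self.carbons < 0 or self.double_bonds < 0:
            raise ValueError("carbons and double_bonds must be non-negative")
        if self.headgroup_class is HeadgroupClass.CHOL and (
            self.carbons != 0 or self.double_bonds != 0
        ):
            raise ValueError("cholesterol carries no acyl-chain descriptor")

    @property
    def canonical_name(self) -> str:
        if self.headgroup_class is HeadgroupClass.CHOL:
            return "CHOL"
        return f"{self.class_label} {self.carbons}:{self.double_bonds}"

    def __str__(self) -> str:
        return self.canonical_name

    def sort_key(self) -> tuple:
        return (self.headgroup_class.value, self.carbons, self.double_bonds)


CHOLESTEROL = LipidSpecies(HeadgroupClass.CHOL, 0, 0)


def _parse_chain_resolved(cls_token: str, body: str, name: str) -> tuple[int, int]:
    """Collapse a chain-resolved descriptor like ``20:0/20:0`` to totals."""
    chains = re.split(r"[/_]", body)
    carbons = bonds = 0
    for chain in chains:
        m = _CHAIN_RE.fullmatch(chain.strip())
        if m is None:
            raise SpeciesParseError(
                f"unparseable acyl chain {chain.strip()!r} in {name!r}"
            )
        carbons += int(m.group(1))
        bonds += int(m.group(2))
    return carbons, bonds


def _resolve_class(token: str, name: str, strict: bool) -> tuple[HeadgroupClass, str]:
    upper = token.upper()
    if upper in HeadgroupClass.__members__ and upper != "OTHER":
        return HeadgroupClass(upper), upper
    if strict:
        raise SpeciesParseError(f"unknown lipid class {token!r} in {name!r}")
    return HeadgroupClass.OTHER, upper


def parse_species_name(name: str, strict: bool = True) -> LipidSpecies:
    """Parse a shorthand (or chain-resolved) lipid species name.

    Parameters
    ----------
    name:
        e.g. ``"PC 34:1"``, ``"sm34:1"``, ``"cholesterol"``, ``"PE(20:0/20:0)"``.
    strict:
        If True, an unknown class token is an error; otherwise it maps to
        :attr:`HeadgroupClass.OTHER`, keeping the token as the class label.
    """
    if not isinstance(name, str) or not name.strip():
        raise SpeciesParseError("empty species name")
    s = name.strip()

    if _CHOL_RE.fullmatch(s):
        return CHOLESTEROL

    # chain-resolved forms: "PE(20:0/20:0)" or "PC 16:0/18:1"
    paren = re.fullmatch(r"([A-Za-z]+)\s*\(([^)]+)\)", s)
    if paren is not None or "/" in s or "_" in s:
        if paren is not None:
            cls_token, body = paren.group(1), paren.group(2)
        else:
            parts = s.split(None, 1)
            if len(parts) != 2:
                raise SpeciesParseError(f"malformed species name {name!r}")
            cls_token, body = parts
        cls, label = _resolve_class(cls_token, name, strict)
        if cls is HeadgroupClass.CHOL:
            raise SpeciesParseError(f"cholesterol takes no chain descriptor: {name!r}")
        carbons, bonds = _parse_chain_resolved(cls_token, body, name)
        return LipidSpecies(cls, carbons, bonds, label)

    m = _SHORTHAND_RE.fullmatch(s)
    if m is None:
        if ":" not in s:
            raise SpeciesParseError(
                f"missing ':' carbon:double-bond descriptor in {name!r}"
            )
        raise SpeciesParseError(f"malformed species name {name!r}")
    cls, label = _resolve_class(m.group(1), name, strict)
    if cls is HeadgroupClass.CHOL:
        raise SpeciesParseError(f"cholesterol takes no chain descriptor: {name!r}")
    return LipidSpecies(cls, int(m.group(2)), int(m.group(3)), label)


def class_of(species: LipidSpecies) -> HeadgroupClass:
    """Headgroup class of a species."""
    return species.headgroup_class


_LEAFLET_TOL = 1e-9


@dataclass(frozen=True)
class LeafletComposition:
    """Ground-truth per-leaflet phospholipid composition of a bilayer membrane.

    ``outer`` and ``inner`` map species to mol fractions, each normalised
    within its leaflet (sums to 1). Cholesterol is held separately as a
    fraction of all membrane lipids (``cholesterol_fraction_total``) because
    its leaflet distribution is not modelled. ``outer_share`` is the fraction
    of total phospholipid residing in the outer leaflet; it makes
    whole-membrane amounts recoverable from the leaflet-normalised maps.
    """

    outer: Mapping[LipidSpecies, float]
    inner: Mapping[LipidSpecies, float]
    cholesterol_fraction_total: float
    outer_share: float

    def __post_init__(self) -> None:
        for leaflet_name, leaflet in (("outer", self.outer), ("inner", self.inner)):
            total = 0.0
            for sp, frac in leaflet.items():
                if sp.headgroup_class is HeadgroupClass.CHOL:
                    raise ValueError(
                        "cholesterol must not appear inside the phospholipid maps"
                    )
                if frac < 0:
                    raise ValueError(f"negative mol fraction for {sp} in {leaflet_name}")
                total += frac
            if abs(total - 1.0) > _LEAFLET_TOL:
                raise ValueError(
                    f"{leaflet_name} leaflet mol fractions sum to {total!r}, not 1"
                )
        if not 0.0 <= self.cholesterol_fraction_total < 1.0:
            raise ValueError("cholesterol_fraction_total must be in [0, 1)")
        if not 0.0 < self.outer_share < 1.0:
            raise ValueError("outer_share must be in (0, 1)")

    def class_totals(self, leaflet: str = "outer") -> Dict[HeadgroupClass, float]:
        """Class-level mol fractions within one leaflet, by summation."""
        src = self.outer if leaflet == "outer" else self.inner
        out: Dict[HeadgroupClass, float] = {}
        for sp, frac in src.items():
            out[sp.headgroup_class] = out.get(sp.headgroup_class, 0.0) + frac
        return out

    def species_amounts(self) -> Dict[LipidSpecies, float]:
        """Whole-membrane phospholipid amounts on a total-phospholipid = 1 basis."""
        amounts: Dict[LipidSpecies, float] = {}
        for sp, frac in self.outer.items():
            amounts[sp] = amounts.get(sp, 0.0) + self.outer_share * frac
        for sp, frac in self.inner.items():
            amounts[sp] = amounts.get(sp, 0.0) + (1.0 - self.outer_share) * frac
        return amounts

    def cholesterol_amount(self) -> float:
        """Cholesterol moles on the same total-phospholipid = 1 basis."""
        f = self.cholesterol_fraction_total
        return f / (1.0 - f)

    def within_class_mol_percent(self, leaflet: str = "outer") -> Dict[str, float]:
        """Within-class species mol%, the quantity the reconstruction estimates."""
        src = self.outer if leaflet == "outer" else self.inner
        totals = self.class_totals(leaflet)
        return {
            sp.canonical_name: 100.0 * frac / totals[sp.headgroup_class]
            for sp, frac in src.items()
            if totals[sp.headgroup_class] > 0
        }
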