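"""Lipidome table I/O, detection-limit cleaning, and mol% bookkeeping.

The on-disk lipidome format is a long CSV/TSV with columns
``sample_id, role, loaded_lipid, species, abundance[, censored]`` — one row
per (sample, species). Mol% tables can be computed with either denominator a
lipidomics report might use: within each headgroup class, or over all
phospholipids; cholesterol is never part of a phospholipid denominator.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, NamedTuple, Optional, Sequence, Union

import pandas as pd

from .species import (
    HeadgroupClass,
    LipidSpecies,
    SpeciesParseError,
    parse_species_name,
)

__all__ = [
    "SampleRole",
    "Denominator",
    "LipidEntry",
    "MeasuredLipidome",
    "MolPercentTable",
    "DuplicateRecordError",
    "EmptyLipidomeError",
    "read_lipidome_table",
    "write_lipidome_table",
    "filter_below_detection",
    "to_mol_percent",
    "aggregate_minor_species",
]


class SampleRole(str, enum.Enum):
    UNTREATED_CELLS = "untreated_cells"
    EXCHANGED_CELLS = "exchanged_cells"
    SUPERNATANT = "supernatant"


class Denominator(str, enum.Enum):
    WITHIN_CLASS = "within_class"
    ALL_PHOSPHOLIPIDS = "all_phospholipids"


class LipidEntry(NamedTuple):
    abundance: float
    censored: bool = False


class DuplicateRecordError(ValueError):
    """Two rows resolve to the same (sample, canonical species) pair."""


class EmptyLipidomeError(ValueError):
    """No usable phospholipid entries to normalise."""


@dataclass
class MeasuredLipidome:
    """One sample's species → abundance table with below-detection flags.

    ``loaded_class`` records the headgroup class of the lipid loaded into the
    cyclodextrin for this sample's exchange (None for untreated controls);
    ``loaded_label`` keeps the human-readable name (e.g. "bSM", "POPS").
    """

    sample_id: str
    role: SampleRole
    entries: Dict[LipidSpecies, LipidEntry]
    loaded_class: Optional[HeadgroupClass] = None
    loaded_label: Optional[str] = None

    def abundances(self, include_censored: bool = False) -> Dict[LipidSpecies, float]:
        return {
            sp: e.abundance
            for sp, e in self.entries.items()
            if include_censored or not e.censored
        }

    def total_phospholipid(self) -> float:
        return sum(
            e.abundance
            for sp, e in self.entries.items()
            if not e.censored and sp.headgroup_class is not HeadgroupClass.CHOL
        )


@dataclass
class MolPercentTable:
    """Species mol% under a stated denominator.

    ``values`` is keyed by canonical species name (plain strings, so that
    aggregated "other PCs" entries live in the same container); ``classes``
    maps each name to its headgroup class. ``class_totals`` are class-level
    percentages of all phospholipids, obtained by summation over species.
    """

    denominator: Denominator
    values: Dict[str, float]
    classes: Dict[str, HeadgroupClass]
    class_totals: Dict[HeadgroupClass, float]
    sample_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "species": name,
                "class": self.classes[name].value,
                "percent": pct,
                "denominator": self.denominator.value,
            }
            for name, pct in sorted(self.values.items())
        ]
        return pd.DataFrame(rows, columns=["species", "class", "percent", "denominator"])

    def write_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


_REQUIRED_COLUMNS = ("sample_id", "role", "loaded_lipid", "species", "abundance")


def _parse_loaded(
    raw: object, strict: bool
) -> tuple[Optional[HeadgroupClass], Optional[str]]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
        return None, None
    label = str(raw).strip()
    if not label:
        return None, None
    token = label.upper()
    if token in ("BSM", "SM"):
        return HeadgroupClass.SM, label
    if token == "POPC":
        return HeadgroupClass.PC, label
    if token == "POPS":
        return HeadgroupClass.PS, label
    if token in HeadgroupClass.__members__:
        return HeadgroupClass(token), label
    try:
        sp = parse_species_name(label, strict=strict)
    except SpeciesParseError:
        raise SpeciesParseError(f"unparseable loaded_lipid {label!r}")
    return sp.headgroup_class, label


def read_lipidome_table(
    path: Union[str, Path], strict: bool = True
) -> List[MeasuredLipidome]:
    """Read a long-format lipidome CSV/TSV into per-sample lipidomes.

    Species names are canonicalised through the species parser; two rows of
    one sample that collide after canonicalisation (e.g. ``"PC 34:1"`` and
    ``"pc 34:1"``) raise :class:`DuplicateRecordError`.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"lipidome table {path} missing required columns: {missing}")

    lipidomes: Dict[str, MeasuredLipidome] = {}
    for row in df.itertuples(index=False):
        sample_id = str(row.sample_id)
        species = parse_species_name(str(row.species), strict=strict)
        if sample_id not in lipidomes:
            loaded_class, loaded_label = _parse_loaded(row.loaded_lipid, strict)
            lipidomes[sample_id] = MeasuredLipidome(
                sample_id=sample_id,
                role=SampleRole(str(row.role)),
                entries={},
                loaded_class=loaded_class,
                loaded_label=loaded_label,
            )
        lip = lipidomes[sample_id]
        if species in lip.entries:
            raise DuplicateRecordError(
                f"duplicate record for sample {sample_id!r}, "
                f"species {species.canonical_name!r}"
            )
        censored = bool(getattr(row, "censored", False))
        abundance = float(row.abundance)
        if abundance < 0:
            raise ValueError(
                f"negative abundance for {species.canonical_name} in {sample_id!r}"
            )
        lip.entries[species] = LipidEntry(abundance, censored)
    return list(lipidomes.values())


def write_lipidome_table(
    lipidomes: Sequence[MeasuredLipidome], path: Union[str, Path]
) -> None:
    """Write lipidomes back to the canonical long CSV/TSV format."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    rows = []
    for lip in lipidomes:
        for sp in sorted(lip.entries, key=LipidSpecies.sort_key):
            entry = lip.entries[sp]
            rows.append(
                {
                    "sample_id": lip.sample_id,
                    "role": lip.role.value,
                    "loaded_lipid": lip.loaded_label or "",
                    "species": sp.canonical_name,
                    "abundance": repr(float(entry.abundance)),
                    "censored": entry.censored,
                }
            )
    pd.DataFrame(
        rows,
        columns=["sample_id", "role", "loaded_lipid", "species", "abundance", "censored"],
    ).to_csv(path, index=False, sep=sep)


def filter_below_detection(lip: MeasuredLipidome, limit: float) -> MeasuredLipidome:
    """Drop entries below the instrument detection limit.

    Entries with abundance < ``limit`` — and entries already flagged censored —
    are removed outright, not zero-filled, mirroring how below-detection
    entries are excised from shotgun-lipidomics exports. All surviving entries
    are untouched.
    """
    if limit < 0:
        raise ValueError("detection limit must be non-negative")
    kept = {
        sp: e
        for sp, e in lip.entries.items()
        if not e.censored and e.abundance >= limit
    }
    return replace(lip, entries=kept)


def to_mol_percent(
    lip: MeasuredLipidome,
    denominator: Denominator = Denominator.WITHIN_CLASS,
) -> MolPercentTable:
    """Convert abundances to mol% under the chosen denominator.

    Cholesterol is always excluded from phospholipid denominators; censored
    entries contribute nothing.
    """
    usable = {
        sp: e.abundance
        for sp, e in lip.entries.items()
        if not e.censored and sp.headgroup_class is not HeadgroupClass.CHOL
    }
    total = sum(usable.values())
    if not usable or total <= 0:
        raise EmptyLipidomeError(
            f"sample {lip.sample_id!r} has no usable phospholipid entries"
        )

    class_sums: Dict[HeadgroupClass, float] = {}
    for sp, a in usable.items():
        class_sums[sp.headgroup_class] = class_sums.get(sp.headgroup_class, 0.0) + a

    values: Dict[str, float] = {}
    classes: Dict[str, HeadgroupClass] = {}
    for sp, a in usable.items():
        denom = (
            class_sums[sp.headgroup_class]
            if denominator is Denominator.WITHIN_CLASS
            else total
        )
        values[sp.canonical_name] = 100.0 * a / denom
        classes[sp.canonical_name] = sp.headgroup_class

    class_totals = {cls: 100.0 * s / total for cls, s in class_sums.items()}
    return MolPercentTable(
        denominator=denominator,
        values=values,
        classes=classes,
        class_totals=class_totals,
        sample_id=lip.sample_id,
    )


def other_species_name(cls: HeadgroupClass) -> str:
    """Name of the aggregate bucket for minor species of one class."""
    return f"other {cls.value}s"


def aggregate_minor_species(
    table: MolPercentTable, threshold: float = 1.0
) -> MolPercentTable:
    """Sum species under ``threshold`` percent into one "other" entry per class.

    Mirrors the common figure-level rule of pooling sub-1% species; totals are
    preserved exactly (the bucket carries the plain sum).
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    values: Dict[str, float] = {}
    classes: Dict[str, HeadgroupClass] = {}
    minor: Dict[HeadgroupClass, float] = {}
    for name, pct in table.values.items():
        cls = table.classes[name]
        if pct < threshold:
            minor[cls] = minor.get(cls, 0.0) + pct
        else:
            values[name] = pct
            classes[name] = cls
    for cls, pooled in minor.items():
        name = other_species_name(cls)
        values[name] = values.get(name, 0.0) + pooled
        classes[name] = cls
    return MolPercentTable(
        denominator=table.denominator,
        values=values,
        classes=classes,
        class_totals=dict(table.class_totals),
        sample_id=table.sample_id,
    )
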