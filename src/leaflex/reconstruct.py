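"""Outer-leaflet composition inference by masking and cross-experiment averaging.

The supernatant of each exchange experiment contains the extracted
outer-leaflet lipids *plus* an excess of the exogenous lipid that was loaded
into the cyclodextrin. The loaded lipid's headgroup class is therefore
unquantifiable in its own experiment and is masked out; each class's species
values are instead averaged over the experiments in which a *different* class
was loaded. With three loadings covering SM, PC, and PS, every class is
observable from the other two experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .io import Denominator, MeasuredLipidome, MolPercentTable
from .species import HeadgroupClass
from . import stats as _stats

__all__ = [
    "SpeciesEstimate",
    "OuterLeafletEstimate",
    "ExperimentTable",
    "UnobservableClassError",
    "mask_loaded_lipid",
    "reconstruct_outer_leaflet",
    "compare_before_after",
]


class UnobservableClassError(ValueError):
    """Every experiment loaded this class; it cannot be reconstructed."""


class SpeciesEstimate(NamedTuple):
    mean: float
    sd: float  # NaN when n < 2
    n: int


@dataclass(frozen=True)
class ExperimentTable:
    """One exchange experiment's (replicate-averaged) supernatant mol% table."""

    experiment_id: str
    loaded_class: HeadgroupClass
    table: MolPercentTable


@dataclass
class OuterLeafletEstimate:
    """Reconstructed outer-leaflet species mol% with replicate dispersion.

    ``provenance`` lists, per class, the experiments its values were averaged
    from; by construction a class never draws on its own loading experiment.
    """

    values: Dict[str, SpeciesEstimate]
    classes: Dict[str, HeadgroupClass]
    provenance: Dict[HeadgroupClass, List[str]]
    denominator: Denominator = Denominator.WITHIN_CLASS

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "species": name,
                "class": self.classes[name].value,
                "mean": est.mean,
                "sd": est.sd,
                "n": est.n,
                "provenance": ";".join(self.provenance[self.classes[name]]),
            }
            for name, est in sorted(self.values.items())
        ]
        return pd.DataFrame(
            rows, columns=["species", "class", "mean", "sd", "n", "provenance"]
        )

    def write_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


def mask_loaded_lipid(lip: MeasuredLipidome) -> MeasuredLipidome:
    """Remove every species of the loaded lipid's headgroup class.

    The whole class is masked, not just the loaded species: a natural-mixture
    loading (brain SM) spans many species of its class, and class-level
    masking is what makes the cross-experiment averaging well-posed.
    """
    if lip.loaded_class is None:
        raise ValueError(f"sample {lip.sample_id!r} has no loaded lipid recorded")
    kept = {
        sp: e for sp, e in lip.entries.items()
        if sp.headgroup_class is not lip.loaded_class
    }
    return replace(lip, entries=kept)


def reconstruct_outer_leaflet(
    experiments: Sequence[ExperimentTable],
) -> OuterLeafletEstimate:
    """Average each class over the experiments that did not load it.

    For every species of class K, the estimate is the unweighted arithmetic
    mean (with sample SD and source count n) over all experiments whose loaded
    class is not K. A species censored out of one contributing experiment
    simply reduces its n (n = 1 estimates carry an undefined SD). A class
    loaded in *every* experiment raises :class:`UnobservableClassError`.
    """
    if len(experiments) < 2:
        raise ValueError("need at least 2 experiments with distinct loaded classes")
    if len({e.loaded_class for e in experiments}) < 2:
        raise ValueError("experiments must load at least 2 distinct classes")
    denominators = {e.table.denominator for e in experiments}
    if len(denominators) != 1:
        raise ValueError("experiments mix mol% denominators")

    # species universe and class map across all experiments
    classes: Dict[str, HeadgroupClass] = {}
    for e in experiments:
        for name, cls in e.table.classes.items():
            classes[name] = cls

    # a class whose species only ever appear in its own loading experiment(s)
    # has no usable source at all
    unobservable = []
    for cls in sorted(set(classes.values()), key=lambda c: c.value):
        containing = [
            e
            for e in experiments
            if any(c is cls for c in e.table.classes.values())
        ]
        if containing and all(e.loaded_class is cls for e in containing):
            unobservable.append(cls.value)
    if unobservable:
        raise UnobservableClassError(
            f"classes observed only in their own loading experiments, "
            f"not reconstructable: {unobservable}"
        )

    values: Dict[str, SpeciesEstimate] = {}
    provenance: Dict[HeadgroupClass, List[str]] = {}
    for name, cls in classes.items():
        contributing = [e for e in experiments if e.loaded_class is not cls]
        provenance.setdefault(
            cls, sorted(e.experiment_id for e in contributing)
        )
        obs = [
            e.table.values[name] for e in contributing if name in e.table.values
        ]
        if not obs:
            continue  # censored everywhere it was observable
        arr = np.asarray(obs, dtype=float)
        sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else float("nan")
        values[name] = SpeciesEstimate(float(np.mean(arr)), sd, int(arr.size))

    classes = {name: classes[name] for name in values}
    provenance = {cls: ids for cls, ids in provenance.items() if cls in set(classes.values())}
    return OuterLeafletEstimate(
        values=values,
        classes=classes,
        provenance=provenance,
        denominator=next(iter(denominators)),
    )


class SpeciesComparison(NamedTuple):
    delta: float  # exchanged minus untreated, percentage points
    p_value: Optional[float]
    p_adjusted: Optional[float]
    stars: str


def _as_list(
    tables: Union[MolPercentTable, Sequence[MolPercentTable]]
) -> List[MolPercentTable]:
    if isinstance(tables, MolPercentTable):
        return [tables]
    return list(tables)


def compare_before_after(
    untreated: Union[MolPercentTable, Sequence[MolPercentTable]],
    exchanged: Union[MolPercentTable, Sequence[MolPercentTable]],
) -> Dict[str, SpeciesComparison]:
    """Per-species before/after differences with significance labels.

    With replicated tables (n ≥ 2 per condition) a two-way ANOVA
    (treatment × species) supplies per-species p-values and the star labels;
    with point tables only the differences are returned. Species missing from
    either side are skipped; fully disjoint species sets produce an empty
    result with a warning.
    """
    before = _as_list(untreated)
    after = _as_list(exchanged)
    shared = sorted(
        set.intersection(*(set(t.values) for t in before + after))
    )
    if not shared:
        warnings.warn("no species shared between conditions", UserWarning, stacklevel=2)
        return {}

    def mean_of(tables: List[MolPercentTable], name: str) -> float:
        return float(np.mean([t.values[name] for t in tables]))

    anova: Optional[_stats.AnovaResult] = None
    if len(before) >= 2 and len(after) >= 2:
        rows = []
        for treatment, tables in (("untreated", before), ("exchanged", after)):
            for rep, t in enumerate(tables, start=1):
                for name in shared:
                    rows.append(
                        {
                            "treatment": treatment,
                            "species": name,
                            "replicate": rep,
                            "value": t.values[name],
                        }
                    )
        anova = _stats.two_way_anova(pd.DataFrame(rows))

    out: Dict[str, SpeciesComparison] = {}
    for name in shared:
        delta = mean_of(after, name) - mean_of(before, name)
        if anova is not None:
            out[name] = SpeciesComparison(
                delta,
                anova.species_p[name],
                anova.species_p_adjusted[name],
                anova.star_labels[name],
            )
        else:
            out[name] = SpeciesComparison(delta, None, None, "")
    return out
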