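"""Two-way ANOVA for before/after species-abundance comparisons.

A balanced fixed-effects treatment × species ANOVA supplies the omnibus
tests; per-species follow-up comparisons use each species' own two-cell
pooled variance (df = 2(n−1)) rather than the global mean-square error,
because mol% measurement variance scales strongly with species abundance and
a global MSE would miscalibrate the small species. Šidák correction across
species makes the star labels well-defined.

Star convention: p < 0.01 → "**", p < 0.001 → "***", p < 0.0001 → "****".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["EffectTest", "AnovaResult", "UnbalancedDesignError", "two_way_anova", "star_label"]


class UnbalancedDesignError(ValueError):
    """Design has unequal or singleton cells."""


class EffectTest(NamedTuple):
    F: float
    df: tuple  # (numerator, denominator)
    p: float


@dataclass
class AnovaResult:
    effects: Dict[str, EffectTest]  # "treatment", "species", "interaction"
    species_p: Dict[str, float]
    species_p_adjusted: Dict[str, float]
    star_labels: Dict[str, str]
    n_per_cell: int


def star_label(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    return ""


def _f_test(ss: float, df1: int, ss_err: float, df2: int) -> EffectTest:
    # degenerate inputs: an all-identical table has every SS = 0 -> F = 0, p = 1
    if ss <= 0.0:
        return EffectTest(0.0, (df1, df2), 1.0)
    if ss_err <= 0.0:
        return EffectTest(float("inf"), (df1, df2), 0.0)
    f = (ss / df1) / (ss_err / df2)
    return EffectTest(float(f), (df1, df2), float(sps.f.sf(f, df1, df2)))


def two_way_anova(long_table: pd.DataFrame) -> AnovaResult:
    """Balanced two-way fixed-effects ANOVA with per-species follow-ups.

    ``long_table`` needs columns ``treatment`` (exactly two levels for the
    follow-up contrasts), ``species``, ``replicate``, ``value``; every
    (treatment, species) cell must hold the same number (≥ 2) of replicates.
    Row order is irrelevant.
    """
    required = {"treatment", "species", "value"}
    missing = required - set(long_table.columns)
    if missing:
        raise ValueError(f"long table missing columns: {sorted(missing)}")

    counts = long_table.groupby(["treatment", "species"], sort=True).size()
    treatments = sorted(long_table["treatment"].unique())
    species = sorted(long_table["species"].unique())
    expected_cells = len(treatments) * len(species)
    if len(counts) != expected_cells or counts.nunique() != 1:
        by_n = counts.to_dict()
        bad = min(by_n, key=by_n.get) if by_n else None
        raise UnbalancedDesignError(
            f"design must be balanced with every (treatment, species) cell filled; "
            f"offending cell: {bad}"
        )
    n = int(counts.iloc[0])
    if n < 2:
        raise UnbalancedDesignError("need >= 2 replicates per cell")

    a, b = len(treatments), len(species)
    # cells[i, j, k]: replicate k of treatment i, species j
    cells = np.empty((a, b, n), dtype=float)
    grouped = long_table.groupby(["treatment", "species"], sort=True)["value"]
    t_index = {t: i for i, t in enumerate(treatments)}
    s_index = {s: j for j, s in enumerate(species)}
    for (t, s), vals in grouped:
        cells[t_index[t], s_index[s], :] = np.sort(np.asarray(vals, dtype=float))

    grand = cells.mean()
    mean_t = cells.mean(axis=(1, 2))
    mean_s = cells.mean(axis=(0, 2))
    mean_cell = cells.mean(axis=2)

    ss_a = b * n * float(((mean_t - grand) ** 2).sum())
    ss_b = a * n * float(((mean_s - grand) ** 2).sum())
    ss_ab = n * float(
        ((mean_cell - mean_t[:, None] - mean_s[None, :] + grand) ** 2).sum()
    )
    ss_err = float(((cells - mean_cell[:, :, None]) ** 2).sum())
    df_err = a * b * (n - 1)

    effects = {
        "treatment": _f_test(ss_a, a - 1, ss_err, df_err),
        "species": _f_test(ss_b, b - 1, ss_err, df_err),
        "interaction": _f_test(ss_ab, (a - 1) * (b - 1), ss_err, df_err),
    }

    species_p: Dict[str, float] = {}
    if a == 2:
        df_c = 2 * (n - 1)
        for s in species:
            j = s_index[s]
            x, y = cells[0, j], cells[1, j]
            pooled = (x.var(ddof=1) + y.var(ddof=1)) / 2.0
            diff = y.mean() - x.mean()
            if pooled <= 0.0:
                p = 1.0 if diff == 0.0 else 0.0
            else:
                t = diff / np.sqrt(pooled * 2.0 / n)
                p = float(2.0 * sps.t.sf(abs(t), df_c))
            species_p[s] = p

    m = len(species_p)
    species_p_adj = {
        s: float(1.0 - (1.0 - p) ** m) if p < 1.0 else 1.0
        for s, p in species_p.items()
    }
    stars = {s: star_label(p) for s, p in species_p_adj.items()}
    return AnovaResult(
        effects=effects,
        species_p=species_p,
        species_p_adjusted=species_p_adj,
        star_labels=stars,
        n_per_cell=n,
    )
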