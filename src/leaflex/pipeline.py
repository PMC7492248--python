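"""Seeded pipeline runs: simulate → clean → quantify → mask → reconstruct →
metrics → stats, with CSV intermediates and a machine-readable JSON report.

Identical config + seed gives byte-identical outputs; the report echoes the
full configuration so every run is self-describing.
"""

from __future__ import annotations

import enum
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import metrics as _metrics
from . import reconstruct as _rec
from .io import (
    Denominator,
    MeasuredLipidome,
    SampleRole,
    aggregate_minor_species,
    filter_below_detection,
    read_lipidome_table,
    to_mol_percent,
    write_lipidome_table,
)
from .simulate import (
    NoiseModel,
    default_composition_spec,
    make_ground_truth,
    simulate_experiment_samples,
    simulate_hemolysis_reading,
    simulate_tlc,
    table1_experiments,
)
from .species import CHOLESTEROL, HeadgroupClass

__all__ = ["RunMode", "RunConfig", "run_pipeline", "generate_fixture"]

logger = logging.getLogger("leaflex")

#: Hemolysis-assay control absorbances used by the simulator (DPBS / water).
A_NEG_DEFAULT = 0.10
A_POS_DEFAULT = 1.10


class RunMode(str, enum.Enum):
    SIMULATE = "simulate"
    ANALYZE = "analyze"
    END_TO_END = "end_to_end"


@dataclass
class RunConfig:
    mode: RunMode
    out_dir: Union[str, Path]
    seed: int = 0
    lipidome_table: Optional[Union[str, Path]] = None
    tlc_table: Optional[Union[str, Path]] = None
    absorbance_table: Optional[Union[str, Path]] = None
    noise_cv: float = 0.10
    detection_limit: float = 0.0
    n_replicates: int = 3
    denominator: Denominator = Denominator.WITHIN_CLASS
    minor_threshold: float = 1.0
    aggregate_minor: bool = False

    def __post_init__(self) -> None:
        self.mode = RunMode(self.mode)
        self.denominator = Denominator(self.denominator)
        if self.mode in (RunMode.SIMULATE, RunMode.END_TO_END) and self.seed is None:
            raise ValueError("seed is mandatory in simulate modes")
        if self.mode is RunMode.ANALYZE:
            if self.lipidome_table is None:
                raise ValueError("analyze mode requires a lipidome_table path")
            for p in (self.lipidome_table, self.tlc_table, self.absorbance_table):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(str(p))

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def echo(self) -> dict:
        d = asdict(self)
        d["mode"] = self.mode.value
        d["denominator"] = self.denominator.value
        d["out_dir"] = str(self.out_dir)
        for k in ("lipidome_table", "tlc_table", "absorbance_table"):
            if d[k] is not None:
                d[k] = str(d[k])
        return d


def _simulate_stage(config: RunConfig, out: Path) -> dict:
    truth = make_ground_truth(default_composition_spec(), seed=config.seed)
    noise = NoiseModel(
        cv=config.noise_cv, detection_limit=config.detection_limit, seed=config.seed
    )
    experiments = table1_experiments(truth)

    samples: List[MeasuredLipidome] = []
    tlc_rows = []
    abs_rows = []
    for exp_idx, (name, exp) in enumerate(sorted(experiments.items())):
        samples.extend(
            simulate_experiment_samples(
                truth, exp, noise, n_replicates=config.n_replicates, stream=(exp_idx,)
            )
        )
        untreated = dict(truth.species_amounts())
        untreated[CHOLESTEROL] = truth.cholesterol_amount()
        from .simulate import simulate_exchange  # local import to avoid cycle noise

        cell, _ = simulate_exchange(truth, exp)
        for lane_tag, lipidome in (("before", untreated), ("after", cell)):
            profile = simulate_tlc(lipidome, lane_id=f"{name}_{lane_tag}")
            for cls, inten in sorted(
                profile.band_intensity.items(), key=lambda kv: kv[0].value
            ):
                tlc_rows.append(
                    {
                        "lane_id": profile.lane_id,
                        "experiment": name,
                        "stage": lane_tag,
                        "class": cls.value,
                        "intensity": repr(float(inten)),
                    }
                )
            tlc_rows.append(
                {
                    "lane_id": profile.lane_id,
                    "experiment": name,
                    "stage": lane_tag,
                    "class": "CHOL",
                    "intensity": repr(float(profile.cholesterol_intensity)),
                }
            )
        abs_rows.append(
            {
                "sample_id": name,
                "a_sample": repr(float(
                    simulate_hemolysis_reading(
                        exp.hemolysis_fraction, A_NEG_DEFAULT, A_POS_DEFAULT
                    ))
                ),
                "a_neg": repr(A_NEG_DEFAULT),
                "a_pos": repr(A_POS_DEFAULT),
            }
        )

    lip_path = out / "lipidomes.csv"
    write_lipidome_table(samples, lip_path)
    tlc_path = out / "tlc.csv"
    pd.DataFrame(tlc_rows).to_csv(tlc_path, index=False)
    abs_path = out / "absorbance.csv"
    pd.DataFrame(abs_rows).to_csv(abs_path, index=False)

    truth_rows = [
        {"species": sp.canonical_name, "mol_percent": repr(float(pct))}
        for sp, pct in sorted(
            (
                (sp, truth.within_class_mol_percent("outer")[sp.canonical_name])
                for sp in truth.outer
            ),
            key=lambda kv: kv[0].sort_key(),
        )
    ]
    truth_path = out / "truth_outer_within_class.csv"
    pd.DataFrame(truth_rows).to_csv(truth_path, index=False)

    return {
        "lipidome_table": str(lip_path),
        "tlc_table": str(tlc_path),
        "absorbance_table": str(abs_path),
        "truth_table": str(truth_path),
    }


def _read_tlc_profiles(path: Union[str, Path]) -> Dict[tuple, _metrics.TLCProfile]:
    df = pd.read_csv(path)
    profiles: Dict[tuple, _metrics.TLCProfile] = {}
    for (exp, stage), grp in df.groupby(["experiment", "stage"]):
        bands: Dict[HeadgroupClass, float] = {}
        chol = 0.0
        for _, row in grp.iterrows():
            cls = HeadgroupClass(str(row["class"]))
            if cls is HeadgroupClass.CHOL:
                chol = float(row["intensity"])
            else:
                bands[cls] = float(row["intensity"])
        profiles[(str(exp), str(stage))] = _metrics.TLCProfile(
            lane_id=f"{exp}_{stage}", band_intensity=bands, cholesterol_intensity=chol
        )
    return profiles


def _analyze_stage(config: RunConfig, paths: dict, out: Path) -> dict:
    lipidomes = read_lipidome_table(paths["lipidome_table"])
    cleaned = [filter_below_detection(l, config.detection_limit) for l in lipidomes]

    # per-experiment replicate-averaged supernatant tables, loaded class masked
    supernatants = [l for l in cleaned if l.role is SampleRole.SUPERNATANT]
    by_experiment: Dict[str, List[MeasuredLipidome]] = {}
    for lip in supernatants:
        by_experiment.setdefault(lip.loaded_label or "unknown", []).append(lip)

    exp_tables: List[_rec.ExperimentTable] = []
    for exp_id, lips in sorted(by_experiment.items()):
        masked = [_rec.mask_loaded_lipid(l) for l in lips]
        tables = [to_mol_percent(l, config.denominator) for l in masked]
        # replicate mean per species (species may be censored in some replicates)
        values: Dict[str, List[float]] = {}
        classes = {}
        for t in tables:
            for name, pct in t.values.items():
                values.setdefault(name, []).append(pct)
                classes[name] = t.classes[name]
        mean_table = type(tables[0])(
            denominator=config.denominator,
            values={n: float(np.mean(v)) for n, v in values.items()},
            classes=classes,
            class_totals={},
            sample_id=exp_id,
        )
        if config.aggregate_minor:
            mean_table = aggregate_minor_species(mean_table, config.minor_threshold)
        exp_tables.append(
            _rec.ExperimentTable(
                experiment_id=exp_id,
                loaded_class=lips[0].loaded_class,
                table=mean_table,
            )
        )

    estimate = _rec.reconstruct_outer_leaflet(exp_tables)
    est_path = out / "outer_leaflet_estimate.csv"
    estimate.write_csv(est_path)

    report: dict = {
        "outer_leaflet": {
            name: {"mean": est.mean, "sd": est.sd, "n": est.n}
            for name, est in sorted(estimate.values.items())
        },
        "provenance": {
            cls.value: ids for cls, ids in sorted(estimate.provenance.items())
        },
    }

    # TLC exchange efficiencies
    if paths.get("tlc_table"):
        profiles = _read_tlc_profiles(paths["tlc_table"])
        efficiencies: Dict[str, Dict[str, float]] = {}
        for exp in sorted({k[0] for k in profiles}):
            if (exp, "before") in profiles and (exp, "after") in profiles:
                eff = _metrics.class_efficiencies(
                    profiles[(exp, "before")], profiles[(exp, "after")]
                )
                efficiencies[exp] = {
                    cls.value: v for cls, v in sorted(eff.items(), key=lambda kv: kv[0].value)
                }
        report["exchange_efficiency"] = efficiencies

    # hemolysis
    if paths.get("absorbance_table"):
        df = pd.read_csv(paths["absorbance_table"])
        report["hemolysis_percent"] = {
            str(r.sample_id): _metrics.hemolysis_percent(
                _metrics.HemolysisReading(
                    float(r.a_sample), float(r.a_neg), float(r.a_pos)
                )
            )
            for r in df.itertuples(index=False)
        }

    # before/after comparison on the POPS-exchanged cells (the condition with
    # a delivered inner-leaflet marker), when replicates allow
    cells_by = {
        role: [l for l in cleaned if l.role is role]
        for role in (SampleRole.UNTREATED_CELLS, SampleRole.EXCHANGED_CELLS)
    }
    pops_exchanged = [
        l for l in cells_by[SampleRole.EXCHANGED_CELLS] if l.loaded_label == "POPS"
    ]
    untreated = [
        l for l in cells_by[SampleRole.UNTREATED_CELLS]
        if l.sample_id.startswith("POPS")
    ] or cells_by[SampleRole.UNTREATED_CELLS][: len(pops_exchanged)]
    if len(pops_exchanged) >= 2 and len(untreated) >= 2:
        before_tabs = [to_mol_percent(l, config.denominator) for l in untreated]
        after_tabs = [to_mol_percent(l, config.denominator) for l in pops_exchanged]
        comparison = _rec.compare_before_after(before_tabs, after_tabs)
        report["before_after_pops"] = {
            name: {
                "delta": c.delta,
                "p": c.p_value,
                "p_adjusted": c.p_adjusted,
                "stars": c.stars,
            }
            for name, c in sorted(comparison.items())
        }

    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the JSON report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    report: dict = {"config": config.echo(), "stages": {}}
    try:
        paths = {
            "lipidome_table": config.lipidome_table,
            "tlc_table": config.tlc_table,
            "absorbance_table": config.absorbance_table,
        }
        if config.mode in (RunMode.SIMULATE, RunMode.END_TO_END):
            t0 = time.perf_counter()
            logger.info("stage simulate: seed=%d", config.seed)
            try:
                paths = _simulate_stage(config, out)
            except Exception:
                logger.exception("stage simulate failed")
                raise RuntimeError("pipeline stage 'simulate' failed") from None
            logger.info("stage simulate done in %.3fs", time.perf_counter() - t0)
            report["stages"]["simulate"] = dict(paths)
        if config.mode in (RunMode.ANALYZE, RunMode.END_TO_END):
            t0 = time.perf_counter()
            logger.info("stage analyze")
            try:
                report.update(_analyze_stage(config, paths, out))
            except Exception:
                logger.exception("stage analyze failed")
                raise RuntimeError("pipeline stage 'analyze' failed") from None
            logger.info("stage analyze done in %.3fs", time.perf_counter() - t0)
            report["stages"]["analyze"] = {"done": True}

        report_path = out / "report.json"
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
            fh.write("\n")
        logger.info("report written to %s", report_path)
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()


def generate_fixture(out_dir: Union[str, Path], seed: int = 0) -> dict:
    """Write the three-experiment synthetic dataset used by tests and docs."""
    config = RunConfig(mode=RunMode.SIMULATE, out_dir=out_dir, seed=seed)
    return run_pipeline(config)["stages"]["simulate"]
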