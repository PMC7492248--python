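import math

import numpy as np
import pytest

from leaflex import (
    NoiseModel,
    simulate_experiment_samples,
)
from leaflex.io import (
    Denominator,
    LipidEntry,
    MeasuredLipidome,
    MolPercentTable,
    SampleRole,
    to_mol_percent,
)
from leaflex.reconstruct import (
    ExperimentTable,
    UnobservableClassError,
    compare_before_after,
    mask_loaded_lipid,
    reconstruct_outer_leaflet,
)
from leaflex.species import HeadgroupClass, parse_species_name as _sp

SM, PC, PS, PE = (
    HeadgroupClass.SM,
    HeadgroupClass.PC,
    HeadgroupClass.PS,
    HeadgroupClass.PE,
)


def _table(values, denominator=Denominator.WITHIN_CLASS, sample_id=""):
    classes = {n: _sp(n).headgroup_class for n in values}
    return MolPercentTable(denominator, dict(values), classes, {}, sample_id)


def _lip(entries, loaded_class, sample_id="s"):
    return MeasuredLipidome(
        sample_id=sample_id,
        role=SampleRole.SUPERNATANT,
        entries={_sp(k): LipidEntry(v) for k, v in entries.items()},
        loaded_class=loaded_class,
        loaded_label=loaded_class.value,
    )


def test_mask_removes_entire_loaded_class():
    lip = _lip({"SM 34:1": 1.0, "SM 42:2": 2.0, "PC 34:1": 3.0, "PS 34:1": 4.0}, SM)
    masked = mask_loaded_lipid(lip)
    assert all(sp.headgroup_class is not SM for sp in masked.entries)
    assert len(masked.entries) == 2

    # no entries of the loaded class -> identity
    lip2 = _lip({"SM 34:1": 1.0, "PS 34:1": 4.0}, PC)
    assert mask_loaded_lipid(lip2).entries == lip2.entries

    with pytest.raises(ValueError, match="loaded"):
        mask_loaded_lipid(
            MeasuredLipidome("x", SampleRole.SUPERNATANT, {}, loaded_class=None)
        )


def test_mask_count_bookkeeping():
    rng = np.random.default_rng(3)
    for _ in range(20):
        classes = [SM, PC, PS, PE]
        entries = {}
        for cls in classes:
            for d in range(rng.integers(1, 5)):
                entries[f"{cls.value} 34:{d}"] = float(rng.uniform(0.1, 5))
        loaded = classes[rng.integers(0, len(classes))]
        lip = _lip(entries, loaded)
        n_loaded = sum(1 for n in entries if _sp(n).headgroup_class is loaded)
        assert len(mask_loaded_lipid(lip).entries) == len(entries) - n_loaded


def test_hand_average_two_experiments():
    popc = _table({"SM 34:1": 50.0, "PS 38:4": 60.0}, sample_id="POPC")
    pops = _table({"SM 34:1": 54.0}, sample_id="POPS")
    bsm = _table({"PS 38:4": 62.0}, sample_id="bSM")
    est = reconstruct_outer_leaflet(
        [
            ExperimentTable("POPC", PC, popc),
            ExperimentTable("POPS", PS, pops),
            ExperimentTable("bSM", SM, bsm),
        ]
    )
    sm = est.values["SM 34:1"]
    assert sm.mean == pytest.approx(52.0)
    assert sm.n == 2
    assert sm.sd == pytest.approx(np.std([50.0, 54.0], ddof=1))
    assert est.provenance[SM] == ["POPC", "POPS"]
    # species observed once (censored elsewhere) keeps n = 1 with undefined SD
    ps = est.values["PS 38:4"]
    assert ps.n == 2 and ps.mean == pytest.approx(61.0)


def test_exact_agreement_gives_zero_sd():
    t = {"SM 34:1": 40.0, "SM 42:2": 35.0, "SM 42:1": 25.0}
    est = reconstruct_outer_leaflet(
        [
            ExperimentTable("e1", PC, _table(t)),
            ExperimentTable("e2", PS, _table(t)),
        ]
    )
    for name, e in est.values.items():
        assert e.mean == t[name]
        assert e.sd == 0.0


def test_unobservable_class_errors():
    # SM species appear only in the experiment that itself loaded SM
    with pytest.raises(UnobservableClassError, match="SM"):
        reconstruct_outer_leaflet(
            [
                ExperimentTable("e1", SM, _table({"SM 34:1": 1.0, "PC 34:1": 99.0})),
                ExperimentTable("e2", PC, _table({"PS 34:1": 100.0})),
            ]
        )
    with pytest.raises(ValueError, match="distinct"):
        reconstruct_outer_leaflet(
            [ExperimentTable("e1", SM, _table({"PC 34:1": 100.0}))]
        )


from oracles import brute_force_reconstruct  # noqa: E402


def test_matches_brute_force_oracle_on_random_inputs():
    rng = np.random.default_rng(17)
    classes = [SM, PC, PS, PE]
    for _ in range(50):
        n_exp = int(rng.integers(2, 5))
        loaded = list(rng.choice(len(classes), size=n_exp))
        if len(set(loaded)) < 2:
            loaded[0] = (loaded[1] + 1) % len(classes)
        experiments = []
        for i, li in enumerate(loaded):
            values = {}
            for cls in classes:
                if cls is classes[li]:
                    continue
                for d in range(int(rng.integers(1, 4))):
                    if rng.random() < 0.8:
                        values[f"{cls.value} 34:{d}"] = float(rng.uniform(0, 100))
            if not values:
                values = {"LPC 16:0": 100.0}
            experiments.append(
                ExperimentTable(f"e{i}", classes[li], _table(values))
            )
        est = reconstruct_outer_leaflet(experiments)
        oracle = brute_force_reconstruct(experiments)
        assert set(est.values) == set(oracle)
        for n, (mean, sd, cnt) in oracle.items():
            got = est.values[n]
            assert got.mean == mean
            assert got.n == cnt
            assert (math.isnan(got.sd) and math.isnan(sd)) or got.sd == pytest.approx(
                sd, abs=1e-12
            )
        # provenance never includes a class's own loading experiment
        for cls, ids in est.provenance.items():
            for e in experiments:
                if e.loaded_class is cls:
                    assert e.experiment_id not in ids


def test_compare_identical_tables_all_zero():
    t = _table({"PC 34:1": 60.0, "PC 34:2": 40.0})
    out = compare_before_after(t, t)
    assert all(c.delta == 0.0 for c in out.values())
    assert all(c.p_value is None for c in out.values())


def test_compare_disjoint_species_warns_empty():
    with pytest.warns(UserWarning, match="no species shared"):
        out = compare_before_after(
            _table({"PC 34:1": 100.0}), _table({"SM 34:1": 100.0})
        )
    assert out == {}


def test_pops_delivery_flags_ps_increase_and_pe_null(truth, experiments):
    """POPS loading raises PS 34:1 significantly; PE species stay null."""
    noise = NoiseModel(cv=0.05, detection_limit=0.0, seed=23)
    samples = simulate_experiment_samples(
        truth, experiments["POPS"], noise, n_replicates=3
    )
    before = [
        to_mol_percent(s, Denominator.WITHIN_CLASS)
        for s in samples
        if s.role is SampleRole.UNTREATED_CELLS
    ]
    after = [
        to_mol_percent(s, Denominator.WITHIN_CLASS)
        for s in samples
        if s.role is SampleRole.EXCHANGED_CELLS
    ]
    out = compare_before_after(before, after)
    ps = out["PS 34:1"]
    assert ps.delta > 0
    assert ps.stars in ("**", "***", "****")
    pe_names = [n for n in out if n.startswith("PE ")]
    assert pe_names
    assert all(out[n].stars == "" for n in pe_names)
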