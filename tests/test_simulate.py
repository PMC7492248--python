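import numpy as np
import pytest

from leaflex import (
    CHOLESTEROL,
    CompositionConstraints,
    ExchangeExperimentConfig,
    HeadgroupClass,
    InfeasibleCompositionError,
    NoiseModel,
    default_composition_spec,
    make_ground_truth,
    simulate_exchange,
    simulate_hemolysis_reading,
    simulate_ms_measurement,
    simulate_tlc,
)
from leaflex.metrics import InvalidControlError
from leaflex.species import parse_species_name as _sp


@pytest.mark.parametrize("seed", [0, 1, 7, 123])
def test_ground_truth_satisfies_asymmetry_constraints(seed):
    t = make_ground_truth(seed=seed)
    outer = t.class_totals("outer")
    inner = t.class_totals("inner")
    assert outer[HeadgroupClass.SM] + outer[HeadgroupClass.PC] >= 0.85
    assert inner[HeadgroupClass.PE] >= 0.45
    assert inner[HeadgroupClass.PS] >= 0.25
    # >= 90% of all SM and ~60% of all PC sit in the outer leaflet
    def alloc(cls):
        o = t.outer_share * outer.get(cls, 0.0)
        i = (1 - t.outer_share) * inner.get(cls, 0.0)
        return o / (o + i)
    assert alloc(HeadgroupClass.SM) >= 0.90
    assert 0.55 <= alloc(HeadgroupClass.PC) <= 0.65
    # outer-leaflet SM abundance order and PC leaders
    by_name = {sp.canonical_name: f for sp, f in t.outer.items()}
    assert by_name["SM 34:1"] > by_name["SM 42:2"] > by_name["SM 42:1"]
    pcs = sorted(
        (f, sp.canonical_name)
        for sp, f in t.outer.items()
        if sp.headgroup_class is HeadgroupClass.PC
    )
    assert {pcs[-1][1], pcs[-2][1]} == {"PC 34:1", "PC 34:2"}


def test_infeasible_constraints_raise_with_listing():
    spec = default_composition_spec()
    spec.class_fractions[HeadgroupClass.PS] = 0.10
    spec.class_fractions[HeadgroupClass.PE] = 0.34
    constraints = CompositionConstraints(
        min_outer_share={HeadgroupClass.PS: 0.5},
        min_inner_share={HeadgroupClass.PS: 0.25},
    )
    with pytest.raises(InfeasibleCompositionError, match="outer PS share"):
        make_ground_truth(spec, seed=0, constraints=constraints)


def _pops_config(truth, h=0.0, **kw):
    return ExchangeExperimentConfig(
        name="POPS",
        loaded={_sp("PS 34:1"): 1.0},
        efficiency={
            sp: (0.0 if sp.headgroup_class is HeadgroupClass.PE else 0.5)
            for sp in truth.outer
        },
        hemolysis_fraction=h,
        **kw,
    )


def test_exchange_pops_no_hemolysis_supernatant_contents(truth):
    cell, sup = simulate_exchange(truth, _pops_config(truth, h=0.0))
    classes = {sp.headgroup_class for sp in sup}
    assert HeadgroupClass.SM in classes and HeadgroupClass.PC in classes
    assert HeadgroupClass.PE not in classes
    assert CHOLESTEROL not in sup
    assert sup[_sp("PS 34:1")] > 0  # excess loaded lipid


def test_hemolysis_contaminates_supernatant_with_inner_markers(truth):
    h = 0.03
    exp = ExchangeExperimentConfig(
        name="SM35",
        loaded={_sp("SM 35:1"): 1.0},
        efficiency={
            sp: (0.0 if sp.headgroup_class in (HeadgroupClass.PE, HeadgroupClass.PS) else 0.5)
            for sp in truth.outer
        },
        hemolysis_fraction=h,
    )
    _, sup = simulate_exchange(truth, exp)
    total_ps = sum(
        a for sp, a in truth.species_amounts().items()
        if sp.headgroup_class is HeadgroupClass.PS
    )
    sup_ps = sum(
        a for sp, a in sup.items() if sp.headgroup_class is HeadgroupClass.PS
    )
    assert sup_ps == pytest.approx(h * total_ps, rel=1e-12)
    assert sup[CHOLESTEROL] == pytest.approx(h * truth.cholesterol_amount(), rel=1e-12)


def test_no_exchange_identity(truth):
    exp = ExchangeExperimentConfig(
        name="null",
        loaded={_sp("PS 34:1"): 1.0},
        default_efficiency=0.0,
        hemolysis_fraction=0.0,
    )
    cell, sup = simulate_exchange(truth, exp)
    untreated = truth.species_amounts()
    for sp, amt in untreated.items():
        assert cell[sp] == pytest.approx(amt, rel=1e-12)
    # loaded excess would need delivery; nothing delivered, so supernatant empty
    assert sup == {}


@pytest.mark.parametrize("h", [0.0, 0.01, 0.1])
@pytest.mark.parametrize("e", [0.2, 1.0])
def test_mole_conservation(truth, h, e):
    exp = ExchangeExperimentConfig(
        name="c",
        loaded={_sp("PC 34:1"): 1.0},
        default_efficiency=e,
        hemolysis_fraction=h,
        delivered_excess_factor=2.0,
    )
    cell, sup = simulate_exchange(truth, exp)
    surv = 1.0 - h
    delivered = sum(
        exp.efficiency_for(sp) * truth.outer_share * f * surv
        for sp, f in truth.outer.items()
    )
    phospho = lambda d: sum(
        a for sp, a in d.items() if sp.headgroup_class is not HeadgroupClass.CHOL
    )
    total_after = phospho(cell) + phospho(sup)
    expected = 1.0 + (1.0 + exp.delivered_excess_factor) * delivered
    assert total_after == pytest.approx(expected, abs=1e-9)
    chol_after = cell.get(CHOLESTEROL, 0.0) + sup.get(CHOLESTEROL, 0.0)
    assert chol_after == pytest.approx(truth.cholesterol_amount(), abs=1e-9)


def test_supernatant_inner_markers_increase_with_h(truth):
    # loading must not itself be an inner-leaflet marker, else the shrinking
    # excess of loaded lipid confounds the contamination signal
    def ps_pe(h):
        exp = ExchangeExperimentConfig(
            name="POPC",
            loaded={_sp("PC 34:1"): 1.0},
            efficiency={
                sp: (0.0 if sp.headgroup_class is HeadgroupClass.PE else 0.5)
                for sp in truth.outer
            },
            hemolysis_fraction=h,
        )
        _, sup = simulate_exchange(truth, exp)
        return sum(
            a for sp, a in sup.items()
            if sp.headgroup_class in (HeadgroupClass.PE, HeadgroupClass.PS)
        )
    amounts = [ps_pe(h) for h in (0.0, 0.005, 0.02, 0.1, 0.5)]
    assert all(b > a for a, b in zip(amounts, amounts[1:]))


def test_ms_noiseless_identity_and_censoring(truth):
    lipidome = {_sp("PC 34:1"): 0.5, _sp("SM 34:1"): 2.0}
    out = simulate_ms_measurement(
        lipidome, NoiseModel(cv=0.0, detection_limit=0.0, seed=0)
    )
    assert {sp: e.abundance for sp, e in out.entries.items()} == lipidome
    assert not any(e.censored for e in out.entries.values())

    censored = simulate_ms_measurement(
        lipidome, NoiseModel(cv=0.0, detection_limit=1.0, seed=0)
    )
    assert censored.entries[_sp("PC 34:1")].censored
    assert not censored.entries[_sp("SM 34:1")].censored


def test_ms_noise_magnitude_matches_cv():
    noise = NoiseModel(cv=0.1, detection_limit=0.0, seed=42)
    draws = np.array(
        [
            simulate_ms_measurement({_sp("PC 34:1"): 1.0}, noise, stream=(i,))
            .entries[_sp("PC 34:1")]
            .abundance
            for i in range(10_000)
        ]
    )
    sample_cv = draws.std(ddof=1) / draws.mean()
    assert abs(sample_cv - 0.1) / 0.1 < 0.10
    assert draws.mean() == pytest.approx(1.0, abs=0.01)


def test_ms_seeded_reproducibility(truth):
    noise = NoiseModel(cv=0.2, detection_limit=0.0, seed=7)
    lipidome = truth.species_amounts()
    a = simulate_ms_measurement(lipidome, noise, stream=(3,))
    b = simulate_ms_measurement(lipidome, noise, stream=(3,))
    assert a.entries == b.entries


def test_tlc_band_arithmetic():
    pc1, pc2, sm = _sp("PC 34:1"), _sp("PC 34:2"), _sp("SM 34:1")
    prof = simulate_tlc({pc1: 1.0, pc2: 2.0})
    assert prof.band_intensity[HeadgroupClass.PC] == 3.0
    assert HeadgroupClass.SM not in prof.band_intensity

    gains = {HeadgroupClass.PC: 2.0, HeadgroupClass.SM: 1.0}
    prof = simulate_tlc({pc1: 1.0, sm: 2.0}, gains=gains)
    assert prof.band_intensity[HeadgroupClass.PC] == 2.0
    assert prof.band_intensity[HeadgroupClass.SM] == 2.0

    with_chol = simulate_tlc({pc1: 1.0, CHOLESTEROL: 4.0})
    assert with_chol.cholesterol_intensity == 4.0


def test_hemolysis_reading_endpoints_and_validation():
    assert simulate_hemolysis_reading(0.0, 0.10, 1.10) == 0.10
    assert simulate_hemolysis_reading(1.0, 0.10, 1.10) == 1.10
    assert simulate_hemolysis_reading(0.022, 0.10, 1.10) == pytest.approx(0.122)
    with pytest.raises(InvalidControlError):
        simulate_hemolysis_reading(0.5, 1.0, 0.5)


def test_config_validation():
    with pytest.raises(ValueError):
        ExchangeExperimentConfig(
            name="bad", loaded={_sp("PC 34:1"): 1.0}, hemolysis_fraction=1.5
        )
    with pytest.raises(ValueError):
        ExchangeExperimentConfig(
            name="bad", loaded={_sp("PC 34:1"): 1.0}, loaded_lipid_mM=-1.0
        )
    with pytest.raises(ValueError):
        ExchangeExperimentConfig(name="bad", loaded={})
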