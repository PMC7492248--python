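# Methods

## Data model

Lipid species are identified at sum-composition level by the shotgun-lipidomics
shorthand `CLASS C:D` (headgroup class, total acyl carbons, total double
bonds). Chain-resolved names (`PE(20:0/20:0)`, `PC 16:0/18:1`) are collapsed to
totals on parsing; unknown class tokens either error (strict mode) or map to a
catch-all `OTHER` class while retaining the original token. Cholesterol is a
chain-less special species held outside the phospholipid maps everywhere: it is
never part of a mol% denominator and its leaflet distribution is not modelled.

A ground-truth membrane (`LeafletComposition`) consists of two within-leaflet
normalised species maps, the fraction of total phospholipid in the outer
leaflet (`outer_share`), and the cholesterol fraction of all membrane lipids.
`outer_share` is what makes whole-membrane amounts, and hence the hemolysis
contamination term, well defined from the two leaflet-normalised maps.

## Ground-truth generator

`make_ground_truth` realises a membrane from a declarative recipe: class
shares of total phospholipid, per-class outer-leaflet allocations, and
within-class species weights (shared by both leaflets). The defaults encode
the accepted RBC asymmetry picture and the reported species rank orders:

| quantity | default | why |
|---|---|---|
| class shares PC/SM/PE/PS/PI/LPC | 0.29/0.25/0.29/0.15/0.015/0.005 | typical human RBC phospholipid panel |
| outer allocation SM / PC | 0.90 / 0.60 | ~90% of SM and ~60% of PC are outer-leaflet |
| outer allocation PE / PS | 0.04 / 0.005 | PE and PS are inner-leaflet markers |
| cholesterol fraction | 0.40 | cholesterol ≈ 40% of RBC membrane lipids |
| top SM species | SM 34:1 > SM 42:2 > SM 42:1 | reported outer-leaflet SM order |
| top PC species | PC 34:1, PC 34:2 | reported PC leaders |
| species-weight jitter CV | 0.02 | distinct seeds give distinct membranes without breaking the rank orders |

The realised composition is checked against an explicit constraint set (outer
SM+PC ≥ 85% of outer phospholipid, SM allocation ≥ 0.90, PC allocation in
[0.55, 0.65], inner PE ≥ 45% and PS ≥ 25%, the rank orders above); any
violation raises an error listing every failed constraint, so a user-supplied
recipe that contradicts its own constraints fails loudly rather than silently
producing an unrepresentative membrane. Comparisons carry a 1e-9 slack because
several constraints are met with exact equality by construction.

Species weights are identical in both leaflets per class. This is a deliberate
simplification: the method estimates within-class profiles, and no
species-resolved per-leaflet reference exists to calibrate a difference. It
also means hemolysis contamination cannot bias within-class profiles in the
simulator (see limitations).

## Exchange model

On a total-phospholipid = 1 basis, with hemolysis fraction `h`, survivors
`1 − h`:

1. The lysed sub-population spills its entire pre-exchange membrane — both
   leaflets plus cholesterol — into the supernatant (`h ×` whole membrane).
2. Each outer-leaflet species `s` of the surviving cells loses a fraction
   `e_s ∈ [0, 1]` to the supernatant; the extracted moles are replaced
   one-for-one by the loaded lipid (mole-for-mole replacement keeps the outer
   leaflet at constant size — the stoichiometry is not otherwise constrained
   by observation).
3. The supernatant additionally carries `delivered_excess_factor ×` the
   delivered amount of un-delivered loaded lipid (default 3; only the sign of
   this excess is observationally constrained, not its size).

Consequences used as oracles: inner-leaflet lipids and cholesterol appear in
the supernatant only through term 1 (at `h = 0` the supernatant is
cholesterol-free and PS-free unless PS was loaded); supernatant PS+PE is
strictly increasing in `h`; total moles are conserved up to the loaded-lipid
influx.

`efficiency` values are fractions of the *outer-leaflet* pool. The TLC
statistic measures whole-cell class removal, which equals `e ×` (outer
allocation); the optimized-condition presets use class efficiencies 0.525 (PC)
and 0.475 (SM) — midpoints of the observed TLC ranges — applied to the outer
pool, 0.5 for other accessible classes, and 0 for PE, which sits almost
entirely in the inner leaflet and shows no band change across the exchange.
The presets also carry the optimized wet conditions (MαCD 20 mM, 1 h; bSM at
15% hematocrit / 0.375 mM with 2.2% hemolysis; POPC at 5% / 0.375 mM, 0.9%;
POPS at 5% / 0.750 mM, 1.5%). Brain SM is modelled as a five-species SM
mixture dominated by the stearoyl species (SM 36:1).

## Observation models

**MS readout.** Each amount is multiplied by an independent mean-one
log-normal factor with configured CV (σ² = ln(1 + CV²), μ = −σ²/2); values
below the detection limit are flagged censored and later removed (not
zero-filled or imputed — removal is the documented practice for these
exports). CV = 0 is the exact identity, which the noiseless oracle tests rely
on. Species are visited in canonical order so a given (seed, stream) is
bit-reproducible; replicate and sample indices extend the seed sequence rather
than perturbing values ad hoc.

**TLC.** One band per class = per-class gain × class mole sum, cholesterol
band from the cholesterol pool, optional mean-one log-normal band noise. This
emulates densitometry of charred plates at the class level only — TLC does not
resolve species.

**Hemolysis.** Absorbance at 541 nm is linear in the lysed fraction between
the negative (DPBS) and positive (water) controls. The quantifier inverts that
interpolation; the subtraction convention is a declared choice (the assay
description fixes the controls but not the spreadsheet arithmetic). The round
trip recovers `100·h` exactly when the baseline subtraction is
floating-point-exact (e.g. `A_neg = 0`), and to ~1 ulp otherwise.

## Mol% bookkeeping

Two denominators are supported: within each headgroup class (default, matching
how species panels are presented per class) and over all phospholipids.
Cholesterol is excluded from both. Class totals are always computed by
summation over species. Minor species below a threshold (default 1%) can be
pooled into one "other ⟨CLASS⟩s" bucket per class, preserving totals exactly.
The abundance column is assumed already quantitative (internal-standard
conversion and response-factor calibration happen upstream of this package).

## Reconstruction

The loaded lipid's entire headgroup class is masked in its own experiment —
not just the loaded species — because a natural mixture like brain SM spans
many species of its class, and class-level masking is what makes the
cross-experiment average well-posed. Averaging operates on within-class mol%
tables (experiments differ in total lipid, so raw abundances are not
comparable) with an unweighted arithmetic mean across experiments; replicates
are averaged within an experiment first. A species censored out of one
contributing experiment keeps an estimate with reduced `n` (n = 1 estimates
carry an undefined SD) rather than being silently dropped. Provenance is
recorded per class and, by construction, never includes the class's own
loading experiment. A class whose species appear only in its own loading
experiments is reported as unobservable by an explicit error.

With uniform within-class efficiencies and no noise, the supernatant
within-class mol% equals the outer-leaflet within-class mol% identically, so
the pipeline is exact in the noiseless limit; this is tested at 1e-9.

## Statistics

The omnibus two-way ANOVA (treatment × species, balanced, fixed effects) is
computed from the standard sums-of-squares decomposition; an all-identical
table yields F = 0 / p = 1 by the degenerate-input convention. Per-species
follow-up comparisons use each species' own two-cell pooled variance with
2(n−1) df rather than the global mean-square error: mol% measurement variance
scales roughly with the squared species mean, so a global MSE would
anti-conservatively test abundant species and over-conservatively test rare
ones. Šidák correction across species makes the star labels well-defined
(`**` < 0.01, `***` < 0.001, `****` < 0.0001, on the corrected p). The raw
per-species p-values are also reported; the null-simulation calibration
checks that their 5%-level rejection rate is binomially consistent with 0.05.
Unbalanced or singleton cells are rejected with the offending cell named —
the balanced three-replicate design keeps the sums of squares unambiguous.

## Validation study sizes

The packaged validation runs use: 100 seeded parameter-recovery runs at
CV = 0.10 with three replicates per experiment and the per-condition hemolysis
fractions (≤ 2.2%); 100 seeds for the TLC efficiency estimator at 5% band
noise; 1000 randomized experiment sets for the masking/oracle equivalence;
and 1000 (tests) / 400 (acceptance script) null ANOVA simulations. These sizes
put the Monte-Carlo standard errors well inside the asserted tolerances while
keeping the whole suite in the tens of seconds.

## Limitations

- The simulator does not model complexation kinetics, vesicle physics,
  flip-flop, or cholesterol leaflet distribution; efficiencies are free
  parameters, not predictions.
- Identical within-class species weights across leaflets mean the recovery
  tests cannot detect biases that would arise if the inner leaflet had a
  different species profile within a class; real hemolysis contamination
  could then distort the reconstruction in ways the synthetic study does not
  exercise.
- Log-normal, class-independent MS noise with a hard detection threshold is a
  simplification of real shotgun-lipidomics error structure (no ionisation
  suppression, isotope overlap, or class-correlated drift).
- The delivered-excess factor is unidentified by the available observations;
  it only needs to be large enough to make the loaded class unquantifiable,
  which is why that class is masked rather than corrected.
- Passing parameter recovery on this simulator shows the *analysis* is
  faithful and calibrated under the stated error model; it does not validate
  the wet-lab assumptions (outer-leaflet-only extraction, membrane integrity)
  on real cells.
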