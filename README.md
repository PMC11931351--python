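# nsdquant

Compartment-specific quantification of nucleotide sugar donors (NSDs) —
the activated sugars (UDP-Gal, UDP-GlcNAc, GDP-Man, GDP-Fuc, CMP-Sia, …)
that glycosyltransferases consume while building antibody N-glycans.
NSDs are synthesized in the cytoplasm (CP) but consumed inside the Golgi
apparatus (GA), so whole-cell metabolomics hides exactly the pools that
control glycosylation.  `nsdquant` implements, as a tested and fully
simulatable pipeline, the quantitative workflow behind digitonin-based
subcellular fractionation with standard-addition LC-MS/MS readout:

1. **Permeabilization design.**  Digitonin perforates the cholesterol-rich
   plasma membrane first, releasing cytoplasmic contents into the
   supernatant.  The normalized release curve is fitted with a
   four-parameter logistic

   *y(x) = a + b / (1 + exp((c − x)/d))*

   (floor *a*, span *b*, midpoint *c*, steepness *d*; *x* = digitonin in
   µg/mL).  Literature estimates of relative compartment content
   (*nᵢ = cᵢ·Vᵢ*, shares *rᵢ = nᵢ/Σn*) give the cytoplasmic share of the
   total pool; inverting the curve at that share and rounding **down**
   onto the available concentration grid yields the working digitonin
   concentration that captures the cytoplasm while sparing the organelles.
2. **Quantification.**  Standard addition (peak area regressed on spiked
   concentration, native level = x-intercept magnitude) cancels matrix
   effects; the vial concentration is back-calculated through the dilution
   chain (transfer fractions, reconstitutions) and divided by the cell
   count to give amol/cell, with method-detection-limit flags.
3. **QC.**  Atkinson energy charge EC = (NTP + ½·NDP)/(NTP+NDP+NMP) and
   the triphosphate fraction diagnose degradation during sample
   concentration; a Q10 budget (*t_cold = t_warm · 2^(ΔT/10)*) converts
   warm-temperature processing times into the cold-processing time budget.
4. **Glycans.**  HILIC retention times are normalized to glucose units
   against a dextran ladder, assigned to library species, and summarized
   by the galactosylation index
   *I_G = 100·(2·FA2G2 + FA2G1) / (2·(FA2 + FA2G1 + FA2G2))*.
5. **Synthetic data.**  A first-class generator produces every input the
   pipeline consumes — two-compartment pools, sigmoidal release
   titrations, standard-addition sets, nucleotide degradation, nutrient
   pulse time courses and donor-coupled glycan profiles — so every stage
   is testable end to end without instrument data.

Intended users: bioprocess and analytical scientists modelling or
optimizing glycosylation in production cell lines, and method developers
who need a reference implementation of the fractionation arithmetic.

## Worked example

```python
from nsdquant import run_pipeline

report = run_pipeline(seed=42)   # triplicates, 10 % CV, defaults throughout
d = report.design
print(f"operating digitonin: {d.selected_ug_per_ml:g} ug/mL "
      f"(exact solve {d.exact_solve_ug_per_ml:.1f})")
print(f"EC preservation: {report.qc_summary['ec_preservation_pct']:.1f} %")
print(report.ratio_table.round(2).to_string(index=False))
```

prints

```
operating digitonin: 300 ug/mL (exact solve 327.2)
EC preservation (evaporation vs lyophilization): 63.0 %
          analyte  ga_cp_ratio  true_ga_cp_ratio
      UDP-Glc/Gal        16.44             17.91
UDP-GlcNAc/GalNAc        11.86             12.51
          CMP-Sia         3.34              3.61
          GDP-Fuc         4.19              4.82
          GDP-Man         4.58              4.06
```

The quantification stage recovers the generator's hidden GA:CP ratios to
within the standard-addition noise, and the energy-charge comparison shows
the harsher evaporation branch preserving 63 % of the lyophilized
reference.  (The simulated titration's design point lands at 300 µg/mL
because the simulated supernatant curve includes the late organelle-leak
component; the classical release-curve workflow on a pure cytoplasmic
release curve — as in `scripts/acceptance.py` — selects 50 µg/mL.)

Glycan output for the three nutrient-pulse strategies (A: medium only,
B: +Mn/uridine/fructose, C: +Mn/uridine/galactose — the direct UDP-Gal
precursor):

```
condition  udp_gal_exposure_fmol_h  galactosylation_index_pct
        A                    110.1                       68.2
        B                    120.1                       74.7
        C                    165.4                       87.6
```

Galactose feeding (C) maximizes Golgi UDP-Glc/Gal availability and
therefore *I_G*.

A CLI mirrors the stages (`nsdquant simulate | design | quantify | qc |
glycans | run-all`); `nsdquant run-all --seed 42 --out-dir out/` writes
every intermediate CSV plus a manifest with the config hash and seed.

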