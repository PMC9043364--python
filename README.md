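# cwbind

Analysis toolkit for the biophysical characterisation of CW-domain histone
readers binding methylated H3K4 peptides.  CW domains select among mono-,
di- and tri-methylated lysine 4 of the histone H3 tail; quantifying that
selectivity takes four measurements that this package models end to end:

- **ITC binding thermodynamics** — single-site ("independent") isotherm
  fitting of per-injection heats for (K_d, ΔH, n), with
  ΔG = RT ln K_d, TΔS = ΔH − ΔG, and pooled Student's t-tests between
  replicate groups.
- **Thermal denaturation** — I328/I352 fluorescence-ratio melting curves
  fitted with the four-parameter logistic
  f(x) = y₀ + a/(1 + e^(−b(x−x₀))), T_m = x₀, with a sigmoidality gate
  that refuses to report a T_m for transition-free data, and one-way ANOVA
  across groups.
- **NMR fingerprints and dynamics** — combined chemical-shift perturbations
  Δppm = √(Δδ_HN² + (α_N·Δδ_N)²) with α_N = 0.17, unassigned-fingerprint
  pairing with a shifted-fraction summary, steady-state ¹H→¹⁵N NOE ratios
  with mobility classification, and mono-exponential T1/T2 fits.
- **Pocket geometry** — total-least-squares planes through the nine indole
  ring atoms of binding-pocket tryptophans in PDB structures and the angle
  between them (unsigned and deterministically oriented conventions).

A synthetic-data module generates every input class with controlled ground
truth (titrations, melts, fingerprints, relaxation series, designed ring
pairs), so the full pipeline is testable offline.

## Layout

Library code lives in `src/cwbind/` (`thermo`, `melt`, `csp`, `relax`,
`geometry`, `synth`, `io`, `cli`); the numbered scripts in `analysis/`
re-run the study's analyses and write tables under `results/`; the
`cwbind` console command exposes each stage
(`simulate`, `itc-fit`, `melt-fit`, `csp`, `hetnoe`, `relax-fit`,
`pocket-angle`).

## Worked example

Simulate a wild-type + H3K4me1 titration (K_d = 1.3 µM, ΔH = −89 kJ/mol,
n = 1; 22 × 2 µl of 800 µM peptide into 80 µM protein at 25 °C) with 0.5 µJ
heat noise, subtract its dilution blank, and refit:

```bash
cwbind simulate isotherm --out demo --seed 5 --noise 0.5
cwbind itc-fit --input demo/heats.tsv --blank demo/blank.tsv --out demo/fit.tsv
# Kd = 1.3 uM, dH = -89 kJ/mol, n = 0.997 (c = 61.3, converged=True)
```

`demo/fit.tsv` then carries the derived state functions — for this fit
ΔG = −33.6 kJ/mol, TΔS = −55.5 kJ/mol, ΔS = −186.0 J/(mol·K) — and
`demo/fit_residuals.tsv` the per-injection residuals.  The same
round trip from the library:

```python
from cwbind import thermo, synth

truth = thermo.ThermodynamicParameters(Kd=1.3e-6, dH=-89.0, n=1.0)
sample, blank = synth.gen_isotherm(truth, noise_sigma=0.0, seed=0)
fit = thermo.fit_independent_model(thermo.subtract_blank(sample, blank))
print(fit.params.Kd * 1e6, fit.params.dH)   # 1.3000... -89.000...
```

Running `python analysis/02_itc_thermodynamics.py` reproduces the full
seven-system table (wild type and two loop/helix mutants × three
methylation states), e.g.:

```
   system  Kd_fit_uM  dH_fit_kJ_mol  dS_J_mol_K
   WT:me1       1.30         -89.00     -185.83
   WT:me3      14.20         -60.00     -108.44
L919A:me1      12.20         -77.00     -164.19
```

Enthalpy dominates throughout; the entropic penalty shrinks from me1 to
me3 while affinity weakens an order of magnitude — the enthalpy–entropy
trade-off that underlies the domain's preference for monomethylated ligand.

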