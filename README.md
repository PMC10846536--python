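# ppsfkit

Tools for quantifying the **axial precision of two-photon optogenetic
photostimulation** from calcium-imaging data.

Two-photon optogenetics activates single neurons by spiraling a focused
1030 nm beam over an opsin-expressing soma while a calcium indicator
(e.g. GCaMP6s) reports the response. Two widths describe how precise this
is along the optical axis:

* the **OPSF** (optical point spread function) — the axial intensity
  profile of the stimulation focus, summarized by its FWHM and measured by
  imaging sub-diffraction fluorescent beads;
* the **PPSF** (physiological point spread function) — the neuron's
  response amplitude as a function of the axial offset between the focus
  and the cell, measured as the mean post-stimulation ΔF/F =
  (F − F₀)/F₀ at each offset of a −60…+60 μm sweep and summarized by the
  width of the curve at half the prominence of its peak.

The package implements the full measurement chain for both quantities,
plus the model that links them: the PPSF profile is the convolution of the
cell (a binary square wave of width equal to the soma diameter *d* — exact
for a sphere with membrane-bound opsin, since a spherical zone of
thickness dz has area 2πR·dz at every z) with the OPSF (a Gaussian of
standard deviation σ = FWHM / (2√(2 ln 2))). In closed form,

    C(z) = Φ((z + d/2)/σ) − Φ((z − d/2)/σ),

with Φ the standard normal CDF; the model FWHM follows from C(z) = C(0)/2.
Once *d* exceeds the OPSF FWHM, the predicted PPSF depends almost entirely
on the cell — very different optics converge onto the line of equality
(PPSF FWHM = *d*), which is why tightening the focus beyond a point buys
no extra precision for somatic targeting.

A synthetic-data generator renders bead z-stacks, full photostimulation
movies (frame clock + stimulation gate included) and curve-level cohorts
with known ground truth, so every stage is testable end to end without any
experimental data.

## Modules

| module | contents |
| --- | --- |
| `ppsfkit.synth` | bead stacks, excitation-dose model (axial convolution), Hill dose→ΔF/F law, GCaMP-like transients, movie and fast-path cohort simulation |
| `ppsfkit.opsf` | bead detection, stack registration, profile extraction, 1D Gaussian fits, per-axis FWHM summary with 95% CI |
| `ppsfkit.ppsf` | trial-onset detection from sync traces, ΔF/F, response curves, 0.35 ΔF/F inclusion filter, peak alignment, reverse-sweep flipping, group curves, half-prominence FWHM, per-offset Welch tests |
| `ppsfkit.model` | Gaussian ⊗ square-wave convolution model, FWHM-vs-diameter curves, convergence diameter, erf closed-form oracle |
| `ppsfkit.fileio` / `ppsfkit.cli` | TIFF/CSV/JSON/YAML IO, run configuration, pipeline orchestration, fixture generation, `ppsfkit` command-line entry point |

## Worked example

```python
from ppsfkit import model, synth, opsf

for fwhm in (18.6, 8.3):                    # the two measured OPSF conditions
    for d in (0, 15, 30, 50):
        w = model.erf_oracle_fwhm(fwhm, d)
        print(f"OPSF {fwhm:>4} um, cell {d:>2} um -> model PPSF FWHM {w:6.2f} um")
print("convergence diameter (2 um tolerance):",
      model.convergence_diameter(18.6, 8.3, 2.0), "um")

stack, (c,) = synth.generate_bead_stack(
    synth.SMALL_OPSF, 1, (37, 48, 48),
    noise=synth.AcquisitionSpec(photon_noise_scale=0.5, read_noise_sd=2.0), seed=1)
prof = opsf.extract_profile(stack, c, "axial", half_window=17.0)
fit = opsf.fit_gaussian(prof)
print(f"fitted axial FWHM: {fit.fwhm:.2f} um (R^2 = {fit.r2:.4f})")
```

prints

```
OPSF 18.6 um, cell  0 um -> model PPSF FWHM  18.60 um
OPSF 18.6 um, cell 15 um -> model PPSF FWHM  21.55 um
OPSF 18.6 um, cell 30 um -> model PPSF FWHM  31.14 um
OPSF 18.6 um, cell 50 um -> model PPSF FWHM  50.03 um
OPSF  8.3 um, cell  0 um -> model PPSF FWHM   8.30 um
OPSF  8.3 um, cell 15 um -> model PPSF FWHM  15.29 um
OPSF  8.3 um, cell 30 um -> model PPSF FWHM  30.00 um
OPSF  8.3 um, cell 50 um -> model PPSF FWHM  50.00 um
convergence diameter (2 um tolerance): 26.0 um
fitted axial FWHM: 8.28 um (R^2 = 1.0000)
```

For a point-like cell the model PPSF equals the OPSF; by 30 μm cells the
two very different OPSFs predict nearly identical PPSFs sitting on the
line of equality. The bead fit recovers the 8.3 μm focus condition from a
noisy synthetic stack to within 0.3%.

The same analyses are available from the shell:

```bash
ppsfkit model-curves --opsf-fwhm 18.6 --opsf-fwhm 8.3 --diameters 0:50:1 --out curves.csv
ppsfkit simulate --out-dir run/ --seed 1
ppsfkit opsf-fit beads.tif --out fit/
ppsfkit ppsf-curve --config config.yaml
ppsfkit make-fixtures cohort_shifted_peak --seed 0 --out-dir fixtures/
```

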