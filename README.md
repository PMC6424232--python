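# petflux

Quantification of bone metabolic flux from *static* ¹⁸F-fluoride PET scans,
and percentage-change treatment-response classification of bone metastases.

Dynamic fluoride PET estimates the net plasma clearance to bone mineral
(K_i) from a full time–activity curve and an arterial input function.  This
package implements the static alternative: the patient's plasma input
function is reconstructed from **two late venous samples** (a terminal
exponential through them, plus a population-derived residual curve that
restores the early bolus phase), and K_i is obtained from a single
time-point inversion of the graphical (Patlak) uptake relation

```
Ki = (C_bone(T) − V0·Cp(T)) / ∫₀ᵀ Cp dt
```

alongside body-weight-normalized SUV metrics from the same ROIs.  Lesions
and patients are classified progressive (PD) / stable (SD) / partial
response (PR) by a ±25 % percentage-change threshold; SD∪PR is pooled as
non-PD.

Every stage is verifiable without patient data through a built-in simulator:
a forward two-tissue compartment model (plasma ⇄ free ⇄ bound, rate
constants K1, k2, k3, k4, macro flux K1·k3/(k2+k3)) generates cohorts with
known ground truth, venous samples, measurement noise, treatment-effect
multipliers, flare-like false positives, and Gaussian-blob voxel phantoms
for the 40 %-of-max ROI segmentation.

## Layout

| module | contents |
| --- | --- |
| `petflux.kinetics` | two-tissue forward simulator (exact piecewise-linear convolution), macro flux, dynamic Patlak fit |
| `petflux.input_function` | terminal-exponential fit, population residual curve, input-function reconstruction and integration |
| `petflux.quantification` | well-counter calibration, decay correction, SUV, threshold ROI segmentation, static K_i |
| `petflux.response_pipeline` | index-lesion selection, percent change, PD/SD/PR classification, cohort statistics |
| `petflux.synthetic_data` | cohort / phantom generators with ground truth |
| `petflux.cli_io` | config, CSV/JSON IO, packaged 12-patient outcomes fixture, CLI |

## CLI

```sh
petflux simulate --seed 17 --out sim/            # synthetic cohort CSVs
petflux quantify --lesions sim/lesions.csv --venous sim/venous.csv \
                 --out quantified.csv            # static Ki per lesion
petflux classify --lesion-table quantified.csv --reference labels.csv \
                 --out report.json               # PD/SD/PR + cohort stats
petflux report   --report report.json            # headline numbers
petflux fixtures                                 # packaged fixture path
```

Exit codes: 0 success, 2 validation error, 1 internal error.  All
thresholds (V0 intercept, ±25 % cut, index-lesion rules, population input
function) live in a JSON `PipelineConfig` (`--config`).

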