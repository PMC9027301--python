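# ecistools

Analysis toolkit for **electric cell-substrate impedance sensing (ECIS)**
studies of endothelial barrier function, built around the experiment in
which a confluent human retinal endothelial cell (HREC) monolayer on a
96-well gold-microelectrode array is challenged with the cytopathic-hypoxia
mimic CoCl₂ (0/10/100/1000 µM) and followed for 25 h at nine AC frequencies
(250 Hz – 64 kHz).

The package provides:

* a **Giaever–Keese forward model** of the cell-covered microelectrode:
  with `Zn(f) = 1/(Q·(iω)^n)` the cell-free constant-phase-element (CPE)
  interface, `Zm(f) = 2/(iω·Cm)` the transmembrane path,
  `S = 1/Zn + 1/Zm` and `γ = α·√S`,

  ```
  1/Zc = (1/Zn) · [ Zn/(Zn+Zm) + (Zm/(Zn+Zm)) / ( (γ/2)·I₀(γ)/I₁(γ) + Rb·S ) ]
  ```

  where `Rb` (Ω·cm²) is the paracellular junction resistance, `α`
  (Ω·cm^1/2) the cell–substrate constraint parameter, `Cm` (µF/cm²) the
  combined membrane capacitance, and `I₀/I₁` are modified Bessel functions
  of complex argument;
* **per-timepoint deconvolution** of measured multifrequency spectra into
  (Rb, α, Cm) by bounded least squares on relative complex residuals, with
  the degeneracy rule that α and Cm stop being modelable wherever Rb
  reaches zero;
* the **timecourse analysis pipeline**: cell/cell-free ratio spectra and
  frequency selection, normalization to treatment time, trapezoidal AUC,
  the 20 nF confluency gate, and one-way ANOVA + Tukey HSD group statistics
  with the conventional star annotations;
* **Mito-Stress OCR metrics** (basal, ATP-linked, maximal respiration from
  oligomycin → FCCP → rotenone/antimycin phases) and **LDH cytotoxicity**;
* a **synthetic experiment generator** that emulates the whole study —
  seeding, attachment, junction formation, dose-dependent barrier collapse,
  delayed membrane-capacitance rise, mitochondrial impairment without
  cytotoxicity — with stored ground truth, so every stage is testable
  without instrument data.

## Worked example

Simulate the default experiment and run the full analysis:

```bash
ecistools all --seed 1 --outdir results/run1
```

prints

```
selected frequencies: {'impedance_magnitude': 16000.0, 'resistance': 4000.0, 'capacitance': 64000.0}
artifacts written to results/run1
```

i.e. the cell/cell-free impedance-magnitude ratio of the confluent
monolayer peaks at 16 kHz, the series-resistance ratio at 4 kHz, and the
cell-covered series capacitance is lowest at 64 kHz — the three analysis
frequencies used downstream. `results/run1/stats.csv` then contains the
group statistics; the central rows (seed 1) are:

| quantity | measure | dose (µM) | estimate | p vs control | stars |
|---|---|---|---|---|---|
| rb | auc | 0 | 25.19 | — | — |
| rb | auc | 10 | 10.67 | <1e-4 | **** |
| rb | auc | 100 | 6.10 | <1e-4 | **** |
| rb | auc | 1000 | 0.39 | <1e-4 | **** |
| alpha | auc (window) | 10/100/1000 | ≈ control | >0.05 | ns |
| cm | auc (window) | 10 | ≈ control | >0.05 | ns |
| cm | auc (window) | 100 | elevated | <1e-4 | **** |
| cm | auc (window) | 1000 | elevated | <1e-4 | **** |
| ldh_cytotoxicity_pct | endpoint | all | ≈ 2–4 % | >0.05 | ns |

Reading: the paracellular resistance Rb is the first and only barrier
parameter that collapses dose-dependently (its normalized AUC falls
strictly with dose), cell–substrate adhesion α is untouched within every
modelable window, the membrane capacitance Cm rises only at ≥100 µM, and
none of the doses is cytotoxic — mitochondrial basal respiration, however,
is reduced at every dose (see the `basal_ocr` rows).

The same artifacts are produced per stage by the `simulate`, `deconvolve`
and `analyze` subcommands; every run records config hash, seed and version
in `summary.json`, and identical (config, seed) pairs produce byte-identical
files.

### Library use

```python
from ecistools import (DEFAULT_ELECTRODE, CONFLUENT_BARRIER,
                       well_impedance, extract_series_rc)

z = well_impedance(64000.0, DEFAULT_ELECTRODE, CONFLUENT_BARRIER)
r, c = extract_series_rc(z, 64000.0)
print(f"{c * 1e9:.1f} nF")     # 14.9 nF -> below the 20 nF confluency gate
```

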