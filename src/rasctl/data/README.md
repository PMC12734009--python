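# Packaged reference tables

Small CSV transcriptions of the published calibration and validation tables
for the 8000 kg container crucian-carp system that this package models.
They are used to calibrate the cycle-value model, to diff optimizer output
against the published scenario sweeps, and to build the published composite
stress-score model.

| file | content | provenance |
|---|---|---|
| `scenario_ambient2.csv` | scenario sweep at 2 °C ambient: per-plan control cost and cycle profit for the adaptive (exp) and fixed 20 °C/5 mg/L (ctl) strategies | published |
| `scenario_ambient8.csv` | same sweep at 8 °C ambient | published |
| `scenario_ambient14.csv` | same sweep at 14 °C ambient | published |
| `detection_metrics.csv` | per-behavior detector AP/precision/recall/F1 (percent) | published |
| `pca_eigenvalues.csv` | correlation-matrix PCA eigenvalues of the five serum indicators | published |
| `pca_loadings.csv` | component loading matrix for the five serum indicators | published |

Columns in the scenario files: `ambient_T` current air temperature (°C),
`current_DO` / `target_DO` dissolved oxygen (mg/L), `target_T` commanded
water temperature (°C), costs and profits in RMB per cycle.
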