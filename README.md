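# elastocomp

**MR elastography of tumors under compression — a synthetic end-to-end
re-analysis pipeline.**

Malignant tumors have abnormal biomechanics: high viscoelasticity, elevated
interstitial fluid pressure (IFP), and solid stress exerted by the growing
cell/matrix compartment.  Viscoelasticity is measurable non-invasively by MR
elastography (MRE), but solid stress normally requires an invasive pressure
catheter.  A candidate non-invasive marker is the **compression stiffening
rate**: the slope of apparent elasticity (kPa) versus externally applied
compression (kPa), dimensionless because both axes share a unit.

`elastocomp` implements, as one reproducible pipeline on fully synthetic
data, the analysis of a two-arm xenograft study (15 hepatocellular-carcinoma
vs 9 cholangiocarcinoma mice) in which tumors were scanned at 600 Hz under
graded balloon compression, pressures were measured by catheter, and
collagen/cellularity were quantified from stained sections:

* **`synthetic_data`** — a calibrated cohort generator (covariates and
  structural equations linking IFP/collagen to viscoelasticity and solid
  stress/collagen/cellularity/tumor type to the stiffening rate), a
  motion-encoded wave-acquisition simulator (3 encoding directions × 4 time
  offsets × 9 slices × 87×67 at 300×300×350 µm), a duplicate-averaged
  pressure-catheter simulator, and picrosirius-red / nucleus-stain tile
  renderers with known ground truth.
* **`mre_recon`** — phase unwrapping, temporal harmonic extraction, curl of
  the displacement field, and local Helmholtz inversion
  `G* = −ρω² q / ∇²q` with `G* = G′ + iG″` (storage modulus G′ =
  "elasticity", loss modulus G″ = "viscosity", kPa), plus ROI summaries over
  the five central slices.
* **`compression_analysis`** — per-subject stiffening-rate regression and the
  test–retest repeatability index (1.96 × SD of paired relative differences).
* **`histo_quant`** — collagen fraction by colour deconvolution + threshold,
  cellularity by Otsu + distance-transform watershed.
* **`cohort_stats`** — Mann–Whitney U, partial correlation with tumor type as
  covariate, stepwise multiple regression, rank-based ROC/AUC with
  Hanley–McNeil errors, dichotomization rules (solid stress ≥ 15.6 mmHg,
  collagen ≥ 1.7%), and the AUC-based sample-size calculation.
* **`pipeline` / `elastocomp` CLI** — the whole experiment as one seeded,
  byte-reproducible run with CSV/NIfTI/TIFF/JSON artifacts.

## Worked example

```python
from elastocomp import (AcquisitionGeometry, CohortConfig, sample_cohort,
                        simulate_wave_acquisition, reconstruct,
                        central_roi, roi_statistics)

geometry = AcquisitionGeometry()          # 87x67x9 @ 300x300x350 µm, 600 Hz
subject = sample_cohort(CohortConfig(), seed=42)[0]
print(subject.basal_elasticity, subject.basal_viscosity,
      subject.stiffening_slope)
# 1.5232... 1.0354... 0.2361...

for compression_kpa in (0.0, 2.0, 4.0):
    acq = simulate_wave_acquisition(subject, compression_kpa, geometry,
                                    seed=100, noise_sd=0.01)
    stats = roi_statistics(reconstruct(acq), central_roi(geometry))
    print(compression_kpa, round(stats.mean_storage_kpa, 3),
          round(stats.mean_loss_kpa, 3))
# 0.0 1.531 1.01
# 2.0 1.997 1.006
# 4.0 2.458 1.008
```

The three reconstructed elasticities rise linearly with compression; their
regression slope (≈ 0.23 adim here) recovers the subject's ground-truth
stiffening rate, and the intercept its basal elasticity.

The full experiment — cohort, acquisitions, reconstructions, pressures,
histology, statistics, report — is one call (or `elastocomp run-all`):

```bash
elastocomp run-all --outdir out/          # uses the packaged default config
```

which prints the group summary table (mean ± SD per tumor type with
Mann–Whitney p-values), the four AUCs with Hanley–McNeil SEs, the three
repeatability indexes, and writes `cohort.csv`, per-subject NIfTI elastogram
maps, histology tiles and `report.json` under `out/`.

The sample-size planning calculation used to size such a study is a single
function call:

```python
from elastocomp import auc_sample_size
auc_sample_size(expected_auc=0.85, null_auc=0.5, alpha=0.05,
                power=0.80, neg_pos_ratio=1.7)
# 22
```

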