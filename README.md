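# lmh-octa

Quantitative OCT-angiography (OCTA) analysis of lamellar macular holes
(LMH): some LMHs progressively lose foveal tissue while others stay
stable, and the two behaviours separate both microvascularly and
functionally.  This package reimplements the full measurement pipeline
behind that comparison as tested, reusable code, and ships a synthetic
generator that reproduces the study conditions so every stage can be
validated end to end without patient data.

It is intended for retina researchers and image-analysis developers who
want the individual operators (vessel-map binarization, sector densities,
capillary-free-zone morphometry, tissue-loss classification, exact
small-sample statistics) as a library, and for anyone who wants to rerun
the complete synthetic study from a single seed.

## What it computes

* **Binary vessel maps** from en-face angiograms by fusing a global
  white-pixel band (intensity ≥ 0.7 on the normalized image), a multiscale
  Hessian (Frangi) vesselness filter, and a local-mean adaptive threshold:
  `vessel = global ∨ (adaptive ∧ vesselness ≥ cut)`, followed by
  small-speckle removal.
* **Perfusion maps**: vessel pixels whose inter-frame decorrelation
  `D = 1 − mean_t [2 f_t f_{t+1} / (f_t² + f_{t+1}²)]` exceeds a threshold
  (moving blood decorrelates across repeated frames; static tissue has
  `D = 0`).
* **Vessel density (VD)** and **perfusion density (PD)**, in percent of
  region area, over a foveal 1 mm disk and a 2.9 mm parafoveal ring, each
  split into four quadrants (ROI = quadrant colocalized with tissue loss,
  R1/R2 adjacent, R3 opposite).
* **CFZ morphometry**: area `A`, perimeter `P`, and circularity
  `C = 4πA/P²` of the capillary-free zone (1 for a circle, → 0 for
  irregular contours).
* **Tissue loss**: per-section gap-area change between visits (follow-up −
  baseline), summed over the 3 most involved sections; eyes with ≥
  0.02 mm² form the TL group; speed = loss / follow-up years.
* **Cohort statistics**: Shapiro-Wilk-gated t / Mann-Whitney group
  comparisons (exact permutation null at small n), Wilcoxon signed-rank
  paired tests, Fisher/χ² prevalence tests, permutation-exact Spearman
  correlations, and ICC(2,1) inter-grader agreement.

## Worked example

Run the numbered analysis scripts in order (or call
`lmh_octa.pipeline.run_demo` for the same thing in one step):

```bash
python analysis/01_simulate_study.py 1     # seed 1
python analysis/02_binarize_angiograms.py
python analysis/03_sector_metrics.py
python analysis/04_tissue_loss.py
python analysis/05_cohort_statistics.py
```

With seed 1 this prints (abridged):

```
cohort: 28 patients (14 TL / 14 ST)
  TL-group median summed loss: 0.096 mm^2
SCP: Dice 0.993, PD error 0.15 pp
SCP: CFZ area 0.450 mm^2 (truth 0.450), circularity 0.51, foveal VD 42.7%
TL group: median loss 0.096 mm^2, median speed 0.048 mm^2/year
group contrasts (TL vs ST):
  SCP Foveal VD (%): 16.35 vs 21.04 (p = 0.0000, welch_t)
  SCP Parafoveal PD (%): 31.65 vs 34.69 (p = 0.0004, mann_whitney_asymptotic)
correlations:
  TL amount vs SCP parafoveal PD (TL group): rho = -0.996, p = 0.00001
  Speed of TL vs BCVA decline (TL group): rho = +0.996, p = 0.00001
```

Reading this: the segmentation recovers the known synthetic vessel mask
almost perfectly (Dice 0.993) and the extracted CFZ matches the generated
geometry (area 0.450 mm², circularity 0.51).  The simulated progressive
group shows the expected microvascular deficit (lower foveal VD/PD) and
the two near-perfect monotone links — more tissue loss ↔ less parafoveal
perfusion, faster loss ↔ larger visual-acuity decline — are recovered by
the Spearman machinery.  Tables land in `results/` as CSV.

## Layout

```
src/lmh_octa/     library: synthdata, binarize, grid, metrics,
                  tissueloss, stats, pipeline, io
analysis/         numbered narrative drivers writing to results/
tests/            pytest suite incl. brute-force enumeration oracles
docs/methods.md   model, parameters, and design notes
```
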