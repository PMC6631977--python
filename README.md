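# nirdx

Classification of BRAF V600E mutation status in colorectal-cancer tissue
sections from near-infrared (NIR) transflectance spectra, using a
counter-propagation artificial neural network (CP-ANN).

The V600E mutation substitutes valine for glutamic acid in the BRAF kinase,
replacing a (CH₃)₂CH– side chain with –(CH₂)₂COOH. That chemical difference
shows up in the C–H and O–H overtone/combination bands of the NIR range
(12,000–4,000 cm⁻¹), concentrated in the two subranges 9000–6800 and
6500–4000 cm⁻¹. `nirdx` implements the full chemometric pipeline that turns
raw tissue spectra into a per-sample mutant / wild-type call, for
chemometricians and spectroscopists who want a tested, reproducible
reference implementation:

1. **Spectral I/O** (`nirdx.spectra_io`) — wide-CSV and single-block
   JCAMP-DX readers, subrange extraction, mean/difference spectra.
2. **Preprocessing** (`nirdx.preprocess`) — MC, MSC, SNV, first/second
   derivative, Savitzky–Golay and Norris derivative smoothing, composed as
   strategies like `"SNV+NDS(5,5)+FD+MC"` with strict
   fit-on-calibration / apply-to-validation semantics.
3. **Feature selection** (`nirdx.pca`) — PCA scores with the smallest k
   whose cumulative explained variance reaches 85.0%; if 20 components
   cannot reach it, the model is flagged NA and refused downstream.
4. **Classifier** (`nirdx.cpann`) — a from-scratch CP-ANN: for input xᵢ the
   winning neuron c = argmin_j ‖w_j − xᵢ‖ and its neighborhood are updated by

       w_j ← w_j + η(t) · h(d_jc, r(t)) · (xᵢ − w_j)
       u_j ← u_j + η(t) · h(d_jc, r(t)) · (yᵢ − u_j)

   where u_j are the output-layer class weights, yᵢ the one-hot label,
   η(t) decays linearly 0.5 → 0.01, the radius r(t) shrinks linearly from
   S/2 to 0 on the non-toroidal S×S map, and h is a triangular neighborhood
   factor. Prediction = argmax of the winning neuron's class weights.
5. **Model selection** (`nirdx.model_select`) — the strategy × subrange ×
   map-size grid with CAC / CACV / CAV accuracies (calibration,
   sample-grouped 5-fold cross-validation, validation).
6. **Diagnosis** (`nirdx.diagnose`) — OR-voting over the 3 replicate spectra
   of each sample (wild type only if all three replicates are wild type),
   then sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy, with
   mutant as the positive class.
7. **Synthetic data** (`nirdx.synthetic_data`) — a generator of two-class
   spectra with Gaussian bands at the diagnostic C–H/O–H positions,
   replicate heterogeneity, multiplicative scatter, preparation-class
   interference (paraffin / HE stain) and noise, so the whole pipeline is
   testable without clinical data.

## Worked example

```python
from nirdx import workflow

result = workflow.run_default_pipeline(seed=1, cv_folds=5)
print(f"CAC {result.cac_pct:.1f}%  CACV {result.cacv_pct:.1f}%  CAV {result.cav_pct:.1f}%")
s, p, a = result.cal_report.rounded()
print(f"calibration diagnosis: sensitivity {s}%  specificity {p}%  accuracy {a}%")
```

prints

```
CAC 100.0%  CACV 98.3%  CAV 100.0%
calibration diagnosis: sensitivity 100.0%  specificity 100.0%  accuracy 100.0%
```

i.e. on the default synthetic dataset (80 calibration + 24 validation
samples, 3 spectra each) the 12×12 CP-ANN classifies 100% of calibration
spectra correctly (CAC), 98.3% under sample-grouped cross-validation (CACV),
100% of held-out validation spectra (CAV), and the OR-voting rule over
replicates yields perfect sample-level sensitivity and specificity.

The numbered drivers under `analysis/` run the same stages as a narrative:
`01_simulate.py` writes the dataset, `02_spectra_overview.py` the class mean
and difference spectra (99.6% of the class-difference energy falls inside
the two modeling subranges), `03_model_grid.py` the full 60-row comparison
grid (mean centering wins; scatter- and derivative-based strategies go NA
under the 85% variance rule on this data), `04_diagnose.py` the diagnostic
report and projection map. A `nirdx` console command exposes the same
workflow (`nirdx simulate/train/diagnose/report -c config.yaml`).

## Layout

```
src/nirdx/        library (one module per pipeline stage)
analysis/         numbered narrative drivers writing results/
scripts/          acceptance.py reproduction script
tests/            pytest suite (unit, property and end-to-end tests)
docs/methods.md   models, parameter choices, limitations
```
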