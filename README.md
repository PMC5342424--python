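# radiogen-psp

Radiogenomic biomarker discovery for distinguishing **pseudoprogression
(PsP)** from **true tumor progression (TTP)** in glioblastoma (GBM).

After chemoradiation, a substantial fraction of GBM patients show imaging
changes that mimic tumor regrowth but later stabilize without any change in
treatment. Telling this pseudoprogression apart from genuine progression is
a hard clinical problem: follow-up imaging takes months, and biopsy requires
a second surgery. This package implements a discovery pipeline that looks
for *genetic* biomarkers of PsP vs. TTP by associating baseline gene
expression with the way tumor morphology evolves on longitudinal MRI.

## The pipeline

1. **Morphometrics** — per-slice and per-case morphological features
   (areas, margin thickness, axis lengths, solidity, eccentricity,
   compactness, sphericity, ...) from labeled tumor masks (enhanced rim /
   necrotic core), with largest-slice and mean/max/min/sum aggregation.
2. **Screening** — per-gene two-sided Wilcoxon rank-sum test between PsP
   and TTP groups at raw p < 0.005, plus average-linkage hierarchical
   clustering of the survivors on 1 − Pearson-r distance.
3. **Longitudinal sparse regression** — the core model. With imaging
   features X_t ∈ ℝ^{n×d} at time points t = 1…T and expression
   Y ∈ ℝ^{n×c}, it minimizes

   ```
   Σ_t ‖X_t W_t − Y‖_F²
     + θ₁ Σ_k √( Σ_t ‖W_t^k − (1/T) Σ_s W_s^k‖² )     (temporal-smoothness group ℓ2,1)
     + θ₂ ‖[W_1 | … | W_T]‖_*                          (trace norm of the unfolding)
   ```

   solved by an iteratively reweighted closed-form update
   `W_t = (X_tᵀX_t + θ₁D + θ₂D̄̄)⁻¹ (X_tᵀY + θ₁DD̄)`. Genes are ranked by
   their overall weight `W′(t, j) = Σ_i |W_t(i, j)|`, averaged over time.
4. **Coverage-rate selection** — every (θ, iteration-count) cell of a
   9 × 3 grid (θ₁ = θ₂ ∈ {0.1, 0.2, 0.5, 1, 2, 5, 10, 20, 50}; 800 / 1000 /
   1200 iterations) is fit; a gene's coverage rate P is the fraction of the
   27 runs in which it ranks in the top-k (k = 50) by average weight.
   Candidates are genes with occurrence ≥ ceil(P · 27), i.e. 22 / 25 / 27
   at P = 0.8 / 0.9 / 1.
5. **Validation** — candidates are re-tested on an independent cohort with
   the same Wilcoxon engine, reporting direction and boxplot statistics.

Because the original clinical cohorts are private, the package ships a
first-class synthetic-data module that emulates the study design (17
discovery samples, 5 PsP / 12 TTP, 225 imaging features, 119 genes, 4 MRI
time points; 21 validation samples, 6 PsP / 15 TTP) with planted sparse,
temporally smooth, low-rank imaging→expression associations and known
ground truth.

## Worked example

```python
import radiogen_psp as r

cohort, result = r.run_synthetic_study(r.SimulationConfig(seed=1))
print("screened genes :", len(result.screened_genes))
print("candidates (P>=0.8):", ", ".join(result.candidate_symbols))
print(result.validation.frame[["gene", "p_value", "direction"]].to_string(index=False))
```

prints

```
screened genes : 10
candidates (P>=0.8): g004, g017, g030, g038, g053, g057, g085, g096, g108, g111
gene  p_value     direction
g004 0.000147 higher-in-PsP
g017 0.000037 higher-in-PsP
...
g111 0.000037 higher-in-PsP
```

Ten genes pass the p < 0.005 screen on this cohort (the ten planted ones);
all ten survive the 27-run coverage criterion at P ≥ 0.8 and all validate
as significantly higher in the PsP group of the independent cohort —
exactly the behaviour expected when the planted biomarkers carry both a
group shift and a stable association with the imaging features.

The same steps are available from the shell:

```bash
radiogen-psp generate --config cfg.yaml --out data/ --seed 1
radiogen-psp morpho   --masks masks/ --out features.tsv
radiogen-psp screen   --data data/ --out pvalues.tsv
radiogen-psp fit      --data data/ --theta1 1 --theta2 1 --iters 1000 --out fit/
radiogen-psp select   --data data/ --coverage 0.8 --out coverage.tsv
radiogen-psp validate --data val/ --genes g004,g017 --out report.tsv
```

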