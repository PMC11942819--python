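# liftpattern

Detecting changes in movement patterns during barbell exercises from
sagittal-plane bar-path recordings.

When a lifter performs a standing biceps curl, the bar traces a repeatable
arc in the sagittal plane. Adding load changes that pattern — most visibly
as an inflated vertical range of motion. `liftpattern` quantifies such
changes from marker-tracked bar coordinates: it builds each subject's own
no-load reference, measures how far every loaded execution deviates from
it, scores the similarity of executions with an adapted Morisita–Horn
index, and turns deviations into an interpretable execution grade with a
Sugeno fuzzy-inference system. A support-vector-regression benchmark puts
the fuzzy model's fit quality in context.

It is aimed at biomechanics and strength-and-conditioning researchers who
work from ordinary 30 Hz video with semi-automatic marker tracking and
want reproducible, scriptable movement-quality metrics.

## The method

For a subject's three bar-only executions, the mean of the per-execution
maximum displacements defines the reference **MMD0** (per axis). Each
loaded execution *e* is summarised by its maximum displacement
`max_e = max_i |y_i − y_start|` over the ascending (lifting) phase, and by

* the **absolute deviation** `dev_abs = |max_e − MMD0|` (cm), and
* the **Morisita–Horn index** between the execution's and the reference's
  time-normalized displacement sequences,

  `I_MH = 2 Σ x_i y_i / [(Σx_i²/X² + Σy_i²/Y²) · X · Y]`, with sample
  totals `X = Σx_i`, `Y = Σy_i`; 1 means identical composition, 0 disjoint.

Three models relate deviation to similarity:

1. **Quadratic trend** — OLS fit `I_MH ≈ a·dev² + b·dev + c`.
2. **Sugeno fuzzy system** — 18 rules (6 Gaussian deviation levels ×
   3 load levels), product t-norm, weighted-average defuzzification;
   constant rule consequents are calibrated to observed (deviation, MH)
   pairs by linear least squares. Scores map onto five categories from
   *Total Error* to *Total Accuracy* over the output range [0.97, 1.0].
3. **SVR benchmark** — six fixed presets (linear/quadratic/cubic kernels
   and fine/medium/coarse Gaussian with kernel scales √P/4, √P, 4√P),
   compared by 5-fold cross-validated RMSE, R², and Pearson r.

A synthetic-data generator produces 30 Hz curl trajectories on circular
arcs with programmable load-dependent amplitude inflation and tracking
noise, so the whole pipeline is testable against known ground truth.

## Worked example

The package ships a ten-volunteer reference dataset (maximum absolute
deviations at 25 % and 50 % body-weight load, and the vertical MH indices
at 50 % load). Fitting the three models on its 30 (deviation, MH) pairs:

```python
import liftpattern as lp

pairs = lp.paired_vertical_50()          # 30 rows: volunteer, execution, deviation_cm, mh

quad = lp.QuadraticTrend.from_dataframe(pairs).fit()
print(quad.summary())
```

```
Quadratic deviation-similarity trend (OLS)
==============================================
  n observations      30
  a (dev², cm⁻²)      -3.102586e-05   se 9.36e-06
  b (dev, cm⁻¹)       -4.153487e-04   se 2.18e-04
  c (intercept)        1.001250   se 1.13e-03
  R²                   0.9272
  Pearson r (obs,fit)  0.9629
```

Similarity decays gently and nonlinearly with deviation: an execution
24 cm off its reference still scores ≈ 0.97. The calibrated fuzzy system
fits the same data a little better than the quadratic:

```python
fis = lp.FuzzyScoringModel.from_dataframe(pairs).fit()
print(round(fis.rsquared, 4), round(fis.pearson_r, 4))   # 0.9497 0.9745
s = fis.score(18.6)                                      # deviation 18.6 cm at 50 % load
print(round(s.similarity, 4), s.category)                # 0.9808 Medium Error
```

and the SVR benchmark (20 fold partitions) ranks the presets:

```python
bench = lp.SVRBenchmark.from_dataframe(pairs).fit(seed=0, repeats=20)
print(bench.summary())
```

```
SVR benchmark (5-fold CV, 20 seed(s))
====================================================
                   rmse      r2  pearson_r
preset                                    
linear          0.00253 0.86370    0.93087
quadratic       0.00307 0.79855    0.91234
cubic           0.00410 0.63582    0.89084
fine_gaussian   0.00424 0.61771    0.78968
medium_gaussian 0.00348 0.74339    0.86810
coarse_gaussian 0.00264 0.85239    0.94408
best preset by RMSE: linear
```

The fuzzy model (R² ≈ 0.95) outperforms every SVR preset on this dataset.

The same stages are available from the shell:

```bash
liftpattern simulate --subjects 10 --seed 42 --out study/   # synthetic study + ground truth
liftpattern ingest study/S01_Ex1_0.csv --reps 1             # per-rep maxima
liftpattern calibrate --out fis.json                        # fit rule constants
liftpattern score --deviation 12.3 --load 50 --config fis.json
liftpattern run --fixtures --out report/                    # full pipeline bundle
```

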