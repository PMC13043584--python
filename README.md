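# keyclock

Passive estimation of diurnal typing regularity and sleep from smartphone
keystroke **metadata** (timestamps, key categories, press durations — never
text), and prediction of practice-adjusted digital Trail-Making-Test-B
(dTMT-B) performance from the derived features. The package is aimed at
digital-phenotyping and computational-psychiatry researchers who want the
whole pipeline — from raw event streams to interpretable held-out
predictions — reproducible from a single seed, plus a synthetic-cohort
generator with planted ground truth, since real keyboard streams of this
kind are rarely shareable.

## The method

A participant's typing is binned into `days x 24` matrices of keystroke
counts `k[j, i]` and hourly typing speed (median alphanumeric-to-alphanumeric
interkey delay). Sparse typing makes raw matrices unreliable, so they are
smoothed on a **torus**: hour 23 wraps into hour 0 of the next day, and the
same hour couples across nearby days. Cells become graph nodes with hour
edges weighted `(k[j,i] + k[j,i+1]) / 2` (including the midnight wrap) and
day edges (1–3 days apart) weighted by the 7-day median count of that hour.
With `B` the graph Laplacian and `X` the 2 x n stacked data matrix, the
smoothed trajectory `W*` solves

```
min_{H,W}  ||X − HW||_F² + α·Tr(W B Wᵀ)    s.t. HᵀH = I_r      (r = 1, α = 100)
```

via the Cholesky factor `D` of `I + αB` and the thin SVD of `XD⁻ᵀ`
(`H* = Ẽ`, `W* = Σ̃F̃ᵀD⁻¹`). Sleep is the prolonged contiguous block of
smoothed zero activity per relative 24 h period, found by binarizing `W*`,
flood-filling the inactive block, extending it backwards across midnight,
and cleaning small gaps with an 8 h sliding window.

Per dTMT-B task, 13 typing/orientation features (±3 h window, ≥ 20
keystrokes) and 5 regularity/sleep features (prior 7 days of `W*` and sleep
labels) are each expanded into grand-mean (`_gm`) and subject-centered
(`_sc`) predictors — 36 candidates. Completion times are z-scored within
task-number groups to remove practice effects. After an 80/20 split by
participant, mutual information retains the top 10 features; Lasso, SVR,
KNN, and random-forest regressors are tuned with participant-grouped 3-fold
grid search and compared to a mean-prediction baseline, with exact additive
(Shapley) attributions and a paired sign-flip permutation test on absolute
residuals.

See `docs/methods.md` for assumptions, numerical choices, and limitations.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from keyclock import CohortConfig, PipelineConfig, run_pipeline, sleep_recovery

cfg = PipelineConfig(cohort=CohortConfig(n_participants=30, n_days=21), seed=100)
result = run_pipeline(cfg)

rec = sleep_recovery(result)
print(f"participants kept: {len(result.participants)}  "
      f"tasks retained: {int(result.adjusted_tasks['included'].sum())}")
print(f"median estimated sleep: {rec['median_sleep_h'].median():.1f} h  "
      f"hour-level truth agreement: {rec['agreement'].mean():.2f}")
for kind, report in result.modeling["reports"].items():
    print(f"{kind:13s} test RMSE {report.rmse:.3f}  MAE {report.mae:.3f}")
print("top MI features:", ", ".join(result.modeling["selected"][:3]))
```

prints

```
participants kept: 30  tasks retained: 77
median estimated sleep: 5.0 h  hour-level truth agreement: 0.89
lasso         test RMSE 0.943  MAE 0.723
svr           test RMSE 0.809  MAE 0.686
knn           test RMSE 0.931  MAE 0.729
rf            test RMSE 0.819  MAE 0.542
baseline_mean test RMSE 0.983  MAE 0.793
top MI features: varAAIKD_gm, typingSpeed_gm, medianCosineSimilarity_1diff_gm
```

All 30 synthetic participants pass the activity filters and 77 of their 137
scheduled tasks survive the first-six / percentile / typing-window filters.
Estimated sleep (median 5 h against a planted ~8 h window) is conservative
by design — smoothing marks boundary hours as active — and agrees with the
planted truth on 89 % of hour cells. The adjusted times are in SD units, so
the random forest's held-out RMSE of 0.82 vs. 0.98 for the mean baseline
means typing behavior explains a real share of between-participant
performance; the selection picking average typing speed and the
day-to-day pattern-similarity feature is exactly the planted signal
(latent speed and regularity drive the simulated task times).

The same stages are available as a CLI:

```
keyclock simulate --seed 5 --out sim/
keyclock build-matrices --keystrokes sim/keystrokes.csv --out mat/
keyclock smooth --counts mat/counts_P000.csv --speed mat/speed_P000.csv --out sm/
keyclock sleep --wstar sm/wstar_P000.csv --out sl/
keyclock run-all --seed 5 --out run/
```

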