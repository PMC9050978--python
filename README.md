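# lungrad

2-D CT lung-lesion radiomics: lesion segmentation, a compact panel of eight
texture/shape/histogram features plus diameter, a random-survival-forest
composite prognosis score, and the downstream association and reliability
analyses — all exercisable end to end on a bundled synthetic-cohort
generator with known ground truth.

## Who this is for

Researchers studying quantitative CT markers of lung-cancer heterogeneity:
how much prognostic and biological signal a small, pre-selected radiomic
panel carries, and how stable those measurements are across repeat scans and
segmentation algorithms. Because public CT collections rarely ship the
manually drawn lesion ROIs that such analyses require, every stage here can
run against synthetic lesions whose shape, texture, survival hazard, and
molecular/semantic labels are generated with stated effect sizes — so each
statistical claim the pipeline makes is testable against a known truth.

## The model

**Features.** On the maximum-area lesion slice, from a 2-D image + binary
ROI discretized to G = 32 gray levels over the in-mask range:

- *circularity* = 4πA/P² (subpixel-contour perimeter; 1 for a disk);
- *variance*, *kurtosis* (Pearson, Gaussian → 3), *energy* = Σᵢ p(i)² of the
  level histogram;
- *cluster shade* = Σ(i + j − μᵢ − μⱼ)³ p(i, j) and *maximum probability* =
  max p(i, j) of the distance-1, direction-averaged, symmetric gray-level
  co-occurrence matrix;
- *LongHEM* = long-run high gray-level emphasis (1/N_r)ΣR(i,j)·j²·i²,
  averaged over the four principal directions of the gray-level run-length
  matrix;
- *a_lre* = long-run emphasis computed on the low-low subband of a one-level
  Haar wavelet transform of the ROI;
- *diameter* = round((major + minor axis)/2) in mm from image moments.

**Score.** A random survival forest (50 trees, minimum terminal node 10,
maximum depth 4, mtry = ⌈√p⌉) grown on bootstrap samples with log-rank
splitting and Nelson–Aalen cumulative hazards at the leaves. A subject's
risk is the ensemble mortality — the leaf cumulative hazard summed over the
training event-time grid, averaged over trees — rescaled to a 0–100 score by
the training min/max. Cohorts are split 2:1 into training and testing;
prognosis is read out as Harrell's C, IPCW time-dependent AUC(t), and the
high-vs-low hazard ratio from a binary Cox model after a median split.

**Associations and reliability.** Features are screened against semantic
flags, EGFR/KRAS/ALK status, and histology with two-sided Wilcoxon rank-sum
tests, and against ordinal grade with Spearman correlation. Measurement
reliability uses ICC(2,1) (two-way random effects, absolute agreement,
single measure) with an ICC ≥ 0.8 robustness rule, plus Bland–Altman limits
of agreement.

## Worked example

Generate a 150-lesion synthetic cohort, extract features, attach survival
outcomes driven by LongHEM and kurtosis, and fit the composite score:

```python
import lungrad as lr
from lungrad.forest import RSFHyperParams, split_cohort
from lungrad.phantom import CohortConfig, sample_phantom_configs, simulate_survival

configs  = sample_phantom_configs(150, seed=0, image_size=96)
phantoms = [lr.make_lesion_phantom(c) for c in configs]
feats    = lr.extract_table([p[0] for p in phantoms], [p[1] for p in phantoms])

cc    = CohortConfig(n_subjects=150, log_hr={"longhem": 0.7, "kurtosis": 0.4}, seed=3)
table = feats.merge(simulate_survival(feats, cc), on="subject_id")

train, test = split_cohort(table, seed=4)
results = lr.RadiomicScoreModel.from_dataframe(
    train, hyper=RSFHyperParams(seed=5)).fit()
print(results.summary())
```

```
Composite radiomic score (random survival forest)
==================================================
subjects: 100   events: 73
features: circularity, variance, kurtosis, energy, cluster_shade, maximum_probability, longhem, a_lre
hyperparameters: ntree=50 nodesize=10 nodedepth=4 mtry=ceil(sqrt(p)) seed=5
training C-statistic: 0.810
AUC at 24 months: 0.910
AUC at 60 months: 0.888
high vs low score HR: 7.048 (95% CI 3.922-12.666), log-rank p = 0.0000
```

The held-out third of the cohort gives an honest read of the same model:

```python
rep = results.evaluate(test, test["time_months"], test["event"])
# test C-statistic: 0.657; test AUC(60 mo): 0.788; test HR: 3.80 (1.79-8.06)
```

The training C of 0.81 reflects in-sample optimism; the test C of 0.66 and
test HR of 3.8 show the score still separates fast from slow progressors on
unseen subjects, as expected when two of the eight features truly carry
hazard (log-HR 0.7 and 0.4 per SD).

The same workflow is available from the shell:

```bash
lungrad run-all --out demo_run --seed 0     # full pipeline, every artifact
lungrad simulate --out cohort --n 50        # just the synthetic cohort
lungrad segment cohort/images/S0000.tif --threshold 120 65535 \
        --method region --out S0000_mask.png
```

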