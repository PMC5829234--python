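# fmclass

Functional movement classes from acoustic-telemetry detection data.

Passive acoustic telemetry tracks aquatic animals by logging coded pings
from implanted transmitters ("tags") on moored hydrophone receivers.
Receivers are deployed in named groups — *installations* — ranging from
dense local arrays to coast-spanning curtains. Pooling detections across
a whole national receiver network makes it possible to classify
*individuals* (not species) by how they move: some animals sit on one
installation for years, others are heard once a month, others commute or
roam over thousands of kilometres. `fmclass` implements that workflow for
movement ecologists: from raw detection logs to named functional movement
classes (FMCs) and movement networks, with a built-in detection simulator
so everything runs on a laptop.

## The method

For each tag with at least `min_detections` detections, seven covariates
summarise its detection history:

| covariate | meaning |
|---|---|
| `n_installations` | distinct installations with ≥ 1 detection |
| `n_detections` | total detections |
| `mean_gap_min` | mean time between consecutive detections (min) |
| `q25_km, q50_km, q75_km, q99_km` | quantiles of great-circle distance (km) between consecutive detections |

The 99% quantile replaces the maximum so one extreme hop does not define
the upper tail. Covariates are square-root transformed, centred, and
scaled (sample SD) to give each equal leverage.

Tags are partitioned by k-means (Lloyd, best of `n_init = 25` seeded
restarts). The number of classes k is selected with the **gap statistic**:
for k = 1…k_max,

```
Gap(k) = (1/B) Σ_b log W*_kb − log W_k
```

where `W_k` is the within-cluster sum of squares of the data and `W*_kb`
that of B reference datasets drawn uniformly over each covariate's range;
k is the smallest value with `Gap(k) ≥ Gap(k+1) − s_{k+1}` (one-standard-
error rule, `s_k = sd_b(log W*_kb)·√(1+1/B)`). A four-class solution is
named a posteriori from raw-covariate cluster means: **Roamers** (largest
mean `q99_km`), **Occasionals** (largest `mean_gap_min`), **Residents**
(largest `n_detections`), **Irruptors** (the remainder — frequently
detected, intermediate long-distance movement).

Class differences are attributed to covariates with **SIMPER** under a
Euclidean measure (each covariate's share of mean squared difference over
all cross-class pairs), after dispersion weighting (divide by the mean
within-class variance-to-mean ratio) and `log(x+1)`.

Movement structure is summarised as **relative-movement networks**: nodes
are installations; the directed edge a→b carries the number of consecutive-
detection transitions a→b divided by all between-installation transitions,
so edges sum to 1. Networks are built for the Full array, the IMOS-only
and non-IMOS-only subsets, and per class, and described by 14 metrics
(9 network-level, 5 per installation) plus modularity communities.

## Worked example

```python
import pandas as pd
from fmclass import (SimulationConfig, generate_dataset, compute_covariates,
                     build_covariate_matrix, kmeans_fit, name_clusters,
                     best_match_accuracy)
from fmclass.simper import Simper

ds = generate_dataset(SimulationConfig(seed=42))
print(f"{len(ds.detections)} detections from {ds.truth.shape[0]} tags")

cov, excluded = compute_covariates(ds.detections)
matrix = build_covariate_matrix(cov)
fit = kmeans_fit(matrix.X, 4, n_init=25, seed=42)
assignment = name_clusters(pd.Series(fit.labels, index=cov.index), matrix.raw)
print(assignment.class_labels.value_counts().to_string())

truth = ds.truth.set_index("tag_id").loc[cov.index, "archetype"]
print(f"recovery vs simulated truth: "
      f"{best_match_accuracy(truth.to_numpy(), fit.labels):.3f}")

simper = Simper().fit(matrix.raw, assignment.class_labels.to_numpy())
for name, tab in simper.results_.one_vs_rest.items():
    top = tab.iloc[0]
    print(f"{name}: {top.covariate} ({top.percent:.0f}% contribution)")
```

prints

```
367231 detections from 250 tags
Occasionals    120
Residents       61
Roamers         45
Irruptors       24
recovery vs simulated truth: 0.988
Irruptors: mean_gap_min (39% contribution)
Occasionals: mean_gap_min (40% contribution)
Residents: n_detections (39% contribution)
Roamers: q99_km (35% contribution)
```

The simulated cohort of 250 tags (60 resident, 120 occasional,
25 irruptor, 45 roamer) is recovered almost perfectly by a four-class
k-means solution; residents are set apart by sheer detection volume,
occasionals by long silences, roamers by the distances they cover.

The same workflow is available from the shell:

```bash
fmclass simulate --out data --seed 42
fmclass all --detections data/detections.csv \
            --installations data/installations.csv \
            --seed 7 --out results --plots
```

which writes per-stage CSVs (covariates, gap curve, assignment, SIMPER
table, network and installation metrics, effectiveness summaries) plus a
run manifest, and diagnostic gap-curve/PCA figures.

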