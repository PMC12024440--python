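# edgefc

Edge-centric functional connectivity analysis for parcellated time series:
co-fluctuation edge time series, edge functional connectivity (eFC), k-means
edge communities, node/network overlap entropy, community similarity, and
covariate-adjusted two-group statistics — plus a synthetic-cohort generator
with full ground truth for every pipeline stage.

## What it does

Given per-subject component × time matrices (e.g. ICA component time
courses), a component → network atlas, and a subject table with group labels
and covariates, the pipeline:

1. **z-scores** each component series (population variance convention, so the
   time-average of a product of two z-scores is exactly their Pearson r);
2. builds the **edge time series**: for each of the M = N(N−1)/2 node pairs,
   the element-wise product of the two z-scored series (moment-by-moment
   co-fluctuation);
3. computes **eFC**, the M × M uncentered cosine similarity between edge
   rows;
4. clusters eFC rows with **k-means** (features standardized to unit
   variance; k swept 2–10 by default with 250 random restarts per k, best
   restart by minimum inertia);
5. derives **participation profiles** (fraction of each node's incident
   edges per community), **normalized entropy** (base-2, divided by log2 k)
   at component and network level, and **community similarity** between node
   pairs;
6. compares groups per network/component: pooled **OLS residualization**
   against covariates, equal-variance **two-sample t tests**, and
   **Bonferroni** correction at α/n.

The `simulate` module generates two-group cohorts from a latent mixture
model (k\* standard-normal community signals, nonnegative loading rows
summing to 1, white noise) with known edge-community labels, known node
overlap, and optional planted per-network group differences — so recovery,
calibration and power are all checkable against ground truth.

## CLI

```bash
# synthetic cohort with a planted overlap increase in net05 for group 2
edgefc simulate --out demo/cohort --seed 1 --target-network net05

# full pipeline from a YAML config
edgefc run --config demo/config.yaml

# or stage by stage
edgefc efc --panel demo/cohort/panels/g1_s001.tsv --out demo/g1_s001_efc
edgefc cluster --efc demo/g1_s001_efc --out demo/parts --k-min 2 --k-max 10
edgefc entropy --partition demo/parts/partition_k4.tsv \
    --atlas demo/cohort/atlas.tsv --out demo/entropy.tsv
edgefc compare --entropy run_out/entropy.tsv --subjects demo/cohort/subjects.tsv \
    --level network --k 4 --covariates age,education --out demo/stats.tsv
```

A minimal config:

```yaml
panels: demo/cohort/panels/*.tsv
atlas: demo/cohort/atlas.tsv
subjects: demo/cohort/subjects.tsv
output_dir: demo/out
k_min: 2
k_max: 10
n_restarts: 250
seed: 1
covariates: [age, education, symptom_score, sex]
```

Outputs are delimited tables (`entropy.tsv`, `k_sweep.tsv`,
`stats_network.tsv`, `stats_component.tsv`, per-subject partition tables)
plus a `manifest.json` recording the config, per-subject seeds, family
sizes and thresholds. Reruns with the same config and seed are
byte-identical. Matrices persist as `.npy` with JSON sidecars; use
`--dtype float32` / `--block-size` for large N (at N=200, the dense
M × M eFC matrix is ~3 GB in float64).

## Conventions worth knowing

- Edge order is row-major over the strict upper triangle, i < j.
- "Standardized Euclidean" k-means = per-feature unit-variance scaling, then
  ordinary Lloyd's algorithm with k-means++ starts.
- Entropy normalization divides by log2(k requested), not non-empty
  communities; 0·log2(0) := 0.
- Network entropy is the unweighted mean of member components' normalized
  entropies.
- t statistics follow the (group2 − group1) sign convention with group
  labels sorted lexicographically; the group label never enters the
  residualization design.
- Similarity matrices store 1 on the (undefined) diagonal by convention.

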