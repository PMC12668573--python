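# agrimeta

A tested, reusable pipeline for analysing how the *number* of sustainable
agricultural practices affects agroecosystem services, built around paired
sustainable-vs-intensive field comparisons:

- **effects** — log response ratios (LnRR = ln(x_s / x_i)) per ecosystem
  attribute, binary practice coding and counting (counts 1–8, with 7 and 8
  merged as "7+"; low = 1–3 vs high = 4–8 classes), unweighted aggregation of
  attributes to six services, percentile-bootstrap means and 95% CIs with the
  CI-excludes-zero significance rule, aridity stratification (arid: aridity
  index < 1), and practice-count tabulations.
- **env_analysis** — VIF collinearity screening (threshold 5), Spearman
  correlations, per-block least-squares fits with permutation significance,
  and four-block (spatial / climate / soil / vegetation) variance
  partitioning of adjusted R² via inclusion–exclusion over the 15 non-empty
  block unions.
- **mapping** — replicated random-forest ensembles (default 999 trees × 100
  replicates), permutation importance with permutation-null p-values,
  block aggregation / resampling of covariate grids, Mahalanobis
  applicability masking at a chi-square quantile, 0–1 standardisation per
  scenario, predicted-vs-observed validation, and low-vs-high scenario
  comparison maps.
- **synthetic_data** — a generator for databases with this exact structure
  and *known* ground truth (linear or saturating effect of practice count on
  the LnRR scale, environmental modulation, site effects), so every stage is
  testable without any external download.
- **pipeline_io** — CSV schema + validation with machine-readable exclusion
  reasons, a JSON run manifest, deterministic master-seed fan-out, and the
  end-to-end runner.

## CLI

```sh
agrimeta simulate --n-sites 349 --n-obs 1570 --seed 1 --out runs/sim
agrimeta effects  --db runs/sim/database.csv --group-by count -B 4999 --seed 1 \
                  --out runs/effects_by_bin.csv
agrimeta envpart  --db runs/sim/database.csv --service carbon_sequestration \
                  --class high --permutations 999 --seed 1 --out runs/varpart.csv
agrimeta map      --db runs/sim/database.csv --service carbon_sequestration \
                  --class high --trees 999 --replicates 100 --mask-alpha 0.95 \
                  --seed 1 --out runs/maps
agrimeta report   --db runs/sim/database.csv --out runs/counts.csv
agrimeta run-all  --seed 1 --out runs/full
```

Exit codes: 0 success, 2 validation failure, 3 stage failure.  `run-all`
chains simulate → effects → envpart → map → report deterministically (a
single master seed is split into per-stage seeds) and writes plain CSV
outputs plus `manifest.json`.

## Database schema

One CSV row per (observation, attribute): `study_id, obs_id, site_id, lat,
lon, crop, attribute_id, service_id, x_s, x_i`, one 0/1 column per practice
axis (default 8 axes), and 14 site covariates in four blocks — spatial
(latitude via `lat`, elevation, slope), climate (aridity_index, mat, mdr,
tsea, psea), soil (ph, sand, soc, total_p), vegetation (plant_cover, ndvi,
lai).  Rows with nonpositive means, malformed numerics, or non-binary
practice codes are excluded on load with reason codes reported together.

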