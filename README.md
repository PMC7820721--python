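# runsit

**Which situations make people run longer — and which runners are sensitive
to them?**

`runsit` is a Python package for analyzing the relation between the
*situation* at the start of a run (time of day, weekday, month, weather,
surrounding landuse, neighborhood demographics) and *running performance*,
for runners with different annual activity patterns. It is aimed at
researchers in physical-activity epidemiology and mobile-health analytics
who work with app-collected run histories joined to geographic context, and
it ships a synthetic-world generator with planted ground truth so the whole
pipeline is testable without any proprietary data.

## The method

1. **Context enrichment.** On a 100 m grid, every run start gets 29
   categorical items: 3 temporal, 4 weather, 9 distances to the nearest cell
   of each landuse class, 9 coverage percentages in a 1 km² window, and 4
   neighborhood demographics. Continuous features are discretized into a `0`
   category plus decile bins of the reference cell distribution.
2. **Performance normalization.** Run distance is scored against the
   runner's own statistics,
   `y' = (y − average(yᵘ)) / (max(yᵘ) − min(yᵘ)) ∈ [−1, 1]`,
   so +0.5 means "halfway between personal average and personal best".
3. **Runner clustering.** Each user's most active 52-ISO-week window of
   weekly run counts is compared pairwise with dynamic time warping, and the
   DTW matrix is clustered with Ward agglomerative linkage
   (Lance–Williams update); cutting the dendrogram separates sporadic from
   regular runners.
4. **Weighted frequent item mining.** Runs become weighted transactions
   (29 items, weight `y'`). The weighted support
   `w(X) = Σ { wᵢ : X ⊆ Tᵢ }` of an itemset sums signed weights, so
   situations frequently tied to above-average distance get large positive
   support and below-average ones large negative support; itemsets with
   `|w(X)| ≥ σ` are mined with a signed-weight FP-Growth (exhaustive and
   pruned modes — signed weights break anti-monotone pruning, see
   `docs/methods.md`). Per-feature variability (the SD of single-item
   supports over a feature's values) screens which features matter, and can
   be compared across runner clusters.

## Worked example

```python
from runsit.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=42, n_users=200, width_cells=60, height_cells=60,
                     sigma=30.0, max_len=3)
report = run_pipeline(cfg, "demo_out")
print(report["clusters"])
```

prints (computed, deterministic for this seed):

```
[{'cluster': 0, 'n_users': 169, 'mean_annual_runs': 34.61538461538461},
 {'cluster': 1, 'n_users': 31, 'mean_annual_runs': 96.6774193548387}]
```

The two planted archetypes (sporadic ~34 runs/yr, regular ~94 runs/yr) are
recovered as two clusters with the expected sizes and activity levels. The
default config plants +800 m on Sunday-morning runs and +400 m at moderate
temperatures; the mined top positive temporal situations for the sporadic
cluster (`demo_out/cluster0/top_temporal_positive.csv`) are

```
                         items  weighted_support  count
0  hour=[09,12)|weekday=Sunday        369.864304   1415
1               weekday=Sunday        303.961935   5091
2                 hour=[09,12)        297.994036   6340
```

— the planted Sunday-morning situation ranks first, and its support (the sum
of 1,415 normalized distances) dwarfs anything unplanted. The per-feature
variability table for the same cluster ranks temperature, weekday and hour
far above the unaffected features, mirroring how effect-carrying features
stand out for sensitive runners.

The same pipeline is available stage-by-stage from a shell:

```bash
runsit all --seed 42 --out demo_out          # or: simulate, enrich, prepare,
runsit mine --config demo_out/config.yaml --out demo_out   # cluster, mine, report
```

## Layout

```
src/runsit/
  synthetic_world.py   # landscapes, runner archetypes, planted effects
  geo_context.py       # grid, distance/coverage rasters, quantile binning
  preprocess.py        # cleaning, per-user normalization, weekly matrix
  cluster_runners.py   # DTW, Ward linkage, dendrogram cut, profiles
  situation_miner.py   # weighted FP-Growth, variability, histograms
  pipeline.py, cli.py  # orchestration + click CLI
docs/methods.md        # model, conventions, design decisions, limitations
```
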