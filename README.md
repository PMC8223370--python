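# cytodyna

Dynamic network analysis (DyNA) of multi-compartment inflammatory-mediator
time courses, for systems-immunology studies that measure a multiplex
cytokine/chemokine panel (default: a 20-plex mouse panel) in plasma and
organs of two experimental groups at a handful of terminal sampling times.

The central objects are interval-wise signed correlation networks. For each
consecutive time interval (1–4, 4–6, 6–12, 12–24, 24–48 h), strain, and
compartment, the animals sacrificed at the interval's two endpoints are
pooled; a mediator becomes an edge-eligible node only if its pooled values
differ from the 0 h control group (two-sided Mann–Whitney U, α = 0.05); and
an edge joins two eligible mediators *i*, *j* when the Pearson correlation
of their pooled values satisfies |r_ij| ≥ 0.7 (inclusive), signed by
sgn(r). Per-interval network complexity is

    complexity = (N_1 + N_2 + … + N_n) / (n − 1) = 2|E| / (n − 1),

with N_i the number of connections of mediator i and n the number of
mediators analyzed (the panel size). The total number of connections is
|E| summed over the five intervals, and differential connectivity between
strains is summarized by the per-compartment connection ratio
(wild-type : null). The package also computes trapezoidal AUCs of the mean
concentration trajectories over 0–48 h with compartment sums and strain
ratios, and windowed Spearman rank correlations (0–12 h and 12–48 h pools)
with 95% percentile-bootstrap confidence intervals.

Because studies of this design rarely deposit raw measurements, the package
includes a first-class synthetic-cohort generator (`cytodyna.simulate`)
that plants interval-specific correlation blocks and baseline responders in
log-normal data, so every stage of the pipeline can be validated by
parameter recovery against known ground truth.

## Worked example

```python
from cytodyna import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=1, out_dir="out"))
print("connection-ratio ranking:",
      " > ".join(report["connection_ratio_ranking"]))
for comp in report["connection_ratio_ranking"]:
    print(f"{comp:8s}"
          f" conn_ratio={report['connection_ratio_by_compartment'][comp]:6.2f}"
          f" auc_ratio={report['auc_ratio_by_compartment'][comp]:5.2f}")
```

With the default configuration this simulates the canned study-like
scenario (two strains, seven compartments, 8 vs 4 animals per time point)
and prints:

```
connection-ratio ranking: heart > kidney > liver > plasma > gut > spleen > lung
heart    conn_ratio= 13.00  auc_ratio= 1.66
kidney   conn_ratio=  4.00  auc_ratio= 1.15
liver    conn_ratio=  2.33  auc_ratio= 1.23
plasma   conn_ratio=  1.67  auc_ratio= 1.16
gut      conn_ratio=  1.50  auc_ratio= 0.99
spleen   conn_ratio=  0.75  auc_ratio= 0.76
lung     conn_ratio=  0.50  auc_ratio= 0.78
```

The heart shows by far the largest wild-type : null connection ratio (13
wild-type edges for every null edge) and the largest AUC ratio — the
strain difference is most concentrated there — while gut, lung and spleen
ratios at or below 1 indicate compartments where the null strain's network
is as dense or denser. The same report carries the windowed rank
correlations; e.g. IL-17A~GM-CSF in wild-type plasma is significant only
in the late window:

```
IL-17A~GM-CSF plasma 12-48h: rho=0.857 CI=[0.636,0.940] significant=True
IL-17A~GM-CSF plasma 0-12h:  rho=-0.072 CI=[-0.384,0.256] significant=False
```

`run_pipeline` writes the full bundle — cohort CSV, one edge list and one
GraphML file per (strain, compartment, interval), complexity/AUC/Spearman
JSON summaries, and a consolidated `report.json` + `report.md` — into the
output directory, all stamped with the seed and config hash and
byte-reproducible for a fixed seed.

The same stages are available from the shell:

```bash
cytodyna simulate --seed 1 --out cohort.csv --truth truth.json
cytodyna dyna --cohort cohort.csv --out networks/
cytodyna auc --cohort cohort.csv --out auc.json
cytodyna correlate --cohort cohort.csv --pairs IL-17A:GM-CSF --out spearman.json
cytodyna run-all --seed 1 --out out/
```

To analyze real data, provide a tidy CSV with columns
`strain,compartment,time_h,animal_id,mediator,concentration`
(`read_cohort(..., wide=True)` accepts one-column-per-mediator layouts).

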