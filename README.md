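# selentropy

Selectivity entropy and related promiscuity metrics for compound
panel-profiling data.

## The problem

Kinase inhibitors (and increasingly compounds in other target families) are
profiled against panels of tens to hundreds of assays, producing a matrix
of affinities — Kd, Ki, or IC50 measured at [ATP] = KM,ATP. Medicinal
chemists need to distill each row of that matrix into a single number
answering "how selective is this compound?", to rank hits, steer series,
and decide when a compound is selective enough. `selentropy` implements the
metric designed for exactly that, together with the earlier scores it is
usually compared against, for anyone working with panel profiling data:
screening groups, lead-optimization teams, and computational chemists.

## The model

Imagine a hypothetical mixture of all panel targets with a trace of
compound added: at equilibrium the compound distributes over the targets in
proportion to its association constants, a Boltzmann distribution over
binding free energies. With occupancy fractions

    φᵢ = K_a,i / ΣK,    K_a,i = 1 / K_d,i,    ΣK = Σⱼ K_a,j,

the **selectivity entropy** is the Gibbs/Shannon entropy of that
distribution (natural log, nats):

    S_sel = − Σᵢ φᵢ ln φᵢ

S_sel = 0 means perfectly selective; ln n means uniform promiscuity over n
targets. Because φ is a ratio, S_sel needs no arbitrary cutoff, no reference
target, and is invariant to common rescaling of all affinities — including
the Cheng–Prusoff factor 2 between IC50-at-KM,ATP and Kd. Non-binding
targets contribute nothing (0·ln 0 = 0), so panel padding does not change
the value.

Also implemented, for comparison and because they remain in wide use:

- **S(c)** — fraction of the tested panel hit below a cutoff concentration
  (default 3 μM), and **S(fold)** — fraction within a fold factor (default
  10×) of the most potent target;
- **partition index (Pmax)** — the largest φᵢ, the fraction of compound
  bound to the most potently hit target;
- **Gini score** — one minus twice the area under the Lorenz curve of
  rank-ordered %-inhibition (computed from Kd profiles via the Hill
  expression at a stated test concentration), and the **Ka-Gini** variant
  computed directly on association constants;
- a **weighted entropy** for panels where some targets matter more than
  others.

On top of the per-compound metrics the package provides rank-order
comparison between metrics, cross-dataset robustness statistics (R²,
Pearson correlation, squared distance of normalized value pairs to the 1:1
line), entropy-distribution benchmarking with a selective/promiscuous
classifier (threshold 2 nats), Welch t-tests between labelled compound
groups, hit prioritization for multi-assay screens, and a seeded
synthetic-profile generator.

## Worked example

Panel files are plain CSV: a header of target ids after a compound column,
one row per compound, empty cells for missing measurements and `>X` for
censored ones (default unit nM):

```csv
compound,ABL1,KDR,SRC,AURKA
imatinib-like,1,,,>10000
broad-like,2,3,2,4
mid-like,1,50,1000,
```

```sh
$ selentropy score demo.csv
compound,gini,s_cutoff,s_fold,pmax,ka_gini,entropy,rank_gini,rank_s_cutoff,rank_s_fold,rank_pmax,rank_ka_gini,rank_entropy,n_targets_used
imatinib-like,0.75,0.25,0.25,1,0.75,0,1,1,1,1,1,1,1
broad-like,0.000436145,1,1,0.315789,0.144737,1.34748,3,3,3,3,3,3,4
mid-like,0.35178,0.75,0.25,0.979432,0.739226,0.104179,2,2,2,2,2,2,3
```

`imatinib-like` binds one target at 1 nM and shows the textbook selective
signature: entropy 0, Pmax 1, rank 1 under every metric. `broad-like` hits
all four targets at 2–4 nM, giving an entropy of 1.35 (close to the ln 4 ≈
1.386 ceiling for four equal targets) and a Pmax of 0.32. `mid-like`
illustrates what the entropy adds over cutoff scores: S(10x) cannot
distinguish it from `imatinib-like` (both 0.25), but its weak secondary
activities move the entropy to 0.104. Note rank 1 means *most selective*
for every metric; for Gini-type scores and Pmax, where larger values mean
more selective, ranking is by descending value.

```sh
$ selentropy benchmark demo.csv
mean,median,sd,n,threshold,n_selective,n_promiscuous
0.483888,0.104179,0.749709,3,2.0,3,0
```

All three compounds fall below the 2-nat threshold that separates selective
from promiscuous compounds (the mean entropy of a large 290-kinase
profiling collection is 1.8, median 1.9, sd 1.0 — computable from the
packaged benchmark via `selentropy.kinome_benchmark()`).

Other subcommands: `selentropy compare A.csv B.csv` (cross-dataset
robustness of every metric; panel A is the x dataset and the Ka-Gini set is
min-rescaled before normalization) and `selentropy simulate` (seeded
synthetic panels). The same functionality is available from Python:

```python
import selentropy as se

panel = se.read_panel("demo.csv", unit="nM")
reports = se.compute_all_metrics(panel)
se.selectivity_entropy([1e9, 1e9]).s_sel   # 0.693... = ln 2
```

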